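# epiorient

Quantitative analysis of oriented cell division in the developing mouse
epidermis: cortical polarity-crescent quantification, division-angle
statistics, telophase-correction classification, and clonal fate analysis —
with a synthetic-data generator that attaches ground truth to every image and
table it produces.

## The scientific problem

Basal keratinocyte progenitors in stratified epidermis divide either
**planar** (parallel to the basement membrane, self-renewing) or
**perpendicular** (asymmetric, differentiative). Division orientation is
controlled by an apical cortical crescent of the spindle-orientation scaffold
LGN/Gpsm2, antagonized by its cytoplasmic paralog AGS3/Gpsm1. Many cells
enter anaphase at *oblique* angles (30–60°) and reorient within the following
hour to one of the two stable orientations — *telophase correction*. This
package implements the measurements that make these phenomena quantitative:

- **Crescent metrics** (`epiorient.cortical`). Cortical signal is read along
  the cell perimeter (defined by a membrane stain), compressed to 100 samples
  in percent-perimeter coordinates starting from the basal-most point, and
  background-subtracted. With threshold *t* (default 20 AU) and
  threshold-subtracted samples *aᵢ*, the metrics are
  - maximum F.I. — max of the profile;
  - cortical coverage — span of the longest circularly contiguous run of
    samples with *aᵢ* > 0, in % perimeter;
  - integrated F.I. (AUC) — Σ (aᵢ + aᵢ₊₁)/2 over that run's unit intervals;
  - crescent position — the run's circular midpoint (basal = 0/100, apex = 50).
- **Division angles** (`epiorient.orientation`). The acute angle θ ∈ [0°, 90°]
  between the daughter-centroid axis and the basement membrane; bins
  planar [0, 30), oblique [30, 60), perpendicular [60, 90]; cumulative
  frequency distributions compared across genotypes with the two-sample
  Kolmogorov–Smirnov test.
- **Telophase correction** (`epiorient.correction`). Paired anaphase-onset /
  +1 hr angles (φ, θ) classified by their bin trajectory; oblique entries
  tabulated per genotype as planar- vs perpendicular-corrected and compared
  with Fisher's exact test (chi-square for r×c tables).
- **Clone fates and differentiation** (`epiorient.fate`). Two-cell
  lineage-traced clones classified as SCD (2 basal), ACD (1 basal +
  1 suprabasal), or delamination (1 first-spinous suprabasal); spinous-layer
  thickness measured as thresholded K10⁺ mask area / basement-membrane length.
- **Synthetic data** (`epiorient.synthetic`). Generators for mitotic-cell
  images with parameterized crescents, paired-angle tables with
  genotype-dependent correction bias, clone tables, and two-layer tissue
  images — each with a `SyntheticTruth` record for parameter-recovery testing.

## Worked example

Render a mitotic cell with a known apical crescent (center 50 % perimeter,
nominal width 30 %, amplitude 60 AU over 12 AU background, noise 4 AU), then
quantify it blind to the truth:

```python
import numpy as np
from epiorient import synthetic, cortical
from epiorient.types import CrescentTruth

geom = synthetic.circle_geometry()
truth = CrescentTruth(center_position=50, coverage=30, amplitude=60,
                      background=12, noise_sd=4)
img, mask, _ = synthetic.generate_cell_image(geom, truth, seed=42)

contour = cortical.extract_perimeter(mask, geom.basement_line)
profile = cortical.sample_linescan(img, contour, boundary_mask=mask)
m = cortical.compute_crescent_metrics(profile, threshold=20.0)
print(f"max_fi={m.max_fi:.1f}  integrated_fi={m.integrated_fi:.1f}  "
      f"coverage={m.coverage:.1f}  position={m.position:.1f}")
print("localization:", cortical.classify_localization(m))
```

```
max_fi=59.1  integrated_fi=449.3  coverage=18.0  position=50.0
localization: apical
```

The position and peak are recovered almost exactly. The measured coverage
(18 %) is the *supra-threshold* width of the graded raised-cosine crescent:
at threshold 20 AU and amplitude 60 AU the expected value is
30 · arccos(2·20/60 − 1)/π ≈ 18.2 %, so the metric is behaving exactly as
defined (`docs/methods.md` discusses this shape factor).

Telophase correction, comparing the wild-type preset (obliques correct
50 : 50) with an AGS3-loss-like preset (72 % perpendicular correction),
400 simulated divisions each:

```python
import pandas as pd
from epiorient.correction import correction_table, fisher_exact_2x2

wt, _ = synthetic.simulate_division_angles(synthetic.angle_params_for("WT", n=400, seed=1))
ko, _ = synthetic.simulate_division_angles(synthetic.angle_params_for("AGS3-KO", n=400, seed=2))
table, excluded = correction_table(pd.concat([wt, ko], ignore_index=True))
print(table)
print("Fisher p =", fisher_exact_2x2(table.values))
```

```
          corrected_to_planar  corrected_to_perpendicular
genotype
AGS3-KO                    27                          89
WT                         73                          59
Fisher p = 3.31e-07
```

89/116 ≈ 77 % of the mutant's obliques corrected to perpendicular versus
45 % in the wild type (persistent obliques — 8 and 7 cells — are excluded
from the table and reported separately), a highly significant bias.

The same stages are available from the shell:

```sh
epiorient simulate-angles --genotype AGS3-KO --n 200 --seed 3 --out angles.csv
epiorient correction --table angles.csv --test fisher --out correction.json
epiorient run --seed 1 --out demo/   # full synthetic pipeline + manifest
```

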