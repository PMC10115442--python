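# Methods

This note records the models behind `epiorient`, the parameters that matter,
the numerical conventions, and what the synthetic-data tests do and do not
establish about real microscopy data.

## Coordinates and conventions

Images use (row, col) pixel coordinates, origin top-left, y increasing
downward. The canonical 1-D coordinate along a cell boundary is **percent
perimeter** in [0, 100): position 0 at the basal-most contour point (minimal
perpendicular distance to the basement-membrane line), increasing
counterclockwise in (x = col, y = row) coordinates, apex at 50. Rasterized
contours run flat along the basal side, so the minimal-distance point is
usually a whole segment of ties; the start point is the circular midpoint of
the near-minimal run (half-pixel tolerance), which keeps the
parameterization symmetric — for a circle above a horizontal basement
membrane, position 50 is exactly the topmost point. Any residual exact tie
resolves to the smaller x. Angles are degrees in [0, 90] against the
basement-membrane axis; orientation bins are planar [0, 30), oblique
[30, 60), perpendicular [60, 90] (left-closed/right-open, top bin closed).
Measured angles are continuous, so the boundary convention is immaterial in
practice; it only pins down the behavior of exact integer inputs.

## Crescent quantification

A linescan is 100 evenly spaced samples of mean cortical intensity in a
circular band (half-width 3 px by default) around the contour. The
cytoplasmic background — the mean over interior pixels farther than the
band (+2 px safety margin) from the boundary — is subtracted first; the
detection threshold (default 20 AU) is then applied to the subtracted
profile. This order matters: the background (~12 AU in the emulated data)
and the signal/noise threshold are different quantities with different jobs.

Supra-threshold samples (strictly `>`, assessed circularly so basal
crescents may cross the 0/100 seam) form runs. The **longest** run defines:

- coverage: a run of k samples spans k−1 unit intervals, i.e. (k−1)% for the
  100-point profile (a fully supra-threshold profile spans 100%);
- integrated F.I.: Σ (aᵢ + aᵢ₊₁)/2 over the run's intervals, aᵢ the
  threshold-subtracted value — the trapezoid rule on unit spacing;
- position: the run's circular midpoint (for a fully supra-threshold
  profile, where no midpoint exists, the circular centroid of aᵢ).

Maximum F.I. is taken over the whole profile, so minor disjoint
supra-threshold islands contribute to it but not to coverage/AUC/position.
Equally long runs tie-break to the smaller start position. A longest run of
a *single* sample spans zero intervals and is reported as coverage 0 with no
position: isolated one-sample spikes are sub-resolution noise, which is the
stated purpose of the 20 AU threshold in the first place. Consequence: a
profile can have max F.I. above threshold with zero coverage; "coverage > 0"
implies "max F.I. > threshold" but not conversely.

**Monotonicity.** Coverage is non-increasing in the threshold for arbitrary
profiles (every run shrinks, so the longest span cannot grow); this is
property-tested adversarially. Integrated F.I. is non-increasing for
single-crescent profiles, where the longest run nests as the threshold
rises. It is *not* globally monotone: with two disjoint islands, a rising
threshold can shrink a long dim island below the length of a short bright
one, switching the longest-run identity to a larger AUC. The metric is
defined for cells with one crescent; multi-island profiles are the regime
the threshold exists to suppress.

**Localization classes.** absent (coverage 0); unpolarized (coverage >
60 %); apical (polarized, position in (25, 75)); other polarized crescents
are reported distinctly as `nonapical_polarized` and can be collapsed into
`unpolarized` for three-way tables. The 60 % cut and the apical half-window
are quantitative stand-ins for a qualitative visual score.

**Threshold sensitivity.** Two cell groups are re-scored at several
thresholds (default 10/20/30 AU) and compared on integrated F.I. (coverage
and max F.I. selectable) with the two-sided Mann–Whitney test: exact
permutation enumeration (midranks, doubled smaller tail, capped at 1) when
the combined n ≤ 20, otherwise the tie-corrected normal approximation.

## Synthetic cell images

`generate_cell_image` paints, over a simple-polygon cell: cytoplasm at the
background level; a cortical band (nominal half-width 3 px, painted 1.5 px
wider so a sampling disk centered on the rasterized contour never reads
unpainted pixels) carrying background + amplitude·w(s); additive Gaussian
noise clipped at zero. The window w(s) is a raised cosine of total width
`coverage` centered at `center_position` — antibody crescents have graded
shoulders — with a rectangular option for oracle tests.

The two windows play different roles in validation. With the rectangular
window, thresholding recovers the nominal coverage directly, so the
recovery harness (216-point grid over center × coverage 10–60 % × amplitude
30–100 AU, noise at amplitude/10) uses it and achieves median position error
≤ 2 % and coverage error ≤ 5 % perimeter. With the raised cosine, the
supra-threshold width is the nominal coverage scaled by
arccos(2t/A − 1)/π — e.g. 0.61 at t = 20, A = 60 — so a fixed-threshold
reading *correctly* reports the smaller supra-threshold width; position
recovery is well-posed for both windows and is additionally checked on the
raised cosine.

## Division-angle simulator

Anaphase-onset (t = 0) angles are drawn uniformly within the bin selected by
mixture weights (w_planar, w_oblique, w_perp). The uniform-within-bin choice
is a modeling decision; the emulated observations constrain only the bin
frequencies ("randomized" entry), not the within-bin law. One hour later:

- planar/perpendicular entries persist with Gaussian jitter (sd 5° default),
  clipped to [0, 90] — jitter across a bin edge is reported by the
  trajectory classifier as `destabilized`;
- obliques remain oblique with probability `p_stay_oblique` (default 0.05,
  "rare cells"; re-drawn uniform in [30, 60)), otherwise correct to a
  uniform draw in [60, 90] with probability `p_perp_given_oblique` or in
  [0, 30) with the complement. Correction is a single memoryless Bernoulli
  event: within-hour kinetics are deliberately not modeled.

Genotype presets (conveniences, not claims): wild type w = ⅓ each,
p_perp = 0.5; AGS3-loss-like p_perp = 0.72; LGN-loss-like w_planar = 0.67,
p_perp = 0.14, with the remaining t = 0 weight split 0.20 oblique / 0.13
perpendicular so that oblique entries remain numerous enough to observe
correction events.

## Contingency statistics

Fisher's exact test uses the probability-mass two-sided convention (sum of
hypergeometric probabilities of all margin-fixed tables no more probable
than the observed one); the test suite verifies it against an exact rational
enumeration for every 2×2 table with grand total ≤ 30. Chi-square is Pearson
without Yates correction by default (a flag enables it), erroring on zero
expected counts. The KS p-value uses the asymptotic Kolmogorov distribution
at effective size n_a·n_b/(n_a+n_b), with an exact small-sample option.

**Type-I calibration.** Fisher's test is conservative: its attainable size
at α = 0.05 is well below 5 % for small arms (exact computation over the
binomial outcome grid gives ~2.7–4.0 % for 30–200 obliques per arm). The
calibration study therefore simulates 300 obliques per arm, where the exact
rejection probability is 4.54 %, so a 10,000-replicate Monte-Carlo estimate
(SE ≈ 0.21 %) lies in 5 % ± 1 %. The power check (presets 0.5 vs 0.72) uses
50 obliques per arm, the scale of a realistic live-imaging campaign, and
verifies stability across replicate blocks rather than a point value.

## Clones and thickness

The two-cell tracing rubric classifies (2, 0) → SCD, (1, 1) → ACD, and a
single first-spinous suprabasal cell → delamination; every other composition
(larger clones — more than one division in the tracing window — single basal
cells, or suprabasal cells above the first spinous layer) is `excluded` with
a reason, and counts always reconcile with the input. Fate proportions are
reported against both denominators of interest: divisions (SCD + ACD) and
differentiative clones (ACD + delamination).

Spinous thickness = thresholded K10⁺ mask area (µm²) / basement polyline arc
length (µm). Otsu thresholding is the default (flat images short-circuit to
an empty mask); a fixed-AU threshold is available. The tissue generator
offsets both layers vertically above a sinusoidal basement line, which
preserves band area (Cavalieri), so the true mean thickness against the
arc length is known analytically and recovery is tested to 2 %, and to half
a pixel for a flat basement membrane.

## Problem sizes and determinism

The test suite and acceptance script size their simulations so the full run
completes in well under a minute on one core while keeping Monte-Carlo error
far inside each tolerance: 10⁴ draws for frequency-recovery checks against
exact 99 % binomial intervals, 10⁴ replicates for the type-I calibration,
216 rendered cells for the recovery grid, 400-cell arms for preset
signatures. Every stochastic routine takes an explicit integer seed
(numpy `default_rng`); identical seeds give bit-identical images, tables,
and reports, which the manifest checksums in `epiorient.io.run_pipeline`
make auditable.

## What the synthetic tests do not show

The generator emulates the *statistical structure* the analyses assume, not
microscopy physics: no point-spread function, photobleaching, z-projection
artifacts, segmentation error (boundary masks are inputs), or
embryo-to-embryo variation (cells are pooled, matching the emulated study
design; no mixed-effects structure). Passing recovery tests therefore
demonstrates correctness of the measurement code under the stated model, not
robustness to real staining variability. Angles come from 2-D projections by
construction; no 3-D correction is attempted.
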