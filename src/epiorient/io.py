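"""File I/O, schema-validated tables, configuration, and the pipeline driver.

Conventions: TIFF for images (single- or multi-page), comma-separated UTF-8
CSV with a header row and '.' decimals for tables, JSON/YAML for
configuration, JSON for reports. All stochastic stages take the single
pipeline seed; a run manifest with content checksums makes reruns auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("epiorient")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
    "run_pipeline",
]


# column name -> (dtype, validator) ; validators raise with row context upstream
TABLE_SCHEMAS: dict[str, dict[str, Any]] = {
    "angles": {
        "columns": {"cell_id": str, "genotype": str, "angle_t0": float, "angle_t60": float},
        "checks": {"angle_t0": lambda v: 0 <= v <= 90, "angle_t60": lambda v: 0 <= v <= 90},
    },
    "divisions": {
        "columns": {"cell_id": str, "embryo_id": str, "genotype": str, "stage": str,
                    "angle": float, "reporter": str},
        "checks": {"angle": lambda v: 0 <= v <= 90},
    },
    "clones": {
        "columns": {"clone_id": str, "embryo_id": str, "genotype": str, "n_basal": int,
                    "n_suprabasal": int, "first_spinous": bool},
        "checks": {"n_basal": lambda v: v >= 0, "n_suprabasal": lambda v: v >= 0},
    },
    "linescans": {
        "columns": {"cell_id": str, "reporter": str,
                    **{f"pos_{i}": float for i in range(100)}, "background": float},
        "checks": {"background": lambda v: v >= 0},
    },
}


@dataclasses.dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end synthetic run needs."""

    seed: int = 0
    threshold: float = 20.0
    band_halfwidth: float = 3.0
    n_linescan_points: int = 100
    bin_edges: tuple[float, float] = (30.0, 60.0)
    ks_mode: str = "asymp"
    mw_method: str = "auto"
    n_cells: int = 25
    n_angles: int = 200
    n_clones: int = 500
    genotypes: tuple[str, ...] = ("WT", "AGS3-KO")
    out_dir: str = "epiorient_run"
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if self.threshold < 0 or self.band_halfwidth <= 0:
            raise ValueError("threshold must be >= 0 and band_halfwidth > 0")
        if self.n_linescan_points < 10:
            raise ValueError("n_linescan_points must be >= 10")
        if not (0 < self.bin_edges[0] < self.bin_edges[1] < 90):
            raise ValueError("bin edges must satisfy 0 < e1 < e2 < 90")
        if min(self.n_cells, self.n_angles, self.n_clones) <= 0:
            raise ValueError("sample sizes must be positive")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("bin_edges", "genotypes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    package_version: str
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (channels, h, w) or (h, w) array."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    arr = tifffile.imread(p)
    return np.asarray(arr)


def write_image(path: str | Path, array: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(array))


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises with the row number and column of the first violation.
    """
    if schema not in TABLE_SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; have {sorted(TABLE_SCHEMAS)}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"table not found: {p}")
    spec = TABLE_SCHEMAS[schema]
    # keep literal "NA" reporter labels instead of coercing them to NaN
    df = pd.read_csv(p, keep_default_na=False, na_values=[""])
    missing = set(spec["columns"]) - set(df.columns)
    if missing:
        raise ValueError(f"{p}: missing columns {sorted(missing)}")
    for col, typ in spec["columns"].items():
        try:
            if typ is bool:
                df[col] = df[col].astype(str).str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False})
                if df[col].isna().any():
                    row = int(df[col].isna().idxmax())
                    raise ValueError(f"row {row}")
            else:
                df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as e:
            raise ValueError(f"{p}: column {col!r} failed type coercion to {typ.__name__}: {e}")
    for col, check in spec.get("checks", {}).items():
        ok = df[col].map(check)
        if not ok.all():
            row = int((~ok).idxmax())
            raise ValueError(
                f"{p}: row {row}, column {col!r}: value {df.at[row, col]!r} out of range")
    return df


def write_table(path: str | Path, df: pd.DataFrame, schema: str | None = None) -> None:
    """Write a CSV (UTF-8, comma, header); optionally re-validated on write."""
    df.to_csv(Path(path), index=False)
    if schema is not None:
        read_table(path, schema)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full synthetic demonstration pipeline.

    Stages, in dependency order: simulate cell images and quantify their
    crescents; simulate paired division angles, summarize orientation and
    correction behavior per genotype with KS/Fisher comparisons; simulate and
    classify clones; generate a tissue image and measure spinous thickness.
    Writes four report files plus tables and a manifest into ``out_dir``.
    """
    from . import __version__, cortical, fate, synthetic
    from .correction import correction_table, fisher_exact_2x2
    from .orientation import bin_proportions, ks_two_sample

    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), package_version=__version__,
                           started=time.time())
    rng = np.random.default_rng(config.seed)

    # stage 1: synthetic cells -> crescent metrics
    logger.info("stage crescent: %d synthetic cells", config.n_cells)
    geometry = synthetic.circle_geometry()
    rows = []
    for i in range(config.n_cells):
        truth = synthetic.CrescentTruth(
            center_position=float(rng.uniform(35, 65)),
            coverage=float(rng.uniform(15, 45)),
            amplitude=float(rng.uniform(30, 90)),
            background=12.0,
            noise_sd=3.0,
        )
        img, mask, _ = synthetic.generate_cell_image(
            geometry, truth, seed=int(rng.integers(2**31)), cell_identifier=f"cell_{i:03d}")
        contour = cortical.extract_perimeter(mask, geometry.basement_line)
        prof = cortical.sample_linescan(img, contour, band_halfwidth=config.band_halfwidth,
                                        boundary_mask=mask, cell_id=f"cell_{i:03d}")
        m = cortical.compute_crescent_metrics(prof, threshold=config.threshold)
        rows.append({"cell_id": m.cell_id, "reporter": m.reporter_status,
                     "max_fi": m.max_fi, "integrated_fi": m.integrated_fi,
                     "coverage": m.coverage, "position": m.position,
                     "threshold": m.threshold,
                     "localization": cortical.classify_localization(m)})
    pd.DataFrame(rows).to_csv(out / "crescent_metrics.csv", index=False)

    # stage 2: division angles -> orientation + correction reports
    logger.info("stage orientation/correction: genotypes %s", config.genotypes)
    tables = []
    for k, g in enumerate(config.genotypes):
        params = synthetic.angle_params_for(g, n=config.n_angles, seed=config.seed + 1000 + k)
        t, _ = synthetic.simulate_division_angles(params)
        tables.append(t)
    angles = pd.concat(tables, ignore_index=True)
    write_table(out / "angles.csv", angles, schema="angles")

    div = angles.rename(columns={"angle_t60": "angle"})
    props = bin_proportions(div[["genotype", "angle"]], group_by="genotype")
    g0, g1 = config.genotypes[0], config.genotypes[-1]
    d_stat, ks_p = ks_two_sample(angles.loc[angles.genotype == g0, "angle_t60"],
                                 angles.loc[angles.genotype == g1, "angle_t60"],
                                 mode=config.ks_mode)
    orientation_report = {
        "bin_proportions": props.to_dict(orient="records"),
        "ks": {"groups": [g0, g1], "D": d_stat, "p": ks_p},
    }
    (out / "orientation_report.json").write_text(json.dumps(orientation_report, indent=2))

    ctab, excluded = correction_table(angles)
    correction_report = {
        "table": ctab.to_dict(orient="index"),
        "remained_oblique": excluded.to_dict(orient="index"),
    }
    if ctab.shape == (2, 2):
        correction_report["fisher_p"] = fisher_exact_2x2(ctab.values)
    (out / "correction_report.json").write_text(json.dumps(correction_report, indent=2))

    # stage 3: clones -> fate report
    logger.info("stage clones: %d per genotype", config.n_clones)
    clone_tables = []
    fractions = {"WT": dict(p_scd=0.45, p_acd=0.35, p_delam=0.20),
                 "AGS3-KO": dict(p_scd=0.15, p_acd=0.60, p_delam=0.25),
                 "LGN-KO": dict(p_scd=0.70, p_acd=0.10, p_delam=0.20)}
    for k, g in enumerate(config.genotypes):
        p = fractions.get(g, dict(p_scd=1 / 3, p_acd=1 / 3, p_delam=1 / 3))
        ct, _ = synthetic.simulate_clones(
            synthetic.CloneSimParams(n=config.n_clones, seed=config.seed + 2000 + k,
                                     genotype=g, **p))
        clone_tables.append(ct)
    clones = pd.concat(clone_tables, ignore_index=True)
    clones.insert(1, "embryo_id", clones.pop("embryo_id"))
    write_table(out / "clones.csv", clones, schema="clones")
    fate_report = fate.fate_proportions(clones).to_dict(orient="records")
    (out / "fate_report.json").write_text(json.dumps(fate_report, indent=2))

    # stage 4: tissue thickness
    k10, _k14, poly, truth = synthetic.generate_tissue_image(seed=config.seed + 3000)
    meas = fate.measure_thickness(k10, poly, pixel_size=truth.params["pixel_size"])
    thickness_report = {
        "thickness_um": meas.thickness,
        "k10_area_um2": meas.k10_area,
        "basement_length_um": meas.basement_length,
        "threshold": {"method": meas.threshold_method, "value": meas.threshold_value},
        "truth_thickness_um": truth.labels["expected_thickness_um"],
    }
    (out / "thickness_report.json").write_text(json.dumps(thickness_report, indent=2))

    config.to_yaml(out / "config.yaml")
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    return manifest
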