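"""Telophase-correction analysis of paired anaphase-onset / +1 hr angles.

Basal cells frequently enter anaphase at oblique angles (30-60 degrees) and
reorient within the following hour to planar or perpendicular ("telophase
correction"). Each paired division is classified by its t=0 and t=+1 hr
orientation bins; oblique entries that corrected are tabulated per genotype
as planar- vs perpendicular-corrected (rare persistent obliques are excluded
from the table and reported separately), and genotypes are compared with
Fisher's exact test or the chi-square test.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .orientation import bin_angle
from .types import PairedDivision

__all__ = [
    "classify_trajectory",
    "correction_table",
    "fisher_exact_2x2",
    "chi_square_test",
]

CORRECTION_CATEGORIES = (
    "corrected_to_planar",
    "corrected_to_perpendicular",
    "remained_oblique",
    "stable_planar",
    "stable_perpendicular",
    "destabilized",
)


def classify_trajectory(pair: PairedDivision) -> tuple[str, str]:
    """Correction category of one paired division, from its t=0 x t=+1 hr bins.

    Returns ``(category, detail)`` where detail carries the destination bin
    (useful for destabilized trajectories); for the other categories it
    repeats the t=+1 hr bin.
    """
    b0 = bin_angle(pair.angle_t0)
    b1 = bin_angle(pair.angle_t60)
    if b0 == "oblique":
        if b1 == "planar":
            return "corrected_to_planar", b1
        if b1 == "perpendicular":
            return "corrected_to_perpendicular", b1
        return "remained_oblique", b1
    if b1 == b0:
        return f"stable_{b0}", b1
    return "destabilized", b1


def _pairs_frame(pairs: Iterable[PairedDivision] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
        required = {"cell_id", "genotype", "angle_t0", "angle_t60"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return df
    return pd.DataFrame(
        [{"cell_id": p.cell_id, "genotype": p.genotype,
          "angle_t0": p.angle_t0, "angle_t60": p.angle_t60} for p in pairs]
    )


def classify_trajectories(pairs: Iterable[PairedDivision] | pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_trajectory` over a table of paired angles;
    adds ``category`` and ``t60_bin`` columns."""
    df = _pairs_frame(pairs)
    cats, details = [], []
    for t0, t60 in zip(df["angle_t0"], df["angle_t60"]):
        c, d = classify_trajectory(PairedDivision(cell_id="x", genotype="x",
                                                  angle_t0=float(t0), angle_t60=float(t60)))
        cats.append(c)
        details.append(d)
    out = df.copy()
    out["category"] = cats
    out["t60_bin"] = details
    return out


def correction_table(pairs: Iterable[PairedDivision] | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype x {planar-corrected, perpendicular-corrected} counts for t=0
    obliques; persistent obliques are excluded from the table and returned as
    a separate per-genotype count.

    Returns ``(table, excluded)``. With no oblique entries at all the table
    is empty and a warning is emitted.
    """
    import warnings

    df = classify_trajectories(pairs)
    obl = df[df["category"].isin(
        ["corrected_to_planar", "corrected_to_perpendicular", "remained_oblique"])]
    if obl.empty:
        warnings.warn("no oblique t=0 divisions in input; correction table is empty")
    corrected = obl[obl["category"] != "remained_oblique"]
    genotypes = sorted(obl["genotype"].unique())
    table = pd.DataFrame(
        {
            "corrected_to_planar": [
                int(((corrected["genotype"] == g)
                     & (corrected["category"] == "corrected_to_planar")).sum())
                for g in genotypes
            ],
            "corrected_to_perpendicular": [
                int(((corrected["genotype"] == g)
                     & (corrected["category"] == "corrected_to_perpendicular")).sum())
                for g in genotypes
            ],
        },
        index=pd.Index(genotypes, name="genotype"),
    )
    excluded = pd.DataFrame(
        {
            "remained_oblique": [
                int(((obl["genotype"] == g) & (obl["category"] == "remained_oblique")).sum())
                for g in genotypes
            ]
        },
        index=pd.Index(genotypes, name="genotype"),
    )
    return table, excluded


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The p-value sums hypergeometric probabilities (margins fixed) of every
    table at most as probable as the observed one (probability-mass
    ordering). Returns p in (0, 1].
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return float(p)


def chi_square_test(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, df, p). Expected counts come from the margins; a zero
    expected count raises, naming the cell. Yates continuity correction is
    off by default (flag provided for 2x2 tables).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError(f"need an r x c table with r,c >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    zero = np.argwhere(expected == 0)
    if zero.size:
        r, c = zero[0]
        raise ValueError(f"expected count is zero at cell (row {r}, col {c})")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=yates)
    return float(stat), int(dof), float(p)
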