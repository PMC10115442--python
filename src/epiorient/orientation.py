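"""Division-angle statistics: angle measurement, orientation bins, ECDFs,
and two-sample Kolmogorov-Smirnov comparisons between genotypes.

Division orientation is the acute angle between the basement-membrane axis
and the vector joining the daughter-nucleus centroids, in [0, 90] degrees.
Angles bin into planar [0, 30), oblique [30, 60) and perpendicular [60, 90]
(left-closed/right-open, top bin closed at 90).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DivisionRecord, PLANAR_EDGE, PERP_EDGE

__all__ = ["division_angle", "bin_angle", "ecdf", "ks_two_sample", "bin_proportions",
           "plot_ecdf"]

BIN_NAMES = ("planar", "oblique", "perpendicular")


def division_angle(
    centroid_a: Sequence[float],
    centroid_b: Sequence[float],
    basement_vector: Sequence[float],
) -> float:
    """Acute angle (degrees, [0, 90]) between the daughter-centroid axis and
    the basement-membrane direction; symmetric in daughter order."""
    a = np.asarray(centroid_a, dtype=float)
    b = np.asarray(centroid_b, dtype=float)
    v = np.asarray(basement_vector, dtype=float)
    d = b - a
    if not np.any(d):
        raise ValueError("daughter centroids are identical; no division axis")
    nv = np.hypot(*v)
    if nv == 0:
        raise ValueError("basement vector must be nonzero")
    cos = abs(float(np.dot(d, v))) / (np.hypot(*d) * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def bin_angle(angle: float) -> str:
    """planar [0, 30), oblique [30, 60), perpendicular [60, 90]."""
    if not 0 <= angle <= 90:
        raise ValueError(f"angle must be in [0, 90], got {angle}")
    if angle < PLANAR_EDGE:
        return "planar"
    if angle < PERP_EDGE:
        return "oblique"
    return "perpendicular"


def ecdf(angles: Iterable[float]) -> pd.DataFrame:
    """Right-continuous empirical CDF as (angle, cumulative_fraction) steps
    at the sorted unique sample values; the final fraction is 1."""
    x = np.sort(np.asarray(list(angles), dtype=float))
    if x.size == 0:
        raise ValueError("ecdf of an empty sample")
    ux, counts = np.unique(x, return_counts=True)
    return pd.DataFrame({"angle": ux, "cumulative_fraction": np.cumsum(counts) / x.size})


def ks_two_sample(a: Iterable[float], b: Iterable[float], mode: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test; returns (D, two-sided p).

    D is the supremum over pooled sample points of |F_a - F_b|. The p-value
    comes from the asymptotic Kolmogorov distribution at effective size
    n_a·n_b/(n_a+n_b) by default; ``mode='exact'`` switches to the exact
    small-sample distribution (sensible for n <= 25 per group).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("asymp", "exact"):
        raise ValueError(f"mode must be 'asymp' or 'exact', got {mode!r}")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=mode)
    return float(res.statistic), float(res.pvalue)


def plot_ecdf(groups: dict[str, Iterable[float]], path: str | None = None, ax=None):
    """Cumulative-frequency plot of division angles per group (SVG/PNG by
    file extension), with the orientation-bin edges marked."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for label, angles in groups.items():
        e = ecdf(angles)
        x = np.concatenate([[0.0], e["angle"], [90.0]])
        y = np.concatenate([[0.0], e["cumulative_fraction"], [1.0]])
        ax.step(x, y, where="post", label=f"{label} (n={len(list(angles))})")
    for edge in (PLANAR_EDGE, PERP_EDGE):
        ax.axvline(edge, ls="--", lw=0.6, color="gray")
    ax.set_xlabel("division angle (degrees)")
    ax.set_ylabel("cumulative frequency")
    ax.set_xlim(0, 90)
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def bin_proportions(records: Iterable[DivisionRecord] | pd.DataFrame, group_by: str = "genotype") -> pd.DataFrame:
    """Per-group orientation-bin fractions (with counts).

    Accepts DivisionRecord objects or a frame with ``angle`` and the grouping
    column. Fractions within each group sum to 1.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [{"cell_id": r.cell_id, "embryo_id": r.embryo_id, "genotype": r.genotype,
              "stage": r.stage, "angle": r.angle, "reporter": r.reporter_status}
             for r in records]
        )
    if df.empty:
        raise ValueError("no records")
    df["bin"] = [bin_angle(x) for x in df["angle"]]
    rows = []
    for group, sub in df.groupby(group_by, sort=True):
        n = len(sub)
        for name in BIN_NAMES:
            count = int((sub["bin"] == name).sum())
            rows.append({group_by: group, "bin": name, "count": count, "fraction": count / n, "n": n})
    return pd.DataFrame(rows)
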