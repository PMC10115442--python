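"""Cortical crescent quantification from perimeter linescans.

A mitotic cell's cortical signal is read along its boundary (defined by a
membrane stain), compressed to 100 samples in percent-perimeter coordinates
starting from the basal-most point, background-subtracted, and scored with
four metrics: maximum fluorescence intensity, integrated intensity (the
trapezoidal area under the threshold-subtracted curve, AUC), cortical
coverage (the longest contiguous supra-threshold span), and crescent position
(the circular midpoint of that span). A threshold-sensitivity routine
re-scores two cell groups at several thresholds and compares them with the
two-sided Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import CrescentMetrics, LinescanProfile, N_LINESCAN_POINTS

__all__ = [
    "PerimeterContour",
    "extract_perimeter",
    "sample_linescan",
    "estimate_background",
    "compute_crescent_metrics",
    "classify_localization",
    "aggregate_mean_profile",
    "mann_whitney_u",
    "threshold_sensitivity",
]

DEFAULT_THRESHOLD = 20.0  # AU; discriminates cortical signal from noise
DEFAULT_BAND_HALFWIDTH = 3.0  # px; half-width of the sampling band normal to the contour


@dataclass(frozen=True)
class PerimeterContour:
    """A closed cell contour with percent-arc-length parameterization.

    points : (n, 2) float array of (row, col) contour points, reordered to
        start at the basal-most point and traversed counterclockwise in
        (col, row) coordinates.
    percents : arc-length position of each point in [0, 100).
    total_length : contour length in pixels.
    """

    points: np.ndarray
    percents: np.ndarray
    total_length: float

    def point_at(self, pct: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the contour at percent position(s)."""
        pct = np.atleast_1d(np.asarray(pct, dtype=float)) % 100.0
        p = np.concatenate([self.percents, [100.0]])
        closed = np.vstack([self.points, self.points[:1]])
        r = np.interp(pct, p, closed[:, 0])
        c = np.interp(pct, p, closed[:, 1])
        return np.column_stack([r, c])


def extract_perimeter(
    boundary_mask: np.ndarray,
    basement_line: tuple[tuple[float, float], tuple[float, float]],
) -> PerimeterContour:
    """Trace the outer contour of a single-region mask and parameterize it.

    The start point (percent 0) is the contour point with minimal
    perpendicular distance to the basement-membrane line; ties resolve to the
    smaller column (x) coordinate. Orientation is counterclockwise in
    (x=col, y=row) coordinates.
    """
    from skimage import measure

    mask = np.asarray(boundary_mask).astype(bool)
    n_regions = int(ndimage.label(mask)[1])
    if n_regions != 1:
        raise ValueError(f"boundary mask must contain exactly one region, found {n_regions}")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if len(contour) < 8:
        raise ValueError(f"degenerate contour with {len(contour)} points (need >= 8)")

    # enforce counterclockwise orientation in (col, row) coordinates
    x, y = contour[:, 1], contour[:, 0]
    signed_area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed_area < 0:
        contour = contour[::-1]

    (p0, p1) = np.asarray(basement_line[0], float), np.asarray(basement_line[1], float)
    v = p1 - p0
    rel = contour - p0
    dist = np.abs(rel[:, 0] * v[1] - rel[:, 1] * v[0]) / np.hypot(*v)
    # rasterized contours run flat along the basal side, so a whole segment can
    # tie at the minimum: take the circular midpoint of the near-minimal run
    # (half-pixel tolerance), then smaller x for any residual exact tie
    idx_min = int(np.argmin(dist))
    n = len(contour)
    near = dist <= dist[idx_min] + 0.5
    lo = hi = idx_min
    while near[(lo - 1) % n] and (lo - 1) % n != hi:
        lo -= 1
    while near[(hi + 1) % n] and (hi + 1) % n != lo % n:
        hi += 1
    run = np.arange(lo, hi + 1) % n
    mid_pair = run[[(len(run) - 1) // 2, len(run) // 2]]
    start = int(mid_pair[np.argmin(contour[mid_pair, 1])])

    contour = np.roll(contour, -start, axis=0)
    seg = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    percents = np.concatenate([[0.0], np.cumsum(seg_len[:-1])]) / total * 100.0
    return PerimeterContour(points=contour, percents=percents, total_length=total)


def sample_linescan(
    image: np.ndarray,
    contour: PerimeterContour,
    n_points: int = N_LINESCAN_POINTS,
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH,
    boundary_mask: np.ndarray | None = None,
    cell_id: str = "",
    reporter_status: str = "NA",
) -> LinescanProfile:
    """Read mean cortical intensity in a circular band at ``n_points`` evenly
    spaced percent-perimeter positions.

    Sample i averages the pixels within ``band_halfwidth`` of the contour
    point at position i * (100 / n_points). Background is populated from
    :func:`estimate_background` when ``boundary_mask`` is given, else left 0;
    intensities are *not* background-subtracted here.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    pts = contour.point_at(np.arange(n_points) * (100.0 / n_points))
    if (pts[:, 0].min() < -0.5 or pts[:, 0].max() > h - 0.5
            or pts[:, 1].min() < -0.5 or pts[:, 1].max() > w - 0.5):
        raise ValueError("contour exits image bounds")

    r = int(math.ceil(band_halfwidth))
    samples = np.empty(n_points)
    for i, (pr, pc) in enumerate(pts):
        r0, r1 = max(0, int(pr) - r), min(h, int(pr) + r + 2)
        c0, c1 = max(0, int(pc) - r), min(w, int(pc) + r + 2)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        d2 = (rr - pr) ** 2 + (cc - pc) ** 2
        sel = d2 <= band_halfwidth**2
        samples[i] = image[r0:r1, c0:c1][sel].mean()

    if n_points != N_LINESCAN_POINTS:
        # compress/expand to the canonical 100 points by circular interpolation
        src = np.arange(n_points) * (100.0 / n_points)
        dst = np.arange(N_LINESCAN_POINTS, dtype=float)
        samples = np.interp(dst, np.concatenate([src, [100.0]]),
                            np.concatenate([samples, samples[:1]]))

    background = 0.0
    if boundary_mask is not None:
        # exclude a margin past the sampling band so cortical signal cannot
        # contaminate the cytoplasmic estimate
        background = estimate_background(image, boundary_mask, cortical_band=band_halfwidth + 2.0)
    return LinescanProfile(
        intensities=samples,
        background=background,
        background_subtracted=False,
        cell_id=cell_id,
        reporter_status=reporter_status,
    )


def estimate_background(image: np.ndarray, boundary_mask: np.ndarray, cortical_band: float = DEFAULT_BAND_HALFWIDTH) -> float:
    """Mean cytoplasmic (non-cortical) intensity: interior pixels farther than
    ``cortical_band`` from the cell boundary."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(boundary_mask).astype(bool)
    # distance of interior pixels to the nearest outside pixel
    dist_in = ndimage.distance_transform_edt(mask)
    interior = dist_in > cortical_band
    if not interior.any():
        raise ValueError(
            f"no interior pixels remain beyond a {cortical_band}-px cortical band; "
            "use a smaller band"
        )
    return float(image[interior].mean())


def _circular_runs(supra: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal circularly contiguous True runs."""
    n = len(supra)
    if supra.all():
        return [(0, n)]
    if not supra.any():
        return []
    # unroll at a False sample so no run crosses the cut
    cut = int(np.flatnonzero(~supra)[0])
    rolled = np.roll(supra, -cut)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append(((i + cut) % n, j - i))
            i = j
        else:
            i += 1
    return runs


def compute_crescent_metrics(profile: LinescanProfile, threshold: float = DEFAULT_THRESHOLD) -> CrescentMetrics:
    """Score a linescan at a stated threshold.

    The profile is background-subtracted first (using its own cytoplasmic
    estimate) unless already flagged as subtracted. Supra-threshold samples
    (strictly ``> threshold``, assessed circularly) form runs; the longest
    run defines cortical coverage (its span in percent: k samples span k-1
    sample intervals), crescent position (its circular midpoint), and the
    integrated F.I. (trapezoid sum of threshold-subtracted values over its
    intervals). max_fi is the maximum of the full subtracted profile. Ties
    between equally long runs resolve to the smaller start position.
    """
    v = profile.intensities.astype(float)
    if not profile.background_subtracted:
        v = v - profile.background
    n = len(v)
    unit = 100.0 / n  # percent per sample interval

    max_fi = float(v.max())
    supra = v > threshold
    runs = _circular_runs(supra)
    if not runs:
        return CrescentMetrics(max_fi=max_fi, integrated_fi=0.0, coverage=0.0, position=None,
                               threshold=threshold, cell_id=profile.cell_id,
                               reporter_status=profile.reporter_status)

    length = max(ln for _, ln in runs)
    start = min(s for s, ln in runs if ln == length)

    if length == n:  # fully supra-threshold cortex: no free endpoints
        coverage = 100.0
        a = v - threshold
        integrated = float(np.sum((a + np.roll(a, -1)) / 2.0))
        # position: circular centroid of the threshold-subtracted excess
        ang = 2 * np.pi * np.arange(n) / n
        position = float((np.degrees(math.atan2((a * np.sin(ang)).sum(), (a * np.cos(ang)).sum()))
                          % 360.0) / 360.0 * 100.0)
    else:
        if length == 1:
            # a single supra-threshold sample spans zero intervals: treated as a
            # sub-resolution spike — no measurable crescent
            return CrescentMetrics(max_fi=max_fi, integrated_fi=0.0, coverage=0.0, position=None,
                                   threshold=threshold, cell_id=profile.cell_id,
                                   reporter_status=profile.reporter_status)
        coverage = (length - 1) * unit
        idx = (start + np.arange(length)) % n
        a = v[idx] - threshold
        integrated = float(np.sum((a[:-1] + a[1:]) / 2.0))
        position = ((start + (length - 1) / 2.0) * unit) % 100.0

    return CrescentMetrics(max_fi=max_fi, integrated_fi=integrated, coverage=float(coverage),
                           position=float(position), threshold=threshold,
                           cell_id=profile.cell_id, reporter_status=profile.reporter_status)


def classify_localization(metrics: CrescentMetrics, collapse: bool = False) -> str:
    """Localization pattern from the crescent metrics.

    absent: no supra-threshold coverage. unpolarized: coverage above 60% of
    the perimeter. apical: a polarized crescent centered in the apical half
    (position in (25, 75), apex at 50). Other polarized crescents are
    reported as ``nonapical_polarized``; with ``collapse=True`` they fold
    into ``unpolarized`` for three-way tables.
    """
    if metrics.coverage == 0:
        return "absent"
    if metrics.position is None:
        raise ValueError("internal inconsistency: coverage > 0 but position undefined")
    if metrics.coverage > 60.0:
        return "unpolarized"
    if 25.0 < metrics.position < 75.0:
        return "apical"
    return "unpolarized" if collapse else "nonapical_polarized"


def aggregate_mean_profile(profiles: list[LinescanProfile], subtract_background: bool = True) -> pd.DataFrame:
    """Per-position mean and symmetric t-based 95% CI across cells.

    Returns a 100-row frame with columns position, mean, ci_low, ci_high, n.
    With a single profile the CI is undefined (NaN)."""
    if not profiles:
        raise ValueError("need at least one profile")
    mat = np.stack([
        p.intensities - (p.background if subtract_background and not p.background_subtracted else 0.0)
        for p in profiles
    ])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n > 1:
        sem = mat.std(axis=0, ddof=1) / math.sqrt(n)
        half = stats.t.ppf(0.975, df=n - 1) * sem
    else:
        half = np.full(mat.shape[1], np.nan)
    return pd.DataFrame({
        "position": np.arange(mat.shape[1], dtype=float),
        "mean": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "n": n,
    })


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    ``exact`` enumerates all group assignments of the pooled values (midranks
    handle ties), doubling the smaller tail and capping at 1; ``asymptotic``
    uses the tie-corrected normal approximation; ``auto`` picks exact when the
    combined sample size is at most 20.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    if method == "auto":
        method = "exact" if n_a + n_b <= 20 else "asymptotic"
    if method == "asymptotic":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n_a], n_a)
    total = math.comb(n_a + n_b, n_a)
    le = ge = 0
    for combo in itertools.combinations(range(n_a + n_b), n_a):
        u = _u_statistic(ranks[list(combo)], n_a)
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def threshold_sensitivity(
    group_a: list[LinescanProfile],
    group_b: list[LinescanProfile],
    thresholds=(10.0, 20.0, 30.0),
    metric: str = "integrated_fi",
    method: str = "auto",
) -> pd.DataFrame:
    """Re-score two groups of cells at each threshold and compare them with
    the two-sided Mann-Whitney test on the chosen metric (integrated F.I. by
    default; cortical coverage also supported).

    Returns a frame with one row per threshold: (threshold, metric, n_a, n_b,
    statistic, p).
    """
    if metric not in ("integrated_fi", "coverage", "max_fi"):
        raise ValueError(f"unsupported metric {metric!r}")
    rows = []
    for t in thresholds:
        va = [getattr(compute_crescent_metrics(p, threshold=t), metric) for p in group_a]
        vb = [getattr(compute_crescent_metrics(p, threshold=t), metric) for p in group_b]
        u, p = mann_whitney_u(va, vb, method=method)
        rows.append({"threshold": float(t), "metric": metric, "n_a": len(va), "n_b": len(vb),
                     "statistic": u, "p": p})
    return pd.DataFrame(rows)
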