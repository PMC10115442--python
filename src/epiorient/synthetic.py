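"""Synthetic microscopy images and measurement tables with attached ground truth.

The generators emulate the statistical structure the downstream analyses
assume: mitotic cells carrying a cortical crescent of known position/coverage/
amplitude over cytoplasmic background; paired anaphase-onset / +1 hr division
angles whose near-uniform t=0 distribution resolves into a bimodal profile
with a genotype-dependent correction bias; two-cell clone tables; and
two-layer tissue images of known suprabasal thickness. Every output carries a
:class:`~epiorient.types.SyntheticTruth` record so parameter-recovery tests
need no external data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import (
    AngleSimParams,
    CellGeometry,
    CloneSimParams,
    CrescentTruth,
    PLANAR_EDGE,
    PERP_EDGE,
    SyntheticTruth,
)

__all__ = [
    "GENOTYPE_PRESETS",
    "circle_geometry",
    "generate_cell_image",
    "simulate_division_angles",
    "simulate_clones",
    "generate_tissue_image",
]

#: Convenience presets for the orientation simulator. WT resolves a roughly
#: uniform t=0 mixture 50/50; the AGS3-loss-like preset biases oblique
#: correction toward perpendicular (0.72); the LGN-loss-like preset enters
#: anaphase planar-biased (0.67) and corrects obliques almost always to planar
#: (p_perp 0.14). Presets are conveniences for demos and tests, not claims.
GENOTYPE_PRESETS: dict[str, dict[str, float]] = {
    "WT": dict(w_planar=1 / 3, w_oblique=1 / 3, w_perp=1 / 3, p_perp_given_oblique=0.5),
    "AGS3-KO": dict(w_planar=1 / 3, w_oblique=1 / 3, w_perp=1 / 3, p_perp_given_oblique=0.72),
    "LGN-KO": dict(w_planar=0.67, w_oblique=0.20, w_perp=0.13, p_perp_given_oblique=0.14),
}


def angle_params_for(genotype: str, n: int, seed: int = 0, **overrides) -> AngleSimParams:
    """Build :class:`AngleSimParams` from a named genotype preset."""
    if genotype not in GENOTYPE_PRESETS:
        raise KeyError(f"unknown genotype preset {genotype!r}; have {sorted(GENOTYPE_PRESETS)}")
    kw = dict(GENOTYPE_PRESETS[genotype])
    kw.update(overrides)
    return AngleSimParams(n=n, seed=seed, genotype=genotype, **kw)


def circle_geometry(
    radius: float = 40.0,
    center: tuple[float, float] | None = None,
    image_shape: tuple[int, int] = (128, 128),
    n_vertices: int = 256,
    pixel_size: float = 0.2,
) -> CellGeometry:
    """A circular cell above a horizontal basement membrane.

    The basement line runs along the bottom of the image, so perimeter
    position 0 sits at the lowest contour point (basal) and 50 at the top
    (apical).
    """
    h, w = image_shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    boundary = np.column_stack([center[0] + radius * np.sin(t), center[1] + radius * np.cos(t)])
    basement = ((h - 1.0, 0.0), (h - 1.0, w - 1.0))
    return CellGeometry(boundary=boundary, basement_line=basement, image_shape=image_shape,
                        pixel_size=pixel_size)


def _boundary_arclength(boundary: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Densify a closed polygon; return points, arc length per point, total length."""
    closed = np.vstack([boundary, boundary[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    # densify so adjacent samples are < 0.5 px apart (accurate nearest-point lookup)
    pts, arcs = [], []
    s0 = 0.0
    for p, d, ln in zip(boundary, seg, seg_len):
        k = max(1, int(np.ceil(ln / 0.5)))
        f = np.arange(k) / k
        pts.append(p + f[:, None] * d)
        arcs.append(s0 + f * ln)
        s0 += ln
    return np.vstack(pts), np.concatenate(arcs), total


def crescent_window(s_pct: np.ndarray, truth: CrescentTruth, shape: str = "raised_cosine") -> np.ndarray:
    """Window weight w(s) in [0, 1] at percent-perimeter positions ``s_pct``.

    ``raised_cosine`` gives graded shoulders like antibody crescents;
    ``rect`` is the sharp-edged oracle variant used by recovery tests.
    """
    if truth.coverage == 0:
        return np.zeros_like(np.asarray(s_pct, dtype=float))
    d = np.abs((np.asarray(s_pct, dtype=float) - truth.center_position + 50.0) % 100.0 - 50.0)
    half = truth.coverage / 2.0
    if shape == "rect":
        return (d <= half).astype(float)
    if shape == "raised_cosine":
        w = 0.5 * (1.0 + np.cos(np.pi * d / half))
        return np.where(d <= half, w, 0.0)
    raise ValueError(f"unknown window shape {shape!r}")


def generate_cell_image(
    geometry: CellGeometry,
    truth: CrescentTruth,
    seed: int = 0,
    band_halfwidth: float = 3.0,
    window: str = "raised_cosine",
    cell_identifier: str = "cell",
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Render a mitotic cell with a cortical crescent.

    Cytoplasm pixels carry the truth background; pixels within
    ``band_halfwidth`` of the boundary carry background + amplitude · w(s)
    where s is the percent-perimeter position of the nearest boundary point;
    additive Gaussian noise of sd ``truth.noise_sd`` is applied everywhere
    inside the cell-plus-band support and the result clipped at 0. Identical
    (geometry, truth, seed) gives a bit-identical image.

    Returns ``(image, boundary_mask, truth_record)`` where ``boundary_mask``
    is the filled cell interior.
    """
    from skimage.draw import polygon as draw_polygon

    h, w = geometry.image_shape
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(geometry.boundary[:, 0], geometry.boundary[:, 1], shape=(h, w))
    mask[rr, cc] = True

    boundary = geometry.boundary
    # traverse counterclockwise in (x=col, y=row), matching the analysis convention
    x, y = boundary[:, 1], boundary[:, 0]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        boundary = boundary[::-1]
    dense_pts, dense_arc, total = _boundary_arclength(boundary)
    # anchor percent-perimeter 0 at the basal-most point (nearest the basement line)
    p0 = np.asarray(geometry.basement_line[0], float)
    v = np.asarray(geometry.basement_line[1], float) - p0
    rel = dense_pts - p0
    perp = np.abs(rel[:, 0] * v[1] - rel[:, 1] * v[0]) / np.hypot(*v)
    near = np.flatnonzero(np.isclose(perp, perp.min(), atol=1e-9))
    anchor = int(near[np.argmin(dense_pts[near, 1])])
    dense_arc = (dense_arc - dense_arc[anchor]) % total
    tree = cKDTree(dense_pts)

    grid_r, grid_c = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack([grid_r.ravel(), grid_c.ravel()]).astype(float)
    dist, idx = tree.query(pix, workers=-1)
    dist = dist.reshape(h, w)
    s_pct = (dense_arc[idx].reshape(h, w) / total) * 100.0

    # paint 1.5 px past the nominal half-width so a sampling disk of the same
    # half-width centered on the rasterized mask contour never reads unpainted
    # pixels
    band = dist <= band_halfwidth + 1.5
    support = mask | band

    image = np.zeros((h, w), dtype=float)
    image[support] = truth.background
    if truth.coverage > 0 and truth.amplitude > 0:
        image[band] += truth.amplitude * crescent_window(s_pct[band], truth, shape=window)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image[support] += rng.normal(0.0, truth.noise_sd, size=int(support.sum()))
        np.clip(image, 0.0, None, out=image)

    record = SyntheticTruth(
        identifier=cell_identifier,
        params=truth,
        labels={"seed": seed, "window": window, "band_halfwidth": band_halfwidth},
    )
    return image, mask, record


def _bin_of(angle: np.ndarray) -> np.ndarray:
    out = np.where(angle < PLANAR_EDGE, "planar", np.where(angle < PERP_EDGE, "oblique", "perpendicular"))
    return out


def simulate_division_angles(params: AngleSimParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw paired (t=0, t=+1 hr) division angles for ``params.n`` cells.

    t=0 angles are uniform within the orientation bin chosen by the mixture
    weights. Planar and perpendicular entries persist with truncated-Gaussian
    jitter (sd ``jitter_sd``, clipped to [0, 90]); obliques remain oblique
    with ``p_stay_oblique`` (re-drawn uniform in [30, 60)), otherwise correct
    to a uniform draw in [60, 90] with ``p_perp_given_oblique`` or in [0, 30)
    with the complement.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    bins = rng.choice(
        np.array(["planar", "oblique", "perpendicular"]),
        size=n,
        p=[params.w_planar, params.w_oblique, params.w_perp],
    )
    lo = np.select([bins == "planar", bins == "oblique"], [0.0, PLANAR_EDGE], default=PERP_EDGE)
    hi = np.select([bins == "planar", bins == "oblique"], [PLANAR_EDGE, PERP_EDGE], default=90.0)
    t0 = lo + rng.uniform(0.0, 1.0, size=n) * (hi - lo)

    t60 = np.empty(n)
    outcome = np.empty(n, dtype=object)
    oblique = bins == "oblique"

    jitter = rng.normal(0.0, params.jitter_sd, size=n) if params.jitter_sd > 0 else np.zeros(n)
    t60[~oblique] = np.clip(t0[~oblique] + jitter[~oblique], 0.0, 90.0)
    outcome[~oblique] = np.where(bins[~oblique] == "planar", "stable_planar", "stable_perpendicular")

    stay = rng.uniform(size=n) < params.p_stay_oblique
    to_perp = rng.uniform(size=n) < params.p_perp_given_oblique
    u = rng.uniform(size=n)

    m_stay = oblique & stay
    t60[m_stay] = PLANAR_EDGE + u[m_stay] * (PERP_EDGE - PLANAR_EDGE)
    outcome[m_stay] = "remained_oblique"
    m_perp = oblique & ~stay & to_perp
    t60[m_perp] = PERP_EDGE + u[m_perp] * (90.0 - PERP_EDGE)
    outcome[m_perp] = "corrected_to_perpendicular"
    m_plan = oblique & ~stay & ~to_perp
    t60[m_plan] = u[m_plan] * PLANAR_EDGE
    outcome[m_plan] = "corrected_to_planar"

    table = pd.DataFrame(
        {
            "cell_id": [f"{params.genotype}_{i:05d}" for i in range(n)],
            "genotype": params.genotype,
            "angle_t0": t0,
            "angle_t60": t60,
        }
    )
    truth = SyntheticTruth(
        identifier=f"angles_{params.genotype}_seed{params.seed}",
        params=params,
        labels={
            "t0_bin": bins.tolist(),
            "outcome": outcome.tolist(),
            # label "destabilized" cases where jitter moved a stable cell out of its bin
            "t60_bin": _bin_of(t60).tolist(),
        },
    )
    return table, truth


def simulate_clones(params: CloneSimParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw two-cell clone compositions: SCD (2 basal), ACD (1+1), or
    delamination (a single first-spinous suprabasal cell)."""
    rng = np.random.default_rng(params.seed)
    classes = rng.choice(
        np.array(["SCD", "ACD", "delamination"]),
        size=params.n,
        p=[params.p_scd, params.p_acd, params.p_delam],
    )
    n_basal = np.select([classes == "SCD", classes == "ACD"], [2, 1], default=0)
    n_supra = np.where(classes == "SCD", 0, 1)
    table = pd.DataFrame(
        {
            "clone_id": [f"{params.genotype}_clone_{i:05d}" for i in range(params.n)],
            "embryo_id": "sim_embryo",
            "genotype": params.genotype,
            "n_basal": n_basal,
            "n_suprabasal": n_supra,
            "first_spinous": classes == "delamination",
        }
    )
    truth = SyntheticTruth(
        identifier=f"clones_{params.genotype}_seed{params.seed}",
        params=params,
        labels={"clone_class": classes.tolist()},
    )
    return table, truth


def generate_tissue_image(
    basal_height: float = 10.0,
    suprabasal_height: float = 20.0,
    length: float = 100.0,
    pixel_size: float = 0.5,
    noise_sd: float = 0.0,
    wave_amplitude: float = 0.0,
    wave_period: float = 50.0,
    signal: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SyntheticTruth]:
    """Render a two-layer epidermis: a K14+ basal band on the basement
    membrane and a K10+ suprabasal band of exact height above it.

    All heights/lengths are microns. ``wave_amplitude``/``wave_period`` bend
    the basement membrane into a sinusoid (microns); the layers follow it by
    vertical offset, which preserves the band area (Cavalieri), so the true
    mean thickness is ``suprabasal_height · horizontal_length / arc_length``.

    Returns ``(k10_channel, k14_channel, basement_polyline, truth)`` with the
    polyline as (row, col) pixel coordinates along the basement membrane.
    """
    if min(basal_height, suprabasal_height, length) < 0 or length <= 0:
        raise ValueError("heights must be >= 0 and length > 0")
    nx = int(round(length / pixel_size))
    margin = 4
    ny = int(round((basal_height + suprabasal_height) / pixel_size)) + 2 * margin + int(
        np.ceil(2 * wave_amplitude / pixel_size)
    )
    x_um = (np.arange(nx) + 0.5) * pixel_size
    base_offset_um = wave_amplitude * np.sin(2 * np.pi * x_um / wave_period) if wave_amplitude else np.zeros(nx)
    # basement row (y down): deep edge of the basal band, near the image bottom
    base_row_um = (ny - margin) * pixel_size - base_offset_um

    rows_um = (np.arange(ny)[:, None] + 0.5) * pixel_size  # pixel-center depth
    depth = base_row_um[None, :] - rows_um  # microns above the basement membrane
    k14 = np.where((depth > 0) & (depth <= basal_height), signal, 0.0)
    k10 = np.where(
        (depth > basal_height) & (depth <= basal_height + suprabasal_height), signal, 0.0
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k10 = np.clip(k10 + rng.normal(0, noise_sd, k10.shape), 0, None)
        k14 = np.clip(k14 + rng.normal(0, noise_sd, k14.shape), 0, None)

    polyline = np.column_stack([base_row_um / pixel_size - 0.5, np.arange(nx, dtype=float)])

    seg = np.diff(polyline * pixel_size, axis=0)
    arc_um = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) + pixel_size  # + end pixel widths
    true_area = suprabasal_height * length
    truth = SyntheticTruth(
        identifier=f"tissue_seed{seed}",
        params={
            "basal_height": basal_height,
            "suprabasal_height": suprabasal_height,
            "length": length,
            "pixel_size": pixel_size,
            "noise_sd": noise_sd,
            "wave_amplitude": wave_amplitude,
            "wave_period": wave_period,
        },
        labels={
            "true_area_um2": true_area,
            "arc_length_um": arc_um,
            "expected_thickness_um": true_area / arc_um,
        },
    )
    return k10, k14, polyline, truth
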