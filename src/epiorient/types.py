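"""Domain containers shared across the analysis stages.

Conventions: image pixel coordinates are (row, col) with the origin at the
top-left and y increasing downward; the canonical 1-D coordinate along a cell
boundary is *percent perimeter* in [0, 100), with position 0 at the basal-most
point of the contour (nearest the basement membrane) and the apex at 50.
Angles are degrees in [0, 90] measured against the basement-membrane axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

N_LINESCAN_POINTS = 100

#: Orientation bin edges (degrees): planar [0,30), oblique [30,60), perpendicular [60,90].
PLANAR_EDGE = 30.0
PERP_EDGE = 60.0


def _finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class CellGeometry:
    """A mitotic cell outline and its basement-membrane reference axis.

    Parameters
    ----------
    boundary : (n, 2) array of (row, col) vertices of a simple closed polygon.
        The closing edge from the last vertex back to the first is implicit.
    basement_line : ((r0, c0), (r1, c1)) two points defining the basement-
        membrane direction below the cell.
    image_shape : (height, width) in pixels.
    pixel_size : microns per pixel.
    """

    boundary: np.ndarray
    basement_line: tuple[tuple[float, float], tuple[float, float]]
    image_shape: tuple[int, int]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
            raise ValueError("boundary must be an (n>=3, 2) array of (row, col) points")
        object.__setattr__(self, "boundary", b)
        h, w = self.image_shape
        rows, cols = b[:, 0], b[:, 1]
        bad = np.where((rows < 0) | (rows > h - 1) | (cols < 0) | (cols > w - 1))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"boundary vertex {i} at (row={b[i, 0]:g}, col={b[i, 1]:g}) lies "
                f"outside image of shape {self.image_shape}"
            )
        (p0, p1) = self.basement_line
        if math.hypot(p1[0] - p0[0], p1[1] - p0[1]) == 0:
            raise ValueError("basement_line has zero length")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        # simple-polygon check via shapely (cheap; boundaries are small)
        from shapely.geometry import Polygon

        if not Polygon(b).is_simple:
            raise ValueError("boundary polygon is self-intersecting")


@dataclass(frozen=True)
class CrescentTruth:
    """Generative parameters of a cortical crescent.

    center_position and coverage are in percent perimeter; amplitude,
    background and noise_sd are intensity AU. coverage == 0 means no crescent
    regardless of amplitude.
    """

    center_position: float
    coverage: float
    amplitude: float
    background: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("center_position", "coverage", "amplitude", "background", "noise_sd"):
            _finite(name, getattr(self, name))
        if not 0 <= self.center_position < 100:
            raise ValueError("center_position must be in [0, 100)")
        if not 0 <= self.coverage <= 100:
            raise ValueError("coverage must be in [0, 100]")
        if self.amplitude < 0 or self.background < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, background and noise_sd must be >= 0")


@dataclass(frozen=True)
class AngleSimParams:
    """Mixture parameters for paired anaphase-onset / +1 hr division angles.

    ``w_planar/w_oblique/w_perp`` set the t=0 orientation-bin mixture;
    obliques then remain oblique with ``p_stay_oblique`` or correct, choosing
    perpendicular with ``p_perp_given_oblique``; non-obliques persist with
    truncated-Gaussian jitter of sd ``jitter_sd`` degrees.
    """

    n: int
    w_planar: float = 1 / 3
    w_oblique: float = 1 / 3
    w_perp: float = 1 / 3
    p_perp_given_oblique: float = 0.5
    p_stay_oblique: float = 0.05
    jitter_sd: float = 5.0
    seed: int = 0
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        w = (self.w_planar, self.w_oblique, self.w_perp)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        for name in ("p_perp_given_oblique", "p_stay_oblique"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class CloneSimParams:
    """Class frequencies for two-cell lineage-tracing clones."""

    n: int
    p_scd: float = 1 / 3
    p_acd: float = 1 / 3
    p_delam: float = 1 / 3
    seed: int = 0
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        p = (self.p_scd, self.p_acd, self.p_delam)
        if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("class probabilities must be nonnegative and sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated image or table row set."""

    identifier: str
    params: Any
    labels: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict, is_dataclass

        params = asdict(self.params) if is_dataclass(self.params) else self.params
        return {"identifier": self.identifier, "params": params, "labels": self.labels}


@dataclass
class LinescanProfile:
    """A 100-point perimeter-normalized cortical intensity profile.

    positions run 0, 1, ..., 99 percent perimeter starting at the basal-most
    point; sample 99 is circularly adjacent to sample 0. ``background`` is the
    cytoplasmic estimate used for subtraction.
    """

    intensities: np.ndarray
    background: float = 0.0
    background_subtracted: bool = False
    cell_id: str = ""
    reporter_status: str = "NA"
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        if v.shape != (N_LINESCAN_POINTS,):
            raise ValueError(f"expected exactly {N_LINESCAN_POINTS} intensity samples, got {v.shape}")
        if not np.all(np.isfinite(v)):
            bad = np.where(~np.isfinite(v))[0].tolist()
            raise ValueError(f"non-finite intensities at sample indices {bad}")
        self.intensities = v
        if self.positions is None:
            self.positions = np.arange(N_LINESCAN_POINTS, dtype=float)
        else:
            p = np.asarray(self.positions, dtype=float)
            if p.shape != (N_LINESCAN_POINTS,) or np.any(np.diff(p) <= 0):
                raise ValueError("positions must be 100 strictly increasing samples")
            self.positions = p
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.reporter_status not in ("RFP+", "RFP-", "NA"):
            raise ValueError("reporter_status must be one of 'RFP+', 'RFP-', 'NA'")


@dataclass(frozen=True)
class CrescentMetrics:
    """The four crescent scores at a stated threshold.

    max_fi : highest background-subtracted value of the full linescan (AU).
    integrated_fi : trapezoidal area under the threshold-subtracted curve over
        the longest contiguous supra-threshold run (AU · % perimeter).
    coverage : perimeter span of that run, percent.
    position : circular midpoint of the run, percent, or None when coverage=0.
    """

    max_fi: float
    integrated_fi: float
    coverage: float
    position: float | None
    threshold: float
    cell_id: str = ""
    reporter_status: str = "NA"

    def __post_init__(self) -> None:
        if self.integrated_fi < 0:
            raise ValueError("integrated_fi must be >= 0")
        if not 0 <= self.coverage <= 100:
            raise ValueError("coverage must be in [0, 100]")
        if (self.position is None) != (self.coverage == 0):
            raise ValueError("position must be defined exactly when coverage > 0")


@dataclass(frozen=True)
class DivisionRecord:
    """One terminal division angle from fixed tissue or live imaging."""

    cell_id: str
    embryo_id: str
    genotype: str
    stage: str
    angle: float
    reporter_status: str = "NA"

    def __post_init__(self) -> None:
        if not self.cell_id or not self.embryo_id:
            raise ValueError("cell_id and embryo_id must be non-empty")
        if self.stage not in ("anaphase", "telophase", "fixed_terminal"):
            raise ValueError("stage must be anaphase, telophase or fixed_terminal")
        if not 0 <= _finite("angle", self.angle) <= 90:
            raise ValueError(f"angle must be in [0, 90], got {self.angle}")


@dataclass(frozen=True)
class PairedDivision:
    """Anaphase-onset (t=0) and +1 hr angles for one live-imaged division."""

    cell_id: str
    genotype: str
    angle_t0: float
    angle_t60: float

    def __post_init__(self) -> None:
        for name in ("angle_t0", "angle_t60"):
            a = _finite(name, getattr(self, name))
            if not 0 <= a <= 90:
                raise ValueError(f"{name} must be in [0, 90], got {a}")


@dataclass(frozen=True)
class CloneRecord:
    """Basal/suprabasal composition of a lineage-traced clone."""

    clone_id: str
    embryo_id: str
    genotype: str
    n_basal: int
    n_suprabasal: int
    first_spinous: bool = False

    def __post_init__(self) -> None:
        if self.n_basal < 0 or self.n_suprabasal < 0:
            raise ValueError("cell counts must be >= 0")
        if self.n_basal + self.n_suprabasal < 1:
            raise ValueError("a clone must contain at least one cell")


@dataclass(frozen=True)
class TissueMeasurement:
    """Suprabasal (K10+) thickness as mask area / basement length."""

    k10_area: float
    basement_length: float
    threshold_method: str
    threshold_value: float

    def __post_init__(self) -> None:
        if self.basement_length <= 0:
            raise ValueError("basement_length must be > 0")
        if self.k10_area < 0:
            raise ValueError("k10_area must be >= 0")

    @property
    def thickness(self) -> float:
        return self.k10_area / self.basement_length
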