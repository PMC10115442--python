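"""Clonal fate classification and spinous-layer thickness measurement.

Two-cell lineage-traced clones are classified by basal/suprabasal
composition: symmetric cell division (SCD, two basal daughters), asymmetric
cell division (ACD, one basal + one suprabasal), or delamination (a single
suprabasal cell that entered the first spinous layer without dividing). All
other compositions fall outside the two-cell tracing rubric and are reported
as excluded with a reason, never silently dropped. Differentiation is
additionally indexed by spinous (K10+) layer thickness: the thresholded K10
mask area divided by the basement-membrane length.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .types import CloneRecord, TissueMeasurement

__all__ = ["classify_clone", "classify_clones", "fate_proportions", "measure_thickness"]

FATE_CLASSES = ("SCD", "ACD", "delamination", "excluded")


def classify_clone(record: CloneRecord) -> tuple[str, str]:
    """Fate class of one clone; returns ``(class, reason)`` where reason is
    empty for the three countable classes."""
    nb, ns = record.n_basal, record.n_suprabasal
    if (nb, ns) == (2, 0):
        return "SCD", ""
    if (nb, ns) == (1, 1):
        return "ACD", ""
    if (nb, ns) == (0, 1):
        if record.first_spinous:
            return "delamination", ""
        return "excluded", "single suprabasal cell not in first spinous layer"
    if nb + ns > 2:
        return "excluded", f"clone of {nb + ns} cells exceeds the two-cell rubric (>1 division)"
    return "excluded", f"composition ({nb} basal, {ns} suprabasal) outside the rubric"


def _clones_frame(clones: Iterable[CloneRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(clones, pd.DataFrame):
        df = clones.copy()
        required = {"clone_id", "genotype", "n_basal", "n_suprabasal", "first_spinous"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return df
    return pd.DataFrame(
        [{"clone_id": c.clone_id, "embryo_id": c.embryo_id, "genotype": c.genotype,
          "n_basal": c.n_basal, "n_suprabasal": c.n_suprabasal,
          "first_spinous": c.first_spinous} for c in clones]
    )


def classify_clones(clones: Iterable[CloneRecord] | pd.DataFrame) -> pd.DataFrame:
    """Classify a clone table; adds ``fate_class`` and ``exclusion_reason``."""
    df = _clones_frame(clones)
    cls, reasons = [], []
    for nb, ns, fs in zip(df["n_basal"], df["n_suprabasal"], df["first_spinous"]):
        c, r = classify_clone(CloneRecord(clone_id="x", embryo_id="x", genotype="x",
                                          n_basal=int(nb), n_suprabasal=int(ns),
                                          first_spinous=bool(fs)))
        cls.append(c)
        reasons.append(r)
    out = df.copy()
    out["fate_class"] = cls
    out["exclusion_reason"] = reasons
    return out


def fate_proportions(clones: Iterable[CloneRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-genotype fate fractions with both denominators of interest.

    Division clones are SCD+ACD; differentiative clones are ACD+delamination.
    Emits, per genotype: raw counts per class (including excluded, so counts
    reconcile with the input), SCD and ACD fractions among division clones,
    and ACD and delamination fractions among differentiative clones.
    """
    df = classify_clones(clones)
    rows = []
    for g, sub in df.groupby("genotype", sort=True):
        counts = {c: int((sub["fate_class"] == c).sum()) for c in FATE_CLASSES}
        n_div = counts["SCD"] + counts["ACD"]
        n_diff = counts["ACD"] + counts["delamination"]
        rows.append({
            "genotype": g,
            **{f"n_{c.lower()}": v for c, v in counts.items()},
            "n_total": len(sub),
            "scd_fraction_of_divisions": counts["SCD"] / n_div if n_div else np.nan,
            "acd_fraction_of_divisions": counts["ACD"] / n_div if n_div else np.nan,
            "acd_fraction_of_differentiative": counts["ACD"] / n_diff if n_diff else np.nan,
            "delam_fraction_of_differentiative": counts["delamination"] / n_diff if n_diff else np.nan,
        })
    return pd.DataFrame(rows)


def measure_thickness(
    k10_channel: np.ndarray,
    basement_polyline: np.ndarray,
    pixel_size: float = 1.0,
    threshold: str | float = "otsu",
) -> TissueMeasurement:
    """Spinous-layer thickness from a K10 image and a basement polyline.

    The K10 channel is binarized (Otsu by default, or a fixed AU value) and
    the suprabasal mask area (in square microns) is divided by the polyline
    arc length (microns). The polyline is given in (row, col) pixel
    coordinates. An image with no signal yields thickness 0.
    """
    img = np.asarray(k10_channel, dtype=float)
    poly = np.asarray(basement_polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
        raise ValueError("basement polyline needs at least two (row, col) points")
    seg = np.diff(poly, axis=0)
    length_um = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) * pixel_size
    if length_um <= 0:
        raise ValueError("basement polyline has zero length")

    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        if img.max() == img.min():  # flat image: nothing above threshold
            mask = np.zeros_like(img, dtype=bool)
            tval = float(img.max())
        else:
            tval = float(threshold_otsu(img))
            mask = img > tval
        method = "otsu"
    else:
        tval = float(threshold)
        mask = img > tval
        method = "fixed"

    area_um2 = float(mask.sum()) * pixel_size**2
    return TissueMeasurement(k10_area=area_um2, basement_length=length_um,
                             threshold_method=method, threshold_value=tval)
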