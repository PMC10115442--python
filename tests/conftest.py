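import numpy as np
import pytest

from epiorient import synthetic
from epiorient.types import CrescentTruth, LinescanProfile


@pytest.fixture(scope="session")
def circle_geom():
    return synthetic.circle_geometry()


def make_profile(values, background=0.0, subtracted=True, **kw):
    """A LinescanProfile from a raw 100-vector."""
    return LinescanProfile(
        intensities=np.asarray(values, dtype=float),
        background=background,
        background_subtracted=subtracted,
        **kw,
    )


def pulse_profile(start, stop, height, base=0.0):
    """Rectangular pulse: samples at positions start..stop inclusive = height."""
    v = np.full(100, base)
    idx = np.arange(start, stop + 1) % 100
    v[idx] = height
    return make_profile(v)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def render_and_quantify(geom, truth: CrescentTruth, seed=0, window="rect", threshold=20.0):
    """Full image-to-metrics round trip used by recovery tests."""
    from epiorient import cortical

    img, mask, _ = synthetic.generate_cell_image(geom, truth, seed=seed, window=window)
    contour = cortical.extract_perimeter(mask, geom.basement_line)
    prof = cortical.sample_linescan(img, contour, boundary_mask=mask)
    return cortical.compute_crescent_metrics(prof, threshold=threshold)
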