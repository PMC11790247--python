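"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from aismorph import synthetic
from aismorph.morphometry import MorphometryConfig
from aismorph.straighten import StraightenedProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def morph_cfg():
    return MorphometryConfig()


def make_profile(values, pixel_size=0.21, labels=None):
    """StraightenedProfile from raw per-channel value rows."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    norm = np.full_like(values, np.nan)
    flags = []
    for c in range(values.shape[0]):
        lo, hi = np.percentile(values[c], 1), values[c].max()
        if hi - lo <= 1e-12:
            flags.append(f"no-signal:ch{c}")
        else:
            norm[c] = np.clip((values[c] - lo) / (hi - lo), 0, 1)
    labels = labels or [f"ch{c}" for c in range(values.shape[0])]
    return StraightenedProfile(
        positions_um=np.arange(values.shape[1]) * pixel_size,
        intensity=values, normalized=norm, pixel_size=pixel_size,
        half_width_um=0.63, channel_labels=labels, flags=tuple(flags))


def make_normalized_profile(values, pixel_size=0.21, labels=None):
    """Profile whose *normalized* values are taken verbatim (the extent
    rule operates on already-normalized fluorescence)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = labels or [f"ch{c}" for c in range(values.shape[0])]
    return StraightenedProfile(
        positions_um=np.arange(values.shape[1]) * pixel_size,
        intensity=values.copy(), normalized=values, pixel_size=pixel_size,
        half_width_um=0.63, channel_labels=labels)


@pytest.fixture
def noiseless_ais():
    """A sharp-edged, blur-free, noise-free rendered AIS (truth 10.5 µm)."""
    gt = synthetic.AISGroundTruth(true_length=10.5, psf_sigma=0.0,
                                  noise_sd=0.0, edge_rise_um=0.0)
    image, roi, record = synthetic.generate_ais_image(gt, seed=42)
    return image, roi, record, gt
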