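"""Shared fixtures: a small sensor profile and reusable synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

import hyperscanner as hs
from hyperscanner.synthetic_scene import MINI, mini_layout

MINI_LAYOUT = mini_layout()
MINI_PANEL = (4, 36)
MINI_LINES = 84


def make_mini_scene(effects_by_tray=(None, None), day=20, noise_sd=0.05, seed=0,
                    **kwargs):
    """One small paired scan: two trays + panel strip."""
    return hs.generate_scene(
        MINI, MINI_LAYOUT, effects_by_tray=list(effects_by_tray), day=day,
        noise_sd=noise_sd, seed=seed, n_lines=MINI_LINES,
        panel_columns=MINI_PANEL, **kwargs,
    )


def calibrate_scene(cube, truth, cv_threshold=0.02):
    """Standard calibration chain used across tests."""
    white = hs.select_white_line(cube, truth.panel_columns)
    cv = hs.along_track_cv(cube, truth.panel_columns)
    mask = hs.select_bands(cv, cube.wavelengths, cv_threshold)
    refl = hs.to_reflectance(cube, white)
    return refl, mask, white


def tray_samples(cube, truth, layout=MINI_LAYOUT, n=300, seed=0, names=("a", "b")):
    """Calibrate, segment and draw one sample per tray of a paired scan."""
    refl, mask, _ = calibrate_scene(cube, truth)
    px = hs.extract_plant_pixels(refl, mask, panel_columns=truth.panel_columns)
    out = []
    for tray, name in enumerate(names):
        tp = hs.restrict_to_columns(px, layout.tray_sample_bounds(tray))
        out.append(hs.sample_pixels(tp, refl, n=n, seed=seed + tray, mask=mask,
                                    treatment=name))
    return out, mask


@pytest.fixture(scope="session")
def mini_scene():
    """Noisy control/control mini scene shared by read-only tests."""
    return make_mini_scene(seed=42)


@pytest.fixture(scope="session")
def mini_clean_scene():
    """Noise-free, flat-illumination mini scene (exact forward model)."""
    return make_mini_scene(noise_sd=0.0, seed=7, flat_illumination=True,
                           jitter_sd=0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
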