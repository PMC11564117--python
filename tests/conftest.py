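"""Shared fixtures and independent oracles for the test suite.

The bilinear sampler and line-amplitude oracle here are written from
scratch (no scipy.ndimage) so they stay independent of the package's
profiling path.
"""

from __future__ import annotations

import numpy as np
import pytest

from beadrim import BeadSpec, ProfileConfig, SceneConfig, generate_scene


def bilinear(image: np.ndarray, r: float, c: float) -> float:
    """Hand-rolled bilinear interpolation at (row, col)."""
    h, w = image.shape
    r0 = min(max(int(np.floor(r)), 0), h - 2)
    c0 = min(max(int(np.floor(c)), 0), w - 2)
    fr, fc = r - r0, c - c0
    return float((1 - fr) * (1 - fc) * image[r0, c0]
                 + (1 - fr) * fc * image[r0, c0 + 1]
                 + fr * (1 - fc) * image[r0 + 1, c0]
                 + fr * fc * image[r0 + 1, c0 + 1])


def oracle_line_amplitude(image: np.ndarray, center_rc, radius: float,
                          angle: float, config: ProfileConfig,
                          exclusion_mask: np.ndarray | None = None,
                          refine: int = 10) -> float:
    """Brute-force max-min along one radial line at ``refine``-times finer
    sampling, applying the same truncation rule as the pipeline."""
    h, w = image.shape
    cy, cx = center_rc
    step = config.step_px / refine
    distances = np.arange(0.0, config.length_factor * radius + step * 1e-6,
                          step)
    own_clear = radius + config.own_margin_px
    vals = []
    for d in distances:
        rr = cy + d * np.sin(angle)
        cc = cx + d * np.cos(angle)
        if not (0 <= rr <= h - 1 and 0 <= cc <= w - 1):
            break
        if exclusion_mask is not None and d > own_clear:
            if exclusion_mask[int(round(rr)), int(round(cc))]:
                break
        vals.append(bilinear(image, rr, cc))
    return max(vals) - min(vals) if vals else 0.0


def noiseless_config(**kwargs) -> SceneConfig:
    base = dict(image_shape=(256, 256), n_beads=4, background_level=100.0,
                gaussian_noise_sd=0.0, poisson_scale=0.0,
                min_separation=60.0, radius_distribution=(20.0, 3.0),
                interior_level=0.0, seed=0)
    base.update(kwargs)
    return SceneConfig(**base)


@pytest.fixture
def single_bead_scene():
    """One noiseless bead at an integer center: the cleanest geometry for
    amplitude checks (ring peak 100 above flat background)."""
    cfg = noiseless_config(image_shape=(128, 128), n_beads=1)
    bead = BeadSpec(center_rc=(64.0, 64.0), radius=20.0, rim_amplitude=100.0,
                    rim_sigma=2.0, interior_level=0.0)
    return generate_scene(cfg, bead_overrides=[bead])


@pytest.fixture
def blank_scene():
    return generate_scene(noiseless_config(n_beads=0, background_level=10.0,
                                           image_shape=(64, 64)))
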