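"""Synthetic bead-field scenes with known ground truth.

Emulates confocal equatorial sections of ligand-coated agarose beads in a
flat well: each bead appears as a bright ring (recruited fluorescent prey
concentrated at the bead surface) with a dim interior, on a flat background.
Detector noise is modeled as Poisson shot noise followed by additive
Gaussian read noise.

Every scene carries its generating parameters (per-bead center, radius,
rim amplitude) and a truth label image, so downstream segmentation,
profiling, QC and statistics can each be tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BeadSpec",
    "SceneConfig",
    "SyntheticScene",
    "PlacementError",
    "generate_scene",
    "generate_multichannel_scene",
    "generate_dose_series",
    "dose_response_amplitude",
    "render_noiseless",
    "render_truth_labels",
    "ring_integral",
]


class PlacementError(RuntimeError):
    """Raised when a bead center satisfying the separation constraint
    cannot be placed within the retry budget."""


@dataclass(frozen=True)
class BeadSpec:
    """Ground-truth parameters of a single bead.

    The bead body is a disk of ``radius`` pixels filled at
    ``interior_level`` gray values above background; the recruited signal
    is a ring with Gaussian radial cross-section of width ``rim_sigma``
    peaking at ``rim_amplitude`` gray values on the circle of radius
    ``radius``.  ``defect_fraction`` zeroes a contiguous arc of the ring
    (starting at ``defect_start_rad``), modeling unevenly coated beads.

    Coordinates are (row, col), 0-based; pixel (i, j) has its center at
    continuous coordinate (i, j).
    """

    center_rc: tuple[float, float]
    radius: float
    rim_amplitude: float = 100.0
    rim_sigma: float = 2.0
    interior_level: float = 10.0
    defect_fraction: float = 0.0
    defect_start_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 3:
            raise ValueError(f"bead radius must be >= 3 px, got {self.radius}")
        if self.rim_sigma <= 0:
            raise ValueError("rim_sigma must be > 0")
        if self.rim_amplitude < 0:
            raise ValueError("rim_amplitude must be >= 0")
        if not 0 <= self.defect_fraction < 1:
            raise ValueError("defect_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a whole synthetic field of beads.

    ``poisson_scale`` is the photon count corresponding to one gray value;
    0 disables shot noise.  ``min_separation`` is the minimum distance in
    pixels between bead centers and may be smaller than the sum of two
    radii to produce touching beads.  Rim appearance parameters apply to
    all randomly placed beads; per-bead variation is available through
    explicit ``BeadSpec`` overrides in :func:`generate_scene`.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_beads: int = 12
    background_level: float = 100.0
    gaussian_noise_sd: float = 5.0
    poisson_scale: float = 0.5
    min_separation: float = 50.0
    radius_distribution: tuple[float, float] = (20.0, 3.0)
    seed: int = 0
    rim_amplitude: float = 100.0
    rim_sigma: float = 2.0
    interior_level: float = 10.0
    defect_fraction: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 64 or w < 64:
            raise ValueError("image_shape sides must be >= 64")
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        for name in ("background_level", "gaussian_noise_sd", "poisson_scale",
                     "min_separation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticScene:
    """A rendered scene together with its full ground truth."""

    config: SceneConfig
    beads: list[BeadSpec]
    image: np.ndarray
    truth_labels: np.ndarray

    def truth_table(self):
        """Per-bead ground truth as a pandas DataFrame (1-based bead id
        matching ``truth_labels``)."""
        import pandas as pd

        rows = [
            {
                "bead_id": i + 1,
                "center_row": b.center_rc[0],
                "center_col": b.center_rc[1],
                "radius": b.radius,
                "rim_amplitude": b.rim_amplitude,
                "rim_sigma": b.rim_sigma,
                "interior_level": b.interior_level,
                "defect_fraction": b.defect_fraction,
            }
            for i, b in enumerate(self.beads)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "bead_id", "center_row", "center_col", "radius",
                "rim_amplitude", "rim_sigma", "interior_level",
                "defect_fraction",
            ],
        )


def _bead_window(shape, bead: BeadSpec):
    """Index window covering the bead's support (ring tail included)."""
    h, w = shape
    reach = bead.radius + 4.0 * bead.rim_sigma + 1.0
    r0 = max(int(np.floor(bead.center_rc[0] - reach)), 0)
    r1 = min(int(np.ceil(bead.center_rc[0] + reach)) + 1, h)
    c0 = max(int(np.floor(bead.center_rc[1] - reach)), 0)
    c1 = min(int(np.ceil(bead.center_rc[1] + reach)) + 1, w)
    return slice(r0, r1), slice(c0, c1)


def render_noiseless(shape: tuple[int, int], background_level: float,
                     beads: Sequence[BeadSpec]) -> np.ndarray:
    """Render the noise-free image: background plus, per bead, an interior
    disk and a Gaussian ring peaking at the bead's circle, with defect
    arcs zeroed."""
    img = np.full(shape, float(background_level))
    for bead in beads:
        rs, cs = _bead_window(shape, bead)
        ii, jj = np.mgrid[rs, cs]
        dr = ii - bead.center_rc[0]
        dc = jj - bead.center_rc[1]
        d = np.hypot(dr, dc)
        ring = bead.rim_amplitude * np.exp(
            -((d - bead.radius) ** 2) / (2.0 * bead.rim_sigma ** 2)
        )
        if bead.defect_fraction > 0:
            theta = np.mod(np.arctan2(dr, dc) - bead.defect_start_rad,
                           2.0 * np.pi)
            ring[theta < bead.defect_fraction * 2.0 * np.pi] = 0.0
        img[rs, cs] += ring
        img[rs, cs] += np.where(d <= bead.radius, bead.interior_level, 0.0)
    return img


def render_truth_labels(shape: tuple[int, int],
                        beads: Sequence[BeadSpec]) -> np.ndarray:
    """Label image where pixel value k marks bead k's disk (1-based).

    Where disks overlap, the pixel goes to the bead whose center is
    closest relative to its radius."""
    labels = np.zeros(shape, dtype=np.uint16)
    claim = np.full(shape, np.inf)
    for k, bead in enumerate(beads, start=1):
        rs, cs = _bead_window(shape, bead)
        ii, jj = np.mgrid[rs, cs]
        d = np.hypot(ii - bead.center_rc[0], jj - bead.center_rc[1])
        rel = d / bead.radius
        take = (d <= bead.radius) & (rel < claim[rs, cs])
        labels[rs, cs][take] = k
        claim[rs, cs][take] = rel[take]
    return labels


def ring_integral(bead: BeadSpec) -> float:
    """Closed-form integral of one bead's noiseless signal above
    background over the full plane: ring (2*pi*R*A*sigma*sqrt(2*pi),
    reduced by the defect arc) plus interior disk."""
    ring = (2.0 * np.pi * bead.radius * bead.rim_amplitude
            * bead.rim_sigma * np.sqrt(2.0 * np.pi))
    ring *= 1.0 - bead.defect_fraction
    disk = np.pi * bead.radius ** 2 * bead.interior_level
    return ring + disk


def _place_beads(config: SceneConfig, rng: np.random.Generator) -> list[BeadSpec]:
    h, w = config.image_shape
    mu, sd = config.radius_distribution
    centers: list[tuple[float, float]] = []
    beads: list[BeadSpec] = []
    max_tries = 1000
    for k in range(config.n_beads):
        radius = float(np.clip(rng.normal(mu, sd), 3.0, None))
        # keep the full profiling reach (1.5 R) plus ring tail inside the image
        margin = 1.6 * radius + 4.0 * config.rim_sigma
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"bead {k}: radius {radius:.1f} px does not fit in "
                f"image of shape {config.image_shape}"
            )
        for _ in range(max_tries):
            r = rng.uniform(margin, h - 1 - margin)
            c = rng.uniform(margin, w - 1 - margin)
            if all(np.hypot(r - cr, c - cc) >= config.min_separation
                   for cr, cc in centers):
                break
        else:
            raise PlacementError(
                f"bead {k}: no center at min_separation="
                f"{config.min_separation} px after {max_tries} tries"
            )
        centers.append((r, c))
        beads.append(BeadSpec(
            center_rc=(r, c),
            radius=radius,
            rim_amplitude=config.rim_amplitude,
            rim_sigma=config.rim_sigma,
            interior_level=config.interior_level,
            defect_fraction=config.defect_fraction,
            defect_start_rad=float(rng.uniform(0.0, 2.0 * np.pi)),
        ))
    return beads


def _apply_noise(noiseless: np.ndarray, config: SceneConfig,
                 rng: np.random.Generator) -> np.ndarray:
    img = noiseless
    if config.poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * config.poisson_scale)
        img = img / config.poisson_scale
    if config.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, config.gaussian_noise_sd, img.shape)
    return np.asarray(img, dtype=float)


def _check_overrides(config: SceneConfig, beads: Sequence[BeadSpec]) -> None:
    h, w = config.image_shape
    for i, b in enumerate(beads):
        r, c = b.center_rc
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(
                f"override bead {i} center {b.center_rc} outside image "
                f"bounds {config.image_shape}"
            )


def generate_scene(config: SceneConfig,
                   bead_overrides: Sequence[BeadSpec] | None = None,
                   ) -> SyntheticScene:
    """Generate one single-channel scene.

    When ``bead_overrides`` is given those exact beads are rendered
    (``config.n_beads`` and placement parameters are ignored); otherwise
    beads are placed randomly subject to ``min_separation``.  Identical
    config and seed yield a bit-identical scene.
    """
    rng = np.random.default_rng(config.seed)
    if bead_overrides is not None:
        beads = list(bead_overrides)
        _check_overrides(config, beads)
    else:
        beads = _place_beads(config, rng)
    noiseless = render_noiseless(config.image_shape, config.background_level,
                                 beads)
    image = _apply_noise(noiseless, config, rng)
    labels = render_truth_labels(config.image_shape, beads)
    return SyntheticScene(config=config, beads=beads, image=image,
                          truth_labels=labels)


def generate_multichannel_scene(
    config: SceneConfig,
    channel_rim_amplitudes: Mapping[str, float],
    bead_overrides: Sequence[BeadSpec] | None = None,
) -> tuple[dict[str, np.ndarray], list[BeadSpec], np.ndarray]:
    """Render several channels sharing one bead geometry.

    Each channel re-renders the same beads with its own rim amplitude and
    its own independent noise draw.  Returns (channel -> image, beads,
    truth_labels).
    """
    rng = np.random.default_rng(config.seed)
    if bead_overrides is not None:
        beads = list(bead_overrides)
        _check_overrides(config, beads)
    else:
        beads = _place_beads(config, rng)
    labels = render_truth_labels(config.image_shape, beads)
    channels: dict[str, np.ndarray] = {}
    for name, amp in channel_rim_amplitudes.items():
        chan_beads = [replace(b, rim_amplitude=float(amp)) for b in beads]
        noiseless = render_noiseless(config.image_shape,
                                     config.background_level, chan_beads)
        channels[name] = _apply_noise(noiseless, config, rng)
    return channels, beads, labels


def dose_response_amplitude(dose: float, max_amplitude: float,
                            ic50: float) -> float:
    """Hyperbolic single-site competition surrogate:
    amplitude = max / (1 + dose/ic50).  A demo model for titration
    scenarios, not a fitted binding isotherm."""
    return max_amplitude / (1.0 + dose / ic50)


def generate_dose_series(
    base: SceneConfig,
    doses: Sequence[float],
    amplitude_model: tuple[float, float],
) -> list[tuple[float, SyntheticScene]]:
    """Generate one scene per competitor dose.

    ``amplitude_model`` is (max_amplitude, ic50) in the dose's units; the
    rim amplitude of every bead in the scene for dose d is
    max_amplitude / (1 + d/ic50).  Scenes share all other distributional
    parameters; each dose gets a distinct deterministic seed derived from
    the base seed.
    """
    if len(doses) == 0:
        raise ValueError("doses must be a non-empty sequence")
    if any(d <= 0 for d in doses):
        raise ValueError("all doses must be > 0")
    max_amplitude, ic50 = amplitude_model
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    out = []
    for i, dose in enumerate(doses):
        cfg = replace(
            base,
            rim_amplitude=dose_response_amplitude(dose, max_amplitude, ic50),
            seed=base.seed + i,
        )
        out.append((float(dose), generate_scene(cfg)))
    return out


def scene_config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    d["image_shape"] = list(config.image_shape)
    d["radius_distribution"] = list(config.radius_distribution)
    return d


def scene_config_from_dict(d: Mapping) -> SceneConfig:
    d = dict(d)
    if "image_shape" in d:
        d["image_shape"] = tuple(d["image_shape"])
    if "radius_distribution" in d:
        d["radius_distribution"] = tuple(d["radius_distribution"])
    return SceneConfig(**d)
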