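"""Radial line-profile measurement of bead rim signal.

For each fitted bead circle, a fixed number of evenly spaced radial lines
is drawn from the center outward past the circle border, each sampled by
bilinear interpolation at sub-pixel steps.  The rim signal of a line is
the difference between its maximum and minimum gray values, so a bright
ring on a darker interior/background scores its peak-to-baseline contrast
regardless of absolute offset.  A bead is summarized by the mean and
sample standard deviation of its per-line amplitudes.

Lines are truncated where they would enter a neighboring bead (via the
combined exclusion mask) or leave the image; raw intensities are used,
with no smoothing before the min/max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import BeadROI

__all__ = [
    "ProfileConfig",
    "LineProfile",
    "BeadMeasurement",
    "DegenerateROIError",
    "sample_radial_profiles",
    "summarize_bead",
]


class DegenerateROIError(ValueError):
    """ROI too small to hold a meaningful radial profile."""


def _bilinear(image: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (rr, cc), written in incremental form
    (value = corner + fractional differences) so that constant images
    interpolate exactly, with no floating-point weight residue."""
    h, w = image.shape
    r0 = np.clip(np.floor(rr).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(cc).astype(int), 0, w - 2)
    fr = rr - r0
    fc = cc - c0
    p00 = image[r0, c0]
    p01 = image[r0, c0 + 1]
    p10 = image[r0 + 1, c0]
    p11 = image[r0 + 1, c0 + 1]
    return p00 + fr * (p10 - p00) + fc * (p01 - p00) \
        + fr * fc * (p11 - p10 - p01 + p00)


@dataclass(frozen=True)
class ProfileConfig:
    """Line-profile sampling parameters.

    ``length_factor`` is the line length as a multiple of the fitted
    radius, so lines end in the inter-bead space just outside the rim.
    ``own_margin_px`` must match the exclusion-mask dilation margin: a
    bead never truncates its own lines, so samples closer than
    radius + own_margin_px to the bead's own center ignore the mask.
    """

    n_lines: int = 20
    length_factor: float = 1.5
    step_px: float = 0.5
    min_valid_samples: int = 5
    start_angle_rad: float = 0.0
    own_margin_px: float = 2.0

    def __post_init__(self) -> None:
        if self.n_lines < 3:
            raise ValueError("n_lines must be >= 3")
        if self.length_factor <= 1:
            raise ValueError("length_factor must be > 1")
        if self.step_px <= 0:
            raise ValueError("step_px must be > 0")


@dataclass
class LineProfile:
    """One radial intensity trace and its max - min amplitude."""

    bead_label: int
    angle_rad: float
    distances: np.ndarray
    intensities: np.ndarray
    amplitude: float
    truncated: bool
    valid: bool


@dataclass
class BeadMeasurement:
    """Per-bead summary over valid line amplitudes.

    ``sd_amplitude`` is the sample SD (ddof=1); a single valid line gets
    sd = 0 and ``low_n`` set.  QC fields are filled by the analysis stage
    except for unmeasurable beads (no valid lines), which are marked
    failed here.
    """

    bead_label: int
    line_amplitudes: list[float] = field(default_factory=list)
    mean_amplitude: float = float("nan")
    sd_amplitude: float = float("nan")
    n_valid_lines: int = 0
    low_n: bool = False
    qc_pass: bool | None = None
    qc_reason: str = ""


def sample_radial_profiles(image: np.ndarray, roi: BeadROI,
                           exclusion_mask: np.ndarray,
                           config: ProfileConfig = ProfileConfig(),
                           ) -> list[LineProfile]:
    """Draw ``config.n_lines`` radial lines for one bead.

    Line k runs at angle start_angle + k*2*pi/n_lines, sampled at
    distances 0, step, ..., length_factor*radius from the fitted center
    with bilinear interpolation.  Sampling stops at the first sample that
    falls inside another bead's exclusion region or outside the image;
    lines keeping fewer than ``min_valid_samples`` samples are invalid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if exclusion_mask.shape != image.shape:
        raise ValueError("exclusion_mask shape must match image shape")
    if roi.radius < 2 * config.step_px:
        raise DegenerateROIError(
            f"bead {roi.label}: radius {roi.radius:.2f} px < "
            f"2*step_px ({2 * config.step_px:.2f})"
        )
    h, w = image.shape
    cy, cx = roi.center_rc
    distances = np.arange(
        0.0, config.length_factor * roi.radius + config.step_px * 1e-6,
        config.step_px,
    )
    # +0.5: nearest-pixel mask lookups may land on the bead's own dilated
    # boundary pixel; the own disk must never truncate its own lines
    own_clear = roi.radius + config.own_margin_px + 0.5
    profiles: list[LineProfile] = []
    for k in range(config.n_lines):
        angle = config.start_angle_rad + 2.0 * np.pi * k / config.n_lines
        rr = cy + distances * np.sin(angle)
        cc = cx + distances * np.cos(angle)
        inside = (rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1)
        # nearest-pixel mask lookup; own disk (plus margin) never truncates
        ri = np.clip(np.rint(rr).astype(int), 0, h - 1)
        ci = np.clip(np.rint(cc).astype(int), 0, w - 1)
        forbidden = exclusion_mask[ri, ci] & (distances > own_clear)
        ok = inside & ~forbidden
        bad = np.flatnonzero(~ok)
        stop = int(bad[0]) if bad.size else len(distances)
        truncated = stop < len(distances)
        dist_kept = distances[:stop]
        if stop == 0:
            profiles.append(LineProfile(roi.label, angle, dist_kept,
                                        np.empty(0), 0.0, True, False))
            continue
        vals = _bilinear(image, rr[:stop], cc[:stop])
        amplitude = float(vals.max() - vals.min())
        valid = stop >= config.min_valid_samples
        profiles.append(LineProfile(roi.label, angle, dist_kept, vals,
                                    amplitude, truncated, valid))
    return profiles


def summarize_bead(profiles: list[LineProfile]) -> BeadMeasurement:
    """Mean and sample SD (ddof=1) over valid-line amplitudes.

    Zero valid lines marks the bead unmeasurable (qc_reason
    "no_valid_lines"); one valid line gets sd = 0 with the low-n flag.
    """
    if not profiles:
        raise ValueError("summarize_bead requires at least one profile")
    label = profiles[0].bead_label
    amps = [p.amplitude for p in profiles if p.valid]
    if len(amps) == 0:
        return BeadMeasurement(bead_label=label, qc_pass=False,
                               qc_reason="no_valid_lines")
    mean = float(np.mean(amps))
    if len(amps) == 1:
        return BeadMeasurement(bead_label=label, line_amplitudes=amps,
                               mean_amplitude=mean, sd_amplitude=0.0,
                               n_valid_lines=1, low_n=True)
    sd = float(np.std(amps, ddof=1))
    return BeadMeasurement(bead_label=label, line_amplitudes=amps,
                           mean_amplitude=mean, sd_amplitude=sd,
                           n_valid_lines=len(amps))
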