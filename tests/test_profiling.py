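"""Radial line profiles: amplitudes, invariances, truncation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadrim import (BeadROI, BeadSpec, DegenerateROIError, ProfileConfig,
                     build_exclusion_mask, generate_scene,
                     sample_radial_profiles, summarize_bead)
from conftest import noiseless_config, oracle_line_amplitude


def roi_at(center=(64.0, 64.0), radius=20.0, label=1):
    return BeadROI(label=label, center_rc=center, radius=radius,
                   touches_edge=False, area_px=int(np.pi * radius ** 2))


def no_mask(shape=(128, 128)):
    return np.zeros(shape, dtype=bool)


class TestSampleRadialProfiles:
    def test_flat_image_gives_zero_amplitudes(self):
        img = np.full((128, 128), 42.0)
        profiles = sample_radial_profiles(img, roi_at(), no_mask())
        assert len(profiles) == 20
        assert all(p.amplitude == 0.0 for p in profiles)
        assert all(p.valid and not p.truncated for p in profiles)

    def test_uniform_ring_amplitude_within_2pct(self, single_bead_scene):
        """Bright ring on a flat background: every line's max-min is the
        rim amplitude, up to bilinear interpolation loss."""
        profiles = sample_radial_profiles(single_bead_scene.image, roi_at(),
                                          no_mask())
        for p in profiles:
            assert p.amplitude == pytest.approx(100.0, rel=0.02)

    def test_additive_offset_invariance_is_exact(self, single_bead_scene):
        base = sample_radial_profiles(single_bead_scene.image, roi_at(),
                                      no_mask())
        shifted = sample_radial_profiles(single_bead_scene.image + 50.0,
                                         roi_at(), no_mask())
        for p, q in zip(base, shifted):
            assert q.amplitude == pytest.approx(p.amplitude, abs=1e-9)

    def test_gain_scales_amplitudes_linearly(self, single_bead_scene):
        base = sample_radial_profiles(single_bead_scene.image, roi_at(),
                                      no_mask())
        scaled = sample_radial_profiles(single_bead_scene.image * 3.0,
                                        roi_at(), no_mask())
        for p, q in zip(base, scaled):
            assert q.amplitude == pytest.approx(3.0 * p.amplitude, rel=1e-12)

    def test_amplitude_matches_stored_intensities_exactly(
            self, single_bead_scene):
        for p in sample_radial_profiles(single_bead_scene.image, roi_at(),
                                        no_mask()):
            assert p.amplitude == p.intensities.max() - p.intensities.min()
            assert p.distances[0] == 0.0
            assert np.all(np.diff(p.distances) > 0)

    def test_oracle_equivalence_10x_finer(self, single_bead_scene):
        """Implementation agrees with a from-scratch brute-force resampling
        at 10x finer step on a noiseless bead."""
        config = ProfileConfig()
        profiles = sample_radial_profiles(single_bead_scene.image, roi_at(),
                                          no_mask(), config)
        for p in profiles:
            ref = oracle_line_amplitude(single_bead_scene.image, (64.0, 64.0),
                                        20.0, p.angle_rad, config)
            assert p.amplitude == pytest.approx(ref, rel=0.02)

    def test_rotation_permutes_amplitudes(self):
        """Rotating the scene by 90 degrees permutes the 20 line angles
        (90 = 5 * 18), leaving the amplitude multiset unchanged up to
        interpolation tolerance."""
        cfg = noiseless_config(image_shape=(129, 129), n_beads=1)
        bead = BeadSpec(center_rc=(64.0, 64.0), radius=20.0,
                        rim_amplitude=100.0, rim_sigma=2.0,
                        interior_level=0.0, defect_fraction=0.3)
        scene = generate_scene(cfg, bead_overrides=[bead])
        rotated = np.rot90(scene.image).copy()
        a = sorted(p.amplitude for p in sample_radial_profiles(
            scene.image, roi_at(), no_mask((129, 129))))
        b = sorted(p.amplitude for p in sample_radial_profiles(
            rotated, roi_at(), no_mask((129, 129))))
        assert np.allclose(a, b, rtol=0.01, atol=0.5)

    def test_truncation_by_neighbor_mask(self):
        cfg = noiseless_config(image_shape=(200, 200))
        beads = [BeadSpec(center_rc=(100.0, 80.0), radius=20.0,
                          interior_level=0.0),
                 BeadSpec(center_rc=(100.0, 125.0), radius=20.0,
                          interior_level=0.0)]
        scene = generate_scene(cfg, bead_overrides=beads)
        rois = [roi_at((100.0, 80.0), 20.0, 1), roi_at((100.0, 125.0), 20.0, 2)]
        mask = build_exclusion_mask(rois, (200, 200), margin_px=2.0)
        profiles = sample_radial_profiles(scene.image, rois[0], mask)
        toward = min(profiles, key=lambda p: abs(p.angle_rad))   # angle 0
        away = min(profiles, key=lambda p: abs(p.angle_rad - np.pi))
        assert toward.truncated
        assert not away.truncated
        # truncated line still ends before the neighbor's dilated circle
        assert toward.distances[-1] <= 45 - 20 - 2 + 0.5
        # a bead never truncates itself: all lines keep the full own radius
        assert all(p.distances[-1] >= 20.0 for p in profiles)

    def test_short_lines_marked_invalid(self):
        cfg = ProfileConfig(min_valid_samples=100)  # longer than any line
        profiles = sample_radial_profiles(np.full((128, 128), 1.0), roi_at(),
                                          no_mask(), cfg)
        assert all(not p.valid for p in profiles)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(DegenerateROIError):
            sample_radial_profiles(np.zeros((64, 64)), roi_at(radius=0.5),
                                   no_mask((64, 64)))

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sample_radial_profiles(np.zeros((64, 64)), roi_at(),
                                   np.zeros((32, 32), dtype=bool))


class TestSummarizeBead:
    def test_constant_amplitudes(self):
        profiles = sample_radial_profiles(np.full((128, 128), 5.0) , roi_at(),
                                          no_mask())
        for p in profiles:
            p.intensities = p.intensities + 0  # keep valid flags
        m = summarize_bead(profiles)
        assert m.mean_amplitude == 0.0 and m.sd_amplitude == 0.0
        assert m.n_valid_lines == 20

    def test_mean_and_sample_sd_closed_form(self):
        """Ten 0s and ten 20s: mean 10, sample SD sqrt(20*100/19)."""
        profiles = _fake_profiles([0.0] * 10 + [20.0] * 10)
        m = summarize_bead(profiles)
        assert m.mean_amplitude == pytest.approx(10.0)
        assert m.sd_amplitude == pytest.approx(np.sqrt(2000.0 / 19.0))
        assert m.sd_amplitude == pytest.approx(10.2598, abs=1e-4)

    def test_single_valid_line_gets_zero_sd_and_low_n_flag(self):
        m = summarize_bead(_fake_profiles([7.0]))
        assert m.mean_amplitude == 7.0
        assert m.sd_amplitude == 0.0
        assert m.low_n

    def test_no_valid_lines_marks_unmeasurable(self):
        profiles = _fake_profiles([1.0, 2.0])
        for p in profiles:
            p.valid = False
        m = summarize_bead(profiles)
        assert m.qc_pass is False
        assert m.qc_reason == "no_valid_lines"
        assert m.n_valid_lines == 0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=40))
    def test_summary_matches_numpy_on_any_amplitudes(self, amps):
        m = summarize_bead(_fake_profiles(amps))
        assert m.mean_amplitude == pytest.approx(np.mean(amps), rel=1e-12,
                                                 abs=1e-9)
        assert m.sd_amplitude == pytest.approx(np.std(amps, ddof=1),
                                               rel=1e-9, abs=1e-9)


def _fake_profiles(amplitudes):
    from beadrim import LineProfile

    return [
        LineProfile(bead_label=1, angle_rad=0.0,
                    distances=np.array([0.0, 0.5]),
                    intensities=np.array([0.0, a]), amplitude=float(a),
                    truncated=False, valid=True)
        for a in amplitudes
    ]
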