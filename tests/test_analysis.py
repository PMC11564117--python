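"""QC rule, control normalization, and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from beadrim import (BeadMeasurement, NormalizationError, StatisticsError,
                     anova_dunnett, dunnett_pvalues, normalize_to_control,
                     qc_filter, significance_stars, welch_ttest)


def meas(mean, sd, label=1, n=20):
    return BeadMeasurement(bead_label=label, line_amplitudes=[mean] * n,
                           mean_amplitude=mean, sd_amplitude=sd,
                           n_valid_lines=n)


class TestQCFilter:
    def test_low_sd_passes(self):
        passed, excluded = qc_filter([meas(10.0, 0.0)])
        assert len(passed) == 1 and not excluded
        assert passed[0].qc_pass is True

    def test_boundary_is_inclusive(self):
        """sd exactly equal to half the mean is excluded."""
        passed, excluded = qc_filter([meas(10.0, 5.0)])
        assert not passed and len(excluded) == 1
        assert excluded[0].qc_reason == "high_sd"

    def test_alternating_amplitudes_excluded(self):
        # ten 0s / ten 20s: sd 10.2598 >= mean/2 = 5
        passed, excluded = qc_filter([meas(10.0, np.sqrt(2000 / 19))])
        assert not passed and excluded[0].qc_reason == "high_sd"

    def test_zero_signal_excluded_with_reason(self):
        _, excluded = qc_filter([meas(0.0, 0.0)])
        assert excluded[0].qc_reason == "zero_signal"

    def test_unmeasurable_bead_stays_excluded(self):
        m = BeadMeasurement(bead_label=3, qc_pass=False,
                            qc_reason="no_valid_lines")
        _, excluded = qc_filter([m])
        assert excluded == [m]

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            qc_filter([meas(10.0, 1.0)], ratio=0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(list(range(12))))
    def test_order_independence(self, order):
        rng = np.random.default_rng(0)
        ms = [meas(float(m), float(s), label=i)
              for i, (m, s) in enumerate(zip(rng.uniform(1, 100, 12),
                                             rng.uniform(0, 60, 12)))]
        ref = {m.bead_label for m in qc_filter(ms)[0]}
        got = {m.bead_label for m in qc_filter([ms[i] for i in order])[0]}
        assert got == ref


class TestNormalization:
    def test_forced_arithmetic(self):
        out = normalize_to_control({"ctrl": [10.0, 10.0],
                                    "treat": [20.0, 30.0]}, "ctrl")
        assert list(out["treat"]) == [2.0, 3.0]
        assert np.mean(out["ctrl"]) == 1.0

    def test_control_mean_exactly_one_even_with_spread(self):
        vals = [3.0, 9.0, 17.0, 4.5]
        out = normalize_to_control({"ctrl": vals}, "ctrl")
        assert np.mean(out["ctrl"]) == pytest.approx(1.0, abs=1e-15)

    def test_global_gain_invariance(self):
        groups = {"ctrl": [10.0, 14.0], "a": [20.0, 30.0]}
        scaled = {k: [3.0 * v for v in vals] for k, vals in groups.items()}
        a = normalize_to_control(groups, "ctrl")
        b = normalize_to_control(scaled, "ctrl")
        for k in groups:
            assert np.allclose(a[k], b[k], rtol=1e-15)

    def test_missing_or_empty_control_raises(self):
        with pytest.raises(NormalizationError, match="nope"):
            normalize_to_control({"a": [1.0]}, "nope")
        with pytest.raises(NormalizationError, match="ctrl"):
            normalize_to_control({"ctrl": [], "a": [1.0]}, "ctrl")

    def test_commutes_with_qc(self):
        """QC uses raw mean/sd only, so filtering then normalizing equals
        normalizing then filtering."""
        ms = [meas(100.0, 10.0, 1), meas(80.0, 60.0, 2), meas(120.0, 5.0, 3)]
        passed, _ = qc_filter(ms)
        a = normalize_to_control(
            {"c": [m.mean_amplitude for m in passed]}, "c")["c"]
        norm_all = normalize_to_control(
            {"c": [m.mean_amplitude for m in qc_filter(ms)[0]]}, "c")["c"]
        assert np.allclose(sorted(a), sorted(norm_all))


class TestAnovaDunnett:
    def test_identical_groups_give_f_zero_p_one(self):
        groups = {"c": [1.0, 1.0, 1.0], "a": [1.0, 1.0, 1.0],
                  "b": [1.0, 1.0, 1.0]}
        rep = anova_dunnett(groups, control="c")
        assert rep.statistic == 0.0
        assert all(c.p_adjusted == 1.0 for c in rep.comparisons)

    def test_two_groups_reduce_to_pairwise_t(self):
        """With a single treatment, the Dunnett adjustment vanishes and
        the adjusted p equals the unadjusted pooled two-sided t-test."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 0.1, 35), rng.normal(1.05, 0.1, 28)
        rep = anova_dunnett({"ctrl": a, "treat": b}, control="ctrl")
        ref = sps.ttest_ind(b, a, equal_var=True).pvalue
        assert rep.comparisons[0].p_adjusted == pytest.approx(ref, abs=1e-6)

    def test_agrees_with_reference_dunnett_implementation(self):
        """Cross-check the quadrature p-values against an independent
        (Monte-Carlo based) Dunnett implementation."""
        rng = np.random.default_rng(7)
        groups = {"c": rng.normal(1, 0.2, 30), "t1": rng.normal(1.1, 0.2, 25),
                  "t2": rng.normal(0.9, 0.2, 35), "t3": rng.normal(1, 0.2, 20)}
        rep = anova_dunnett(groups, control="c")
        ref = sps.dunnett(*[groups[k] for k in ("t1", "t2", "t3")],
                          control=groups["c"], rng=0)
        assert np.allclose([c.p_adjusted for c in rep.comparisons],
                           ref.pvalue, atol=5e-4)
        # and the F statistic against scipy's one-way ANOVA
        f_ref = sps.f_oneway(*groups.values())
        assert rep.statistic == pytest.approx(f_ref.statistic, rel=1e-10)

    def test_detects_large_effect_at_fig_scale(self):
        """Control N(1, 0.1) vs treatment N(2, 0.1), n=35: adjusted
        p < 1e-4 in at least 99% of seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rep = anova_dunnett({"c": rng.normal(1, 0.1, 35),
                                 "t": rng.normal(2, 0.1, 35)}, control="c")
            hits += rep.comparisons[0].p_adjusted < 1e-4
        assert hits >= 99

    def test_star_coding_matches_reporting_scheme(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"
        assert significance_stars(0.2) == "ns"
        # boundaries are strict
        assert significance_stars(0.05) == "ns"
        assert significance_stars(0.0001) == "***"

    def test_group_validation(self):
        with pytest.raises(StatisticsError, match="n=1"):
            anova_dunnett({"c": [1.0], "t": [1.0, 2.0]}, control="c")
        with pytest.raises(StatisticsError, match="non-finite"):
            anova_dunnett({"c": [1.0, np.nan], "t": [1.0, 2.0]}, control="c")
        with pytest.raises(StatisticsError, match="control"):
            anova_dunnett({"a": [1.0, 2.0], "b": [1.0, 2.0]}, control="c")

    def test_monotone_in_t(self):
        p = dunnett_pvalues([1.0, 2.0, 3.0], [20, 20, 20], 20)
        assert p[0] > p[1] > p[2]


class TestWelch:
    def test_identical_groups(self):
        rep = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == 0.0
        assert rep.comparisons[0].p_adjusted == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        r1 = welch_ttest(a, b)
        r2 = welch_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.comparisons[0].p_adjusted == pytest.approx(
            r2.comparisons[0].p_adjusted)

    def test_power_at_unit_effect(self):
        """N(0,1) vs N(1,1), n=50/group: rejection at alpha=0.05 in at
        least 99% of 200 seeds (closed-form power ~0.999)."""
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rep = welch_ttest(rng.normal(0, 1, 50), rng.normal(1, 1, 50))
            rejections += rep.comparisons[0].p_adjusted < 0.05
        assert rejections >= 198
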