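"""Bead-level QC, control normalization, and group statistics.

QC discards beads whose per-line amplitude SD is equal to or greater than
half the mean amplitude — the signature of unevenly coated, mis-segmented
or artifactual beads.  Passing bead means are divided by the average bead
intensity of a designated control condition to remove inter-experiment
gain differences, and conditions are compared to the control with a
one-way ANOVA followed by Dunnett's many-to-one multiple-comparison test
(or Welch's t-test for two-group designs).

Dunnett adjusted p-values are computed here by deterministic Gaussian
quadrature over the exact equicorrelated multivariate-t representation
(the comparison statistics share the control sample, giving
corr(T_i, T_j) = lambda_i * lambda_j with lambda_i =
sqrt(n_i / (n_i + n_0))).  This avoids Monte-Carlo integration error and
makes reruns bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import stats

from .profiling import BeadMeasurement

__all__ = [
    "ConditionResult",
    "Comparison",
    "StatsReport",
    "NormalizationError",
    "StatisticsError",
    "qc_filter",
    "normalize_to_control",
    "anova_dunnett",
    "welch_ttest",
    "dunnett_pvalues",
    "significance_stars",
]

# significance coding: * < 0.05, ** < 0.005, *** < 0.001, **** < 0.0001
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.005, "**"),
                   (0.05, "*"))


class NormalizationError(ValueError):
    """Control condition missing or without QC-passing beads."""


class StatisticsError(ValueError):
    """Group structure unsuitable for the requested test."""


@dataclass
class ConditionResult:
    """Normalized per-bead values and summary for one condition."""

    condition: str
    replicate: str = ""
    bead_means_raw: list[float] = field(default_factory=list)
    bead_means_normalized: list[float] = field(default_factory=list)
    n_beads_pass: int = 0
    n_beads_excluded: int = 0
    mean_normalized: float = float("nan")
    sd_normalized: float = float("nan")


@dataclass(frozen=True)
class Comparison:
    """One treatment-vs-control comparison."""

    group: str
    estimate: float          # mean difference (group - control)
    statistic: float
    p_adjusted: float
    stars: str


@dataclass
class StatsReport:
    test_name: str
    group_sizes: dict[str, int]
    statistic: float         # F for ANOVA, t for two-sample tests
    df: tuple[float, float]
    comparisons: list[Comparison]
    control: str | None
    alpha: float = 0.05


def significance_stars(p: float) -> str:
    for cut, mark in STAR_THRESHOLDS:
        if p < cut:
            return mark
    return "ns"


def qc_filter(measurements: Sequence[BeadMeasurement],
              ratio: float = 0.5,
              ) -> tuple[list[BeadMeasurement], list[BeadMeasurement]]:
    """Partition beads by the SD rule: excluded iff sd >= ratio * mean
    (inclusive, so zero-signal beads with sd = mean = 0 are excluded too)
    or the bead is unmeasurable.  qc_pass/qc_reason are set in place.

    Order-independent: the verdict depends only on each bead's own
    mean/sd.  Beads failing the SD rule are flagged for optional human
    review rather than corrected automatically.
    """
    if not 0 < ratio <= 1:
        raise ValueError("QC ratio must be in (0, 1]")
    passed: list[BeadMeasurement] = []
    excluded: list[BeadMeasurement] = []
    for m in measurements:
        if m.n_valid_lines == 0:
            m.qc_pass = False
            m.qc_reason = "no_valid_lines"
            excluded.append(m)
        elif m.mean_amplitude == 0 and m.sd_amplitude == 0:
            m.qc_pass = False
            m.qc_reason = "zero_signal"
            excluded.append(m)
        elif m.sd_amplitude >= ratio * m.mean_amplitude:
            m.qc_pass = False
            m.qc_reason = "high_sd"
            excluded.append(m)
        else:
            m.qc_pass = True
            m.qc_reason = ""
            passed.append(m)
    return passed, excluded


def normalize_to_control(bead_means: Mapping[str, Sequence[float]],
                         control: str) -> dict[str, np.ndarray]:
    """Divide every bead mean by the arithmetic mean of the control
    condition's bead means; the control's normalized mean is exactly 1."""
    if control not in bead_means:
        raise NormalizationError(
            f"control condition {control!r} not among conditions "
            f"{sorted(bead_means)}"
        )
    ctrl = np.asarray(bead_means[control], dtype=float)
    if ctrl.size == 0:
        raise NormalizationError(
            f"control condition {control!r} has no QC-passing beads"
        )
    denom = float(ctrl.mean())
    if denom == 0:
        raise NormalizationError(
            f"control condition {control!r} has zero mean intensity"
        )
    return {name: np.asarray(vals, dtype=float) / denom
            for name, vals in bead_means.items()}


def dunnett_pvalues(t_stats: Sequence[float], n_treatments: Sequence[int],
                    n_control: int, df: float | None = None,
                    n_nodes: tuple[int, int] = (160, 128)) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values.

    p_i = 1 - P(max_j |T_j| <= |t_i|) under the global null, where
    (T_1..T_k) is multivariate t with the many-to-one correlation
    structure.  The probability is evaluated by conditioning on the
    shared scale (chi_df / sqrt(df), Gauss-Legendre in its probability
    scale) and the shared control factor (standard normal,
    Gauss-Hermite), making each comparison independent in the inner
    product.  Accuracy is ~1e-7, deterministic.
    """
    n_treatments = np.asarray(n_treatments, dtype=float)
    k = len(n_treatments)
    if k == 0:
        return np.empty(0)
    if df is None:
        df = n_control + n_treatments.sum() - k - 1
    lam = np.sqrt(n_treatments / (n_treatments + n_control))
    slam = np.sqrt(1.0 - lam ** 2)
    n_gl, n_gh = n_nodes
    xg, wg = leggauss(n_gl)
    wu = 0.5 * wg
    w_scale = stats.chi.ppf(0.5 * (xg + 1.0), df) / np.sqrt(df)
    xh, wh = hermgauss(n_gh)
    z0 = np.sqrt(2.0) * xh
    wz = wh / np.sqrt(np.pi)
    out = np.empty(len(t_stats))
    for i, t in enumerate(np.abs(np.asarray(t_stats, dtype=float))):
        if not np.isfinite(t):
            out[i] = 0.0
            continue
        hi = (t * w_scale[:, None, None] - lam * z0[None, :, None]) / slam
        lo = (-t * w_scale[:, None, None] - lam * z0[None, :, None]) / slam
        inner = np.prod(stats.norm.cdf(hi) - stats.norm.cdf(lo), axis=2)
        out[i] = min(max(1.0 - wu @ inner @ wz, 0.0), 1.0)
    return out


def _validate_groups(groups: Mapping[str, Sequence[float]],
                     min_groups: int) -> dict[str, np.ndarray]:
    if len(groups) < min_groups:
        raise StatisticsError(f"need at least {min_groups} groups, "
                              f"got {len(groups)}")
    arrs: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.size < 2:
            raise StatisticsError(f"group {name!r} has n={a.size} < 2")
        if not np.all(np.isfinite(a)):
            raise StatisticsError(f"group {name!r} has non-finite values")
        arrs[name] = a
    return arrs


def anova_dunnett(groups: Mapping[str, Sequence[float]], control: str,
                  alpha: float = 0.05) -> StatsReport:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs control.

    Treatment order follows the mapping's insertion order.  Degenerate
    zero-variance input is handled explicitly: identical group means give
    F = 0 and adjusted p = 1; distinct means with zero within-group
    variance give infinite statistics and p = 0.
    """
    arrs = _validate_groups(groups, min_groups=2)
    if control not in arrs:
        raise StatisticsError(f"control {control!r} not among groups")
    names = list(arrs)
    k_total = len(names)
    n = {g: a.size for g, a in arrs.items()}
    N = sum(n.values())
    grand = sum(a.sum() for a in arrs.values()) / N
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_between = k_total - 1
    df_within = N - k_total
    if ss_within == 0:
        f_stat = 0.0 if ss_between <= 1e-300 else float("inf")
        mse = 0.0
    else:
        mse = ss_within / df_within
        f_stat = (ss_between / df_between) / mse
    treatments = [g for g in names if g != control]
    ctrl = arrs[control]
    t_stats = []
    estimates = []
    for g in treatments:
        a = arrs[g]
        diff = a.mean() - ctrl.mean()
        estimates.append(diff)
        if mse == 0:
            t_stats.append(0.0 if diff == 0 else np.inf * np.sign(diff))
        else:
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / ctrl.size))
            t_stats.append(diff / se)
    pvals = dunnett_pvalues(t_stats, [n[g] for g in treatments],
                            n[control], df=df_within)
    # zero-variance, zero-difference comparisons are exactly null
    pvals = np.array([1.0 if (mse == 0 and t == 0) else p
                      for t, p in zip(t_stats, pvals)])
    comparisons = [
        Comparison(group=g, estimate=float(d), statistic=float(t),
                   p_adjusted=float(p), stars=significance_stars(float(p)))
        for g, d, t, p in zip(treatments, estimates, t_stats, pvals)
    ]
    return StatsReport(test_name="one-way ANOVA + Dunnett",
                       group_sizes=n, statistic=float(f_stat),
                       df=(float(df_between), float(df_within)),
                       comparisons=comparisons, control=control, alpha=alpha)


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float],
                names: tuple[str, str] = ("a", "b"),
                alpha: float = 0.05) -> StatsReport:
    """Two-tailed unpaired t-test with Welch's unequal-variance
    correction, star-coded like the Dunnett report."""
    arrs = _validate_groups({names[0]: group_a, names[1]: group_b},
                            min_groups=2)
    a, b = arrs[names[0]], arrs[names[1]]
    if np.array_equal(a, b):
        t_stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        if np.isnan(p):   # both groups constant and equal handled above
            t_stat, p = 0.0, 1.0
    comparison = Comparison(group=names[0], estimate=float(a.mean() - b.mean()),
                            statistic=t_stat, p_adjusted=p,
                            stars=significance_stars(p))
    return StatsReport(test_name="Welch t-test",
                       group_sizes={names[0]: a.size, names[1]: b.size},
                       statistic=t_stat, df=(1.0, df),
                       comparisons=[comparison], control=names[1],
                       alpha=alpha)


def summarize_condition(condition: str, raw: Sequence[float],
                        normalized: Sequence[float], n_excluded: int,
                        replicate: str = "") -> ConditionResult:
    normalized = list(map(float, normalized))
    mean = float(np.mean(normalized)) if normalized else float("nan")
    sd = (float(np.std(normalized, ddof=1)) if len(normalized) > 1
          else (0.0 if normalized else float("nan")))
    return ConditionResult(condition=condition, replicate=replicate,
                           bead_means_raw=list(map(float, raw)),
                           bead_means_normalized=normalized,
                           n_beads_pass=len(normalized),
                           n_beads_excluded=n_excluded,
                           mean_normalized=mean, sd_normalized=sd)
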