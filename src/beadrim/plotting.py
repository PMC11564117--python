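"""Dot plot of normalized per-bead intensities by condition."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .analysis import StatsReport


def condition_dotplot(norm_values: Mapping[str, Sequence[float]],
                      stats: StatsReport | None = None,
                      control: str | None = None, ax=None):
    """Per-bead normalized values as jittered dots with mean +/- SD bars,
    one column per condition, annotated with significance stars from the
    Dunnett report."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(norm_values) + 1.5, 4))
    rng = np.random.default_rng(0)  # cosmetic jitter only
    stars = {c.group: c.stars for c in stats.comparisons} if stats else {}
    for i, (name, vals) in enumerate(norm_values.items()):
        vals = np.asarray(vals, dtype=float)
        x = i + rng.uniform(-0.15, 0.15, vals.size)
        ax.plot(x, vals, "o", ms=3, alpha=0.6, color="tab:gray")
        if vals.size:
            mean = vals.mean()
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            ax.errorbar([i], [mean], yerr=[sd], fmt="_", color="k",
                        capsize=6, ms=18, lw=1.5)
            if name in stars:
                ax.annotate(stars[name], (i, mean + sd),
                            textcoords="offset points", xytext=(0, 8),
                            ha="center")
    ax.set_xticks(range(len(norm_values)), list(norm_values))
    ax.set_ylabel("normalized rim intensity")
    if control is not None:
        ax.axhline(1.0, color="tab:blue", lw=0.8, ls="--")
    return ax
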