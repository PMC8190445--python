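"""Plotting helpers for replicate summaries and model fits."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_load_by_class", "plot_odds_ratios"]

_CLASS_ORDER = ["long", "medium", "short"]


def plot_load_by_class(summaries: pd.DataFrame, ax=None):
    """Strip plot of per-replicate class means of the load per cM.

    One point per replicate and length class, with the across-replicate mean
    marked; mirrors the usual presentation of simulated load-by-ROH-class
    results.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    rng = np.random.default_rng(0)
    for x, cls in enumerate(_CLASS_ORDER):
        vals = summaries.loc[summaries["length_class"] == cls, "load_per_cm"]
        jitter = rng.uniform(-0.12, 0.12, size=len(vals))
        ax.plot(x + jitter, vals, "o", alpha=0.5, ms=4)
        ax.hlines(vals.mean(), x - 0.25, x + 0.25, color="k", lw=2)
    ax.set_xticks(range(3), _CLASS_ORDER)
    ax.set_xlabel("ROH length class")
    ax.set_ylabel("mutation load per cM (sum of s)")
    return ax


def plot_odds_ratios(fit, ax=None):
    """Forest plot of the odds ratios of a survival-model fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 2.5))
    tab = fit.odds_ratios
    y = np.arange(len(tab))[::-1]
    ax.errorbar(tab["odds_ratio"], y,
                xerr=[tab["odds_ratio"] - tab["lower"],
                      tab["upper"] - tab["odds_ratio"]],
                fmt="o", color="k", capsize=3)
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(y, tab.index)
    ax.set_xlabel("odds ratio of first-year survival (95% interval)")
    return ax
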