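"""Figure helpers: pair-density heatmaps and profile-with-CI plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def pair_density_plot(pair_table: pd.DataFrame, x: str, y: str, ax=None, gridsize: int = 60):
    """Hexbin-style 2D density of one pairwise relation (e.g. anatomical
    distance vs field distance)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    hb = ax.hexbin(pair_table[x], pair_table[y], gridsize=gridsize, cmap="viridis", mincnt=1)
    plt.colorbar(hb, ax=ax, label="pairs per bin")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax


def profile_plot(profile: pd.DataFrame, ax=None, *, ylabel: str = "statistic"):
    """Median-with-CI profile against radius, with the random-control
    median overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = profile.dropna(subset=["median"])
    ax.plot(ok["radius"], ok["median"], color="crimson", label="observed median")
    ax.fill_between(ok["radius"], ok["ci_lo"], ok["ci_hi"], color="crimson", alpha=0.25,
                    label="99% CI")
    ax.plot(ok["radius"], ok["control_median"], color="steelblue", label="random control")
    ax.set_xlabel("radius")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def moran_null_plot(moran, ax=None):
    """Permutation null histogram with observed I and its 95th percentile."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.hist(moran.null, bins=40, color="0.7")
    ax.axvline(moran.p95, color="0.3", ls="--", label="null 95th pct")
    ax.axvline(moran.I, color="crimson", label=f"I = {moran.I:.3f}")
    ax.set_xlabel("Moran's I")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    return ax
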