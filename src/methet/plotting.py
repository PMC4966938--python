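"""Basic plots: Kaplan-Meier curves and genome-wide aberration frequency."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .genome import chrom_sort_key
from .survival import apply_horizon


def km_plot(times, events, groups, horizon: float = 36.0, ax=None):
    """One KM curve per group, administratively censored at the horizon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    for label in pd.unique(g):
        sel = g == label
        tt, ee = apply_horizon(t[sel], e[sel], horizon)
        kmf = KaplanMeierFitter()
        kmf.fit(tt, event_observed=ee, label=str(label))
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    return ax


def frequency_track(freq: pd.DataFrame, ax=None):
    """Gain (up, red) and loss (down, blue) frequencies along the genome.

    Expects the output of ``complexity.patientwise_aberration_frequency``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    chroms = sorted(freq["chrom"].unique(), key=chrom_sort_key)
    offset = 0
    ticks, labels = [], []
    for chrom in chroms:
        g = freq[freq["chrom"] == chrom].sort_values("start_bp")
        x = offset + g["start_bp"].to_numpy()
        w = g["length_bp"].to_numpy()
        ax.bar(x, g["gain_freq"], width=w, align="edge", color="tab:red")
        ax.bar(x, -g["loss_freq"], width=w, align="edge", color="tab:blue")
        span = int(g["end_bp"].max())
        ticks.append(offset + span / 2)
        labels.append(chrom)
        offset += span
        ax.axvline(offset, color="0.8", lw=0.5)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylim(-1, 1)
    ax.set_ylabel("loss    freq    gain")
    ax.axhline(0, color="k", lw=0.5)
    return ax
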