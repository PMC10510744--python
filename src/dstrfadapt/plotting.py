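"""Plot helpers for filters, aligned time courses and index tables."""

from __future__ import annotations

import numpy as np


def plot_filter(frame, ax=None, rate: float = 100.0, **imshow_kw):
    """Heat map of a (n_freq, n_lag) STRF/dSTRF, lag increasing leftward
    into the past, symmetric color scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = np.asarray(frame)
    vmax = np.abs(frame).max() or 1.0
    n_lag = frame.shape[1]
    im = ax.imshow(frame, aspect="auto", origin="lower",
                   extent=(-n_lag / rate * 1e3, 0, 0, frame.shape[0]),
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax, **imshow_kw)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("frequency band")
    return im


def plot_aligned(aligned, ax=None, label=None, color=None):
    """Transition-averaged time course with a transition marker at t=0."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = aligned.mean()
    ax.plot(aligned.rel_times, m, label=label, color=color)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("time from transition (s)")
    return ax


def plot_index_distributions(index_table, index_kind="noise_filtering",
                             region="inhibitory", ax=None):
    """Per-condition box plot of an index over electrodes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = index_table[(index_table.index_kind == index_kind)
                      & (index_table.region == region)]
    conds = sorted(sub.condition.unique())
    data = [sub[sub.condition == c].value.dropna().values for c in conds]
    ax.boxplot(data, labels=conds)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel(f"{index_kind} index ({region})")
    return ax
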