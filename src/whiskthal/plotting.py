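"""Optional figure helpers (never load-bearing for the analysis)."""

from __future__ import annotations

import numpy as np

from .response import PSTH, normalize_psth
from .state_phase import PhaseTuning


def psth_heatmap(psths, ax=None):
    """log2-normalized PSTH heatmap, one row per neuron, ordered by peak latency."""
    import matplotlib.pyplot as plt

    rows, order_key = [], []
    for p in psths:
        norm, flag = normalize_psth(p)
        rate = p.rate if flag else norm
        rows.append(np.log2(np.maximum(rate, 2 ** -4)) if flag is None else rate)
        order_key.append(np.argmax(p.rate))
    mat = np.vstack([rows[i] for i in np.argsort(order_key)])
    if ax is None:
        _, ax = plt.subplots()
    extent = [psths[0].bin_edges[0] * 1e3, psths[0].bin_edges[-1] * 1e3, 0, mat.shape[0]]
    im = ax.imshow(mat, aspect="auto", extent=extent, cmap="magma")
    ax.set_xlabel("time from deflection (ms)")
    ax.set_ylabel("neuron")
    return ax, im


def polar_tuning(tuning: PhaseTuning, ax=None):
    """Polar plot of the 16-bin phase tuning and its cosine fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ok = ~np.isnan(tuning.rates)
    ax.bar(tuning.bin_centers[ok], tuning.rates[ok],
           width=2 * np.pi / tuning.bin_centers.size, alpha=0.5)
    phi = np.linspace(-np.pi, np.pi, 256)
    fit = tuning.fit_mean + tuning.fit_amp * np.cos(phi - tuning.fit_phase)
    ax.plot(phi, np.clip(fit, 0, None), lw=2)
    return ax
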