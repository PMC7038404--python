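"""Diagnostic figures: GRF profile overlays and Bland-Altman agreement plots."""

from __future__ import annotations

import numpy as np

from .evaluation import BlandAltmanSummary


def plot_profile(time_s, truth_bw, estimated_bw, phase_pred=None, ax=None):
    """Overlay plate and model GRF curves; shade classifier flight intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(time_s, truth_bw, color="0.2", lw=1.2, label="force plate")
    ax.plot(time_s, estimated_bw, color="tab:red", lw=1.0, label="model")
    if phase_pred is not None:
        flight = np.asarray(phase_pred) == 0
        ax.fill_between(time_s, 0, 1, where=flight, alpha=0.15,
                        transform=ax.get_xaxis_transform(),
                        color="tab:blue", label="predicted flight")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("GRF (BW)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_bland_altman(model_peaks, plate_peaks, summary: BlandAltmanSummary,
                      ax=None):
    """Difference-vs-mean plot with the mean bias and limits of agreement."""
    import matplotlib.pyplot as plt

    model_peaks = np.asarray(model_peaks, dtype=float)
    plate_peaks = np.asarray(plate_peaks, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = (model_peaks + plate_peaks) / 2
    diffs = plate_peaks - model_peaks
    ax.scatter(means, diffs, s=18, color="0.3")
    ax.axhline(summary.mean_difference, color="tab:red", lw=1)
    for limit in summary.limits_of_agreement:
        ax.axhline(limit, color="tab:red", lw=1, ls="--")
    ax.set_xlabel("mean of plate and model peak GRF (BW)")
    ax.set_ylabel("plate - model (BW)")
    return ax
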