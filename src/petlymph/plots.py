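"""Kaplan-Meier step plots for one or more survival groups."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .survival import SurvivalCurve

__all__ = ["plot_km"]


def plot_km(curves: dict[str, SurvivalCurve], title: str = "", ax=None):
    """Draw step survival curves, one per named group.

    Returns the matplotlib Axes; callers save or show the figure.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in curves.items():
        t = np.r_[0.0, np.repeat(curve.event_times, 2)]
        s = np.r_[1.0, 1.0, np.repeat(curve.survival_probabilities, 2)[:-1]]
        label = name
        if curve.median_months is not None:
            label += f" (median {curve.median_months:.1f} mo)"
        ax.plot(t, s, drawstyle="default", label=label)
    ax.set_xlabel("months from baseline PET")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
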