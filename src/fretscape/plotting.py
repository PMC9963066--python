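"""Basic figures: efficiency histograms and titration curves."""

from __future__ import annotations

import numpy as np

from .bursts import EfficiencyHistogram
from .thermo import ThermoModel, TitrationSeries

__all__ = ["plot_histogram", "plot_titration"]


def plot_histogram(hist: EfficiencyHistogram, fit=None, ax=None):
    """Bar plot of a transfer-efficiency histogram, optionally with a
    mixture-fit overlay (a :class:`~fretscape.mixture.MixtureResults`)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.centers, hist.counts, width=widths, color="0.7", edgecolor="0.4")
    if fit is not None:
        ax.plot(hist.centers, fit.predicted_counts(), color="crimson", lw=1.5)
    ax.set_xlabel("transfer efficiency E")
    ax.set_ylabel("bursts")
    return ax


def plot_titration(series: TitrationSeries, model: ThermoModel | None = None, ax=None):
    """State fractions vs denaturant concentration, with optional model curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for state in series.states:
        sub = series.table[series.table["state"] == state]
        ax.errorbar(
            sub["conc_M"], sub["fraction"], yerr=sub["sd"], fmt="o", ms=4, label=str(state)
        )
    if model is not None:
        grid = np.linspace(0, series.table["conc_M"].max(), 200)
        fracs = model.fractions(grid)
        for j, state in enumerate(model.states):
            ax.plot(grid, fracs[:, j], lw=1.2)
    ax.set_xlabel("denaturant (M)")
    ax.set_ylabel("population fraction")
    ax.legend()
    return ax
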