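"""Minimal trace plotting (matplotlib optional)."""

from __future__ import annotations

__all__ = ["plot_traces"]


def plot_traces(traceset, sites=None, quantity: str = "vm", ax=None):
    """Plot one quantity at several sites against time.

    Returns the matplotlib axes.  Imports matplotlib lazily so the rest of
    the package has no hard plotting dependency.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for site in sites or traceset.sites:
        ax.plot(traceset.time, traceset[site][quantity], label=site, lw=0.8)
    ax.set_xlabel("time (ms)")
    ylabel = {"vm": "Vm (mV)"}.get(quantity, f"{quantity} (nA)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7, ncol=2)
    return ax
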