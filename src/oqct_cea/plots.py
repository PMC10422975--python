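"""Presentation helpers: CE plane, acceptability curves, tornado diagram.

Thin matplotlib wrappers over the analysis outputs; not part of the tested
model surface.  All functions return the matplotlib figure so callers can
save it in any format.
"""

from __future__ import annotations

import pandas as pd


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_ce_plane(samples: pd.DataFrame, wtp: float, title: str = ""):
    """Incremental cost vs incremental effectiveness scatter with the WTP line."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples["delta_qalys"], samples["delta_cost"], s=3, alpha=0.25,
               color="#30608a", rasterized=True)
    lim = max(abs(samples["delta_qalys"]).max(), 0.1)
    ax.plot([-lim, lim], [-wtp * lim, wtp * lim], "k--", lw=1,
            label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs (oQCT vs DXA)")
    ax.set_ylabel("Incremental cost ($)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_ceac(ceac: pd.DataFrame, title: str = ""):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ceac.columns:
        if col.startswith("p_"):
            ax.plot(ceac["wtp"], ceac[col], label=col[2:].replace("_", " "))
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_tornado(entries, base_icer: float, title: str = "", top: int = 10):
    plt = _mpl()
    shown = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#8aa8c5")
    ax.axvline(base_icer, color="k", lw=1, label="base case")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICER ($/QALY), oQCT vs DXA")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
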