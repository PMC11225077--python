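"""Figure helpers: cost-effectiveness plane, CEAC and tornado charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .uncertainty import PSAResult, TornadoBar

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def plot_ce_plane(
    psa: PSAResult,
    reference: str = "polypill",
    wtp: float = 21768.0,
    path=None,
):
    """Incremental (dQALY, dCost) scatter of the reference arm vs each
    comparator; the dashed line marks the willingness-to-pay threshold."""
    ref = psa.labels.index(reference)
    fig, ax = plt.subplots(figsize=(7, 6))
    for j, label in enumerate(psa.labels):
        if j == ref:
            continue
        dq = psa.qalys[:, ref] - psa.qalys[:, j]
        dc = psa.costs[:, ref] - psa.costs[:, j]
        ax.scatter(dq, dc, s=4, alpha=0.35, label=f"vs {label}")
    lim = max(abs(np.array(ax.get_xlim())).max(), 1e-9)
    xs = np.linspace(-lim, lim, 100)
    ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP = {wtp:,.0f} USD/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.set_title(f"Cost-effectiveness plane: {reference} vs comparators")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_ceac(ceac_df: pd.DataFrame, wtp: float = 21768.0, path=None):
    """Acceptability curves per strategy with the threshold marked."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, grp in ceac_df.groupby("strategy"):
        grp = grp.sort_values("wtp")
        ax.plot(grp["wtp"], grp["probability"], label=label)
    ax.axvline(wtp, color="k", ls="--", lw=1)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curves")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_tornado(bars: list[TornadoBar], base_outcome: float = 0.0, path=None):
    """Horizontal tornado chart, widest bar on top."""
    bars = sorted(bars, key=lambda b: abs(b.spread))
    names = [b.parameter for b in bars]
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(bars))))
    for i, b in enumerate(bars):
        lo, hi = sorted((b.low, b.high))
        ax.barh(i, hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.axvline(base_outcome, color="k", lw=1)
    ax.set_yticks(range(len(bars)))
    ax.set_yticklabels(names, fontsize=7)
    ax.set_xlabel("outcome")
    ax.set_title("One-way sensitivity (tornado)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
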