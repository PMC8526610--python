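"""Incidence-rate-ratio forest plot across interval durations."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def forest_irr(contrasts: pd.DataFrame, path=None):
    """Forest plot of category IRRs (one panel per interval duration).

    ``contrasts`` is the concatenated output of ``pairwise_contrasts``
    with a ``duration_s`` column, as written by the model driver.
    """
    durations = sorted(contrasts["duration_s"].unique())
    fig, axes = plt.subplots(1, len(durations), sharey=True,
                             figsize=(2.6 * len(durations), 2.8))
    if len(durations) == 1:
        axes = [axes]
    order = ["before vs between", "after vs between", "after vs before"]
    for ax, d in zip(axes, durations):
        sub = contrasts[contrasts["duration_s"] == d].set_index("contrast")
        ys = range(len(order))
        ax.errorbar([sub.loc[c, "irr"] for c in order], ys,
                    xerr=[[sub.loc[c, "irr"] - sub.loc[c, "irr_low"] for c in order],
                          [sub.loc[c, "irr_high"] - sub.loc[c, "irr"] for c in order]],
                    fmt="o", color="k", capsize=3)
        ax.axvline(1.0, ls=":", color="grey")
        ax.set_title(f"{d:.0f} s")
        ax.set_xlabel("IRR")
    axes[0].set_yticks(range(len(order)), order)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
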