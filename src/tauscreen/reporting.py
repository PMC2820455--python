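"""QC figure for a screen run: control dispersion and effect landscape."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["qc_figure"]


def qc_figure(norm_wells: pd.DataFrame, summaries: pd.DataFrame, path) -> None:
    """Two-panel QC: NS-control normalized spread and per-siRNA volcano."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))

    ns = norm_wells[norm_wells["role"] == "non_silencing"]
    for col, color in (("phospho_norm", "crimson"), ("total_norm", "seagreen")):
        ax1.hist(ns[col], bins=30, alpha=0.6, color=color, label=col)
    ax1.axvline(1.0, color="k", lw=1)
    ax1.set_xlabel("normalized control readout")
    ax1.set_ylabel("wells")
    ax1.set_title("non-silencing controls")
    ax1.legend(frameon=False, fontsize=8)

    p = summaries["phospho_p"].clip(lower=1e-12)
    ax2.scatter(summaries["phospho_avg"], -np.log10(p), s=10, alpha=0.6, c="steelblue")
    ax2.axhline(-np.log10(0.05), color="grey", ls="--", lw=1)
    ax2.axvline(1.0, color="k", lw=1)
    ax2.set_xlabel("phospho-tau average (fraction of control)")
    ax2.set_ylabel("-log10 p")
    ax2.set_title("per-siRNA effects")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
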