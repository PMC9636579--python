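"""Basic plot renderings: volcano plots and delta-Bliss heatmaps.

The pipeline's primary outputs are plot-ready tables; these helpers give a
quick matplotlib rendering of the two figures analysts ask for first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["volcano", "volcano_table", "bliss_heatmap"]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """log2fc / -log10 p / pass flag table ready for external plotting."""
    out = results[["log2fc", "p_value"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=1e-300))
    if "passes" in results.columns:
        out["passes"] = results["passes"]
    return out


def volcano(results: pd.DataFrame, title: str = "", ax=None):
    """Scatter of log2 fold change against -log10 p, passing features
    highlighted."""
    tab = volcano_table(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    passing = tab["passes"] if "passes" in tab.columns else pd.Series(False, index=tab.index)
    ax.scatter(tab.loc[~passing, "log2fc"], tab.loc[~passing, "neg_log10_p"], s=6, c="0.7")
    ax.scatter(tab.loc[passing, "log2fc"], tab.loc[passing, "neg_log10_p"], s=10, c="crimson")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    return ax


def bliss_heatmap(grid, ax=None):
    """Heatmap of the delta-Bliss matrix (positive = synergy)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    arr = grid.delta_bliss.to_numpy()
    lim = max(abs(np.nanmin(arr)), abs(np.nanmax(arr)), 0.05)
    im = ax.imshow(arr, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(len(grid.conc_b)), [f"{c:g}" for c in grid.conc_b])
    ax.set_yticks(range(len(grid.conc_a)), [f"{c:g}" for c in grid.conc_a])
    ax.set_xlabel(f"{grid.drug_b} (uM)")
    ax.set_ylabel(f"{grid.drug_a} (uM)")
    plt.colorbar(im, ax=ax, label="delta Bliss")
    return ax
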