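"""Summary figures for a cohort run (optional; needs matplotlib)."""

from __future__ import annotations

import numpy as np

from . import laminar as _laminar
from .selectivity import ECC_BIN_NAMES
from .synthetic import CONTRASTS


def summary_figure(result, path):
    """Write a four-panel overview of a cohort run.

    Panels: compartment SI per contrast, V2 laminar SI profiles, texture
    SI by eccentricity, and the group connectivity matrix (mean r, starred
    where FDR-significant).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    ax = axes[0, 0]
    comps = ("thin", "pale", "thick")
    width = 0.25
    for i, contrast in enumerate(CONTRASTS):
        tab = result.compartment_table(contrast)[list(comps)]
        x = np.arange(len(comps)) + (i - 1) * width
        ax.bar(x, tab.mean(), width, yerr=tab.sem(), capsize=3, label=contrast)
    ax.set_xticks(range(len(comps)), comps)
    ax.set_ylabel("selectivity index")
    ax.set_title("V2 stripe compartments")
    ax.legend(frameon=False, fontsize=8)

    ax = axes[0, 1]
    bins = list(_laminar.DEPTH_BINS)
    for contrast in CONTRASTS:
        tab = result.laminar_table("V2", contrast)[bins]
        ax.errorbar(range(len(bins)), tab.mean(), yerr=tab.sem(), marker="o", label=contrast)
    ax.set_xticks(range(len(bins)), bins)
    ax.set_ylabel("selectivity index")
    ax.set_title("V2 cortical depth profile")
    ax.legend(frameon=False, fontsize=8)

    ax = axes[1, 0]
    tab = result.ecc_table("texture")[list(ECC_BIN_NAMES)]
    ax.bar(range(3), tab.mean(), yerr=tab.sem(), capsize=3, color="tab:green")
    ax.set_xticks(range(3), ECC_BIN_NAMES)
    ax.set_ylabel("texture selectivity index")
    ax.set_title("V2 texture selectivity by eccentricity")

    ax = axes[1, 1]
    g = result.group_connectivity
    cells = g[["lower", "higher", "direction"]].drop_duplicates().reset_index(drop=True)
    mat = np.zeros((len(cells), len(CONTRASTS)))
    sig = np.zeros_like(mat, dtype=bool)
    for j, contrast in enumerate(CONTRASTS):
        for i, row in cells.iterrows():
            cell = g[
                (g["contrast"] == contrast)
                & (g["lower"] == row["lower"])
                & (g["higher"] == row["higher"])
                & (g["direction"] == row["direction"])
            ].iloc[0]
            mat[i, j] = cell["mean_r"]
            sig[i, j] = cell["q"] < 0.05
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    for (i, j), flag in np.ndenumerate(sig):
        if flag:
            ax.text(j, i, "*", ha="center", va="center", fontsize=14)
    ax.set_xticks(range(len(CONTRASTS)), CONTRASTS, fontsize=8)
    ax.set_yticks(
        range(len(cells)),
        [f"{r.lower}-{r.higher} {r.direction[:2].upper()}" for r in cells.itertuples()],
        fontsize=7,
    )
    ax.set_title("informational connectivity (mean r)")
    fig.colorbar(im, ax=ax, shrink=0.8)

    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
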