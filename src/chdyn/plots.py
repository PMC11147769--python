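"""Optional plotting helpers (require matplotlib, installed via the 'plot' extra)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_cooccurrence_heatmap(cooc: pd.DataFrame, path: str | Path) -> None:
    """Gene co-occurrence heatmap: cell color = VAF-ordering fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted(set(cooc["gene_1"]) | set(cooc["gene_2"]))
    frac = np.full((len(genes), len(genes)), np.nan)
    for _, row in cooc.iterrows():
        i, j = genes.index(row["gene_1"]), genes.index(row["gene_2"])
        frac[i, j] = row["frac_gene1_higher_vaf"]
    fig, ax = plt.subplots(figsize=(1.2 * len(genes), 1.0 * len(genes)))
    im = ax.imshow(frac, vmin=0, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(genes)), genes, rotation=45, ha="right")
    ax.set_yticks(range(len(genes)), genes)
    fig.colorbar(im, ax=ax, label="fraction gene 1 VAF higher")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gene_fitness(fitness: pd.DataFrame, path: str | Path) -> None:
    """Violin plot of per-gene clonal fitness estimates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted(fitness["gene"].unique())
    data = [fitness.loc[fitness["gene"] == g, "s"].to_numpy() for g in genes]
    fig, ax = plt.subplots(figsize=(1.2 * len(genes) + 2, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(genes) + 1), genes, rotation=45, ha="right")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_ylabel("clonal fitness s (/year)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
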