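"""Regional association plot: stacked -log10 p tracks for the three traits."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def regional_plot(
    mqtl, eqtl, gwas, cpg=None, genes=(), path=None, title=None
):
    """Overlaid -log10 p-value tracks for methylation, expression and trait.

    Takes the three RegionalDatasets of one region, an optional CpG
    annotation (marked with a red cross) and gene annotations (drawn as
    bars below the x axis).  Writes to ``path`` when given and returns the
    matplotlib figure.
    """
    fig, ax = plt.subplots(figsize=(8, 4.5))
    tracks = [
        (gwas, "complex trait", "0.4"),
        (eqtl, "expression", "tab:blue"),
        (mqtl, "methylation", "tab:red"),
    ]
    for ds, label, color in tracks:
        t = ds.table[ds.table["pvalue"].notna()]
        ax.scatter(
            t["pos"] / 1e6, -np.log10(t["pvalue"]),
            s=14, alpha=0.75, label=f"{label} ({ds.trait_id})", color=color,
        )
    ymin = ax.get_ylim()[0]
    for gene in genes:
        ax.plot(
            [gene.start / 1e6, gene.end / 1e6], [ymin - 1, ymin - 1],
            lw=5, color="tab:green", solid_capstyle="butt",
        )
        ax.annotate(
            gene.gene_id, ((gene.start + gene.end) / 2e6, ymin - 1),
            textcoords="offset points", xytext=(0, -12),
            ha="center", fontsize=7,
        )
    if cpg is not None:
        ax.plot(
            cpg.pos / 1e6, ymin - 1, marker="x", color="red", markersize=9,
            markeredgewidth=2,
        )
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\log_{10} P$")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    ax.margins(y=0.18)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
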