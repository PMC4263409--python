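"""Static figure files for the standard panels.

All functions take the tables the analysis modules produce and return a
matplotlib Figure; callers save with ``fig.savefig(path)``.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_parallelism_histogram(histogram: pd.DataFrame, title: str = ""):
    # display_genes carries the capped singleton bin; stored counts untouched
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(histogram):
        ax.bar(histogram.n_populations, histogram.display_genes, color="#4878a8")
        capped = histogram.display_genes < histogram.n_genes
        for _, row in histogram[capped].iterrows():
            ax.annotate(
                f"{row.n_genes}", (row.n_populations, row.display_genes),
                ha="center", va="bottom", fontsize=8,
            )
    ax.set_xlabel("populations with a mutation in the gene")
    ax.set_ylabel("genes")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_parallelism_scatter(summary: pd.DataFrame, label_top: int = 5, title: str = ""):
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(summary):
        ax.scatter(summary.n_populations, summary.n_mutations, s=12, alpha=0.6)
        for _, row in summary.head(label_top).iterrows():
            ax.annotate(row.gene_id, (row.n_populations, row.n_mutations), fontsize=7)
    ax.set_xlabel("populations with mutations in gene")
    ax.set_ylabel("total mutations in gene")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_cumulative_frequency(freq_summary, title: str = ""):
    fig, ax = plt.subplots(figsize=(7, 4))
    cum = freq_summary.cumulative
    ax.bar(range(len(cum)), cum.to_numpy(), color="#a84848")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(cum)))
    ax.set_xticklabels(cum.index, rotation=90, fontsize=6)
    ax.set_ylabel(f"cumulative {freq_summary.gene_id} frequency")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_allele_spectrum(spectrum: pd.DataFrame, domain_map=None, title: str = ""):
    """Lollipop panel: residue position vs populations carrying each allele."""
    fig, ax = plt.subplots(figsize=(7, 3))
    if len(spectrum) and spectrum.residue.notna().any():
        x = spectrum.residue.astype(float)
        y = spectrum.n_populations.astype(float)
        ax.vlines(x, 0, y, color="grey", lw=0.8)
        lof = spectrum.effect.isin(["stop_gained", "frameshift"])
        ax.scatter(x[~lof], y[~lof], color="#c03030", s=18, label="substitution/in-frame")
        if lof.any():
            ax.scatter(x[lof], y[lof], color="black", s=18, label="stop/frameshift")
        ax.legend(fontsize=7)
        if domain_map is not None:
            for name, start, end in domain_map.domains:
                ax.axvspan(start, end, alpha=0.12)
                ax.annotate(name, ((start + end) / 2, ax.get_ylim()[1]),
                            ha="center", fontsize=7)
    ax.set_xlabel("residue")
    ax.set_ylabel("populations")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_protein_heatmap(table: pd.DataFrame, title: str = ""):
    """Functional heat map: undetected cells rendered grey, not zero."""
    fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * len(table))))
    fc = table.drop(columns=["class"], errors="ignore").astype(float)
    if fc.size:
        masked = np.ma.masked_invalid(fc.to_numpy())
        vmax = np.nanmax(np.abs(fc.to_numpy())) or 1.0
        cmap = plt.get_cmap("RdYlGn_r").copy()
        cmap.set_bad("0.7")
        im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
        fig.colorbar(im, ax=ax, label="log2 fold change vs ancestor")
        ax.set_yticks(range(len(fc)))
        ax.set_yticklabels(fc.index, fontsize=5)
        ax.set_xticks(range(fc.shape[1]))
        ax.set_xticklabels(
            [c.replace("log2fc_", "") for c in fc.columns], rotation=90, fontsize=6
        )
    ax.set_title(title)
    fig.tight_layout()
    return fig
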