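"""Functional enrichment of parallel mutations.

The subsystem score of subsystem *s* is

    score_s = (m_s / g_s) / (M / G)

the subsystem's mutated-gene fraction over the genome-wide mutated-gene
fraction: 1 under uniform placement, >1 for enriched subsystems.  Because
subsystems partition the gene set, the gene-count-weighted mean score is
exactly 1 — a useful internal consistency check.  ``score - 1`` (the
conventionally plotted excess) is included in the output.
"""

from __future__ import annotations

import pandas as pd

from .annotation import GenomeAnnotation
from .parallelism import parallelism_histogram, parallelism_summary

__all__ = ["subsystem_score", "hierarchical_parallelism", "LEVELS"]

LEVELS = ("gene", "subsystem", "category")


def subsystem_score(
    matrix: pd.DataFrame,
    annotation: GenomeAnnotation,
    include_unassigned: bool = True,
) -> pd.DataFrame:
    """Per-subsystem enrichment of mutated genes.

    A gene is 'mutated' if it has >=1 call in >=1 analyzed population
    (i.e. appears as a row of ``matrix`` with a positive total).  With
    ``include_unassigned=False`` the pseudo-subsystem of unannotated genes
    is dropped (the weighted-mean identity then no longer holds).
    """
    genes = annotation.genes
    mutated = set(matrix.index[(matrix.sum(axis=1) > 0)]) & set(genes.gene_id)
    M, G = len(mutated), len(genes)
    if M == 0:
        return pd.DataFrame(
            columns=["subsystem", "category", "m_s", "g_s", "M", "G", "score", "score_minus_1"]
        )
    is_mut = genes.gene_id.isin(mutated)
    per = (
        genes.assign(mutated=is_mut)
        .groupby(["subsystem", "category"], sort=True)
        .agg(m_s=("mutated", "sum"), g_s=("mutated", "size"))
        .reset_index()
    )
    if not include_unassigned:
        per = per[per.subsystem != "unassigned"]
    per["M"], per["G"] = M, G
    per["score"] = (per.m_s / per.g_s) / (M / G)
    per["score_minus_1"] = per["score"] - 1.0
    return per.sort_values("score", ascending=False).reset_index(drop=True)


def hierarchical_parallelism(
    matrix: pd.DataFrame,
    annotation: GenomeAnnotation,
    level: str = "gene",
    cap: int | None = None,
) -> dict:
    """Parallelism summary and histogram at gene, subsystem or category level.

    Aggregation unions population sets: a unit is hit in a population if any
    member gene is, so parallelism is monotone non-decreasing up the
    hierarchy.  Returns ``{"summary": ..., "histogram": ...}``.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if level == "gene":
        agg = matrix
    else:
        mapping = annotation.genes.set_index("gene_id")[level]
        units = matrix.index.map(mapping)
        agg = matrix.groupby(units.fillna("unassigned")).sum()
        agg.index.name = level
    summary = parallelism_summary(agg)
    summary = summary.rename(columns={"gene_id": level if level != "gene" else "gene_id"})
    return {"summary": summary, "histogram": parallelism_histogram(agg, cap=cap)}
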