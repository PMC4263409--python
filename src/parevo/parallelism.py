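"""Parallel-evolution statistics across replicate populations.

Independent populations hitting the same gene is the signature of
adaptation: under neutrality the probability that ``n`` populations each
mutate one specific gene out of ``G`` is ``(1/G)^n``.  This module builds
the gene x population mutation-count matrix and derives from it the
per-gene parallelism summary, display histograms, cumulative within-gene
allele frequencies, the unique-allele spectrum with protein-domain
annotation, the random-parallelism probability, and mutator flagging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "DomainMap",
    "ARCA_LIKE_DOMAINS",
    "gene_mutation_matrix",
    "parallelism_summary",
    "parallelism_histogram",
    "cumulative_gene_frequency",
    "random_parallelism_probability",
    "flag_mutators",
    "unique_allele_spectrum",
]


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping 1-based closed residue intervals."""

    protein: str
    domains: tuple  # of (name, start_residue, end_residue)

    def __post_init__(self):
        prev_end = 0
        for name, start, end in self.domains:
            if start < 1 or end < start:
                raise ValueError(f"bad interval for {name}: {start}-{end}")
            if start <= prev_end:
                raise ValueError(f"overlapping domain {name}")
            prev_end = end

    def domain_of(self, residue: int) -> str:
        for name, start, end in self.domains:
            if start <= residue <= end:
                return name
        return "outside"


#: two-domain response-regulator layout of the arcA-like driver
ARCA_LIKE_DOMAINS = DomainMap(
    protein="arcA_like",
    domains=(("receiver", 1, 123), ("DNA_binding", 124, 238)),
)


# ---------------------------------------------------------------------------
# the gene x population matrix

def gene_mutation_matrix(
    calls: pd.DataFrame,
    annotation: GenomeAnnotation,
    populations: pd.DataFrame,
) -> pd.DataFrame:
    """Mutation counts per gene (rows) per analyzed population (columns).

    Genes with zero calls are omitted from the rows; total gene counts for
    enrichment come from the annotation.  Calls in excluded populations must
    be filtered out before this point.
    """
    pop_ids = list(populations["population_id"])
    unknown = set(calls["population_id"]) - set(pop_ids)
    if unknown:
        raise ValueError(f"calls reference unknown populations: {sorted(unknown)[:5]}")
    coding = calls[calls["gene_id"] != "intergenic"]
    if len(coding) == 0:
        return pd.DataFrame(
            np.zeros((0, len(pop_ids)), dtype=int), columns=pop_ids
        ).rename_axis(index="gene_id")
    counts = (
        coding.groupby(["gene_id", "population_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=pop_ids, fill_value=0)
    )
    return counts.astype(int)


def parallelism_summary(
    matrix: pd.DataFrame,
    populations: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene cross-population summary, ranked by parallelism.

    ``n_populations`` counts populations with >=1 call in the gene
    (presence); ``n_mutations`` is the raw call total; ``n_unique_alleles``
    (requires ``calls``) deduplicates by (position, ref, alt).  Sorted by
    n_populations, then n_mutations, descending, gene_id as tiebreaker.
    """
    if len(matrix) == 0:
        return pd.DataFrame(
            columns=["gene_id", "n_populations", "n_mutations", "n_unique_alleles"]
        )
    rec = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "n_populations": (matrix > 0).sum(axis=1).to_numpy(),
            "n_mutations": matrix.sum(axis=1).to_numpy(),
        }
    )
    if calls is not None:
        uniq = (
            calls[calls.gene_id != "intergenic"]
            .drop_duplicates(["gene_id", "position", "ref", "alt"])
            .groupby("gene_id")
            .size()
        )
        rec["n_unique_alleles"] = rec["gene_id"].map(uniq).fillna(0).astype(int)
    else:
        rec["n_unique_alleles"] = pd.NA
    if populations is not None:
        treatment_of = populations.set_index("population_id")["treatment"]
        for treatment in treatment_of.unique():
            cols = [c for c in matrix.columns if treatment_of.get(c) == treatment]
            rec[f"n_populations_{treatment}"] = (
                (matrix[cols] > 0).sum(axis=1).to_numpy() if cols else 0
            )
    rec = rec.sort_values(
        ["n_populations", "n_mutations", "gene_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return rec


def parallelism_histogram(matrix: pd.DataFrame, cap: int | None = None) -> pd.DataFrame:
    """Genes (and mutations) binned by number of populations hit.

    ``cap`` is display metadata only — the singleton bin dominates, so
    plots truncate it — stored counts are never altered.
    """
    if cap is not None and cap < 1:
        raise ValueError("cap must be >= 1 when given")
    if len(matrix) == 0:
        return pd.DataFrame(columns=["n_populations", "n_genes", "n_mutations", "display_genes"])
    npop = (matrix > 0).sum(axis=1)
    nmut = matrix.sum(axis=1)
    hist = (
        pd.DataFrame({"n_populations": npop, "n_mutations": nmut})
        .groupby("n_populations")
        .agg(n_genes=("n_mutations", "size"), n_mutations=("n_mutations", "sum"))
        .reset_index()
    )
    hist["display_genes"] = (
        hist["n_genes"].clip(upper=cap) if cap is not None else hist["n_genes"]
    )
    return hist


# ---------------------------------------------------------------------------
# within-gene cumulative frequency

@dataclass
class GeneFrequencySummary:
    gene_id: str
    cumulative: pd.Series  # population -> summed allele frequency
    exceeds_one: pd.Series  # population -> bool

    @property
    def mean(self) -> float:
        return float(self.cumulative.mean())

    def ci95_halfwidth(self) -> float:
        n = len(self.cumulative)
        if n < 2:
            return float("nan")
        return float(1.96 * self.cumulative.std(ddof=1) / math.sqrt(n))


def cumulative_gene_frequency(
    calls: pd.DataFrame,
    gene_id: str,
    populations: pd.DataFrame,
    annotation: GenomeAnnotation | None = None,
) -> GeneFrequencySummary:
    """Sum of all allele frequencies of one gene, per population.

    A proxy for the fraction of each population carrying *some* mutation in
    the gene (exact when alleles are mutually exclusive).  Raw sums > 1 are
    reported unchanged with ``exceeds_one`` set — capping would hide either
    co-occurring genotypes or data errors.
    """
    if annotation is not None:
        annotation.gene(gene_id)  # raises on unknown gene
    elif gene_id not in set(calls["gene_id"]):
        raise KeyError(f"unknown gene: {gene_id}")
    pop_ids = list(populations["population_id"])
    sums = (
        calls[calls.gene_id == gene_id]
        .groupby("population_id")["frequency"]
        .sum()
        .reindex(pop_ids, fill_value=0.0)
    )
    return GeneFrequencySummary(gene_id, sums, sums > 1.0)


# ---------------------------------------------------------------------------
# random parallelism

def random_parallelism_probability(gene_counts, n_populations) -> tuple:
    """Probability that the same gene is hit in every population by chance.

    For species ``s`` with ``G_s`` genes and ``n_s`` independently evolved
    populations each mutating one uniformly random gene,
    ``p = prod_s (1/G_s)^{n_s}``; computed in log10 space.  Returns
    ``(log10_p, p)`` with ``p`` None when below the floating-point range.
    """
    gene_counts = list(gene_counts)
    n_populations = list(n_populations)
    if len(gene_counts) != len(n_populations):
        raise ValueError("gene_counts and n_populations must have equal length")
    if any(g < 1 for g in gene_counts):
        raise ValueError("gene counts must be >= 1")
    if any(n < 0 for n in n_populations):
        raise ValueError("population counts must be >= 0")
    log10_p = -sum(n * math.log10(g) for g, n in zip(gene_counts, n_populations))
    linear = 10 ** log10_p if log10_p > -300 else None
    return log10_p, linear


# ---------------------------------------------------------------------------
# mutators

def flag_mutators(
    counts: pd.Series,
    groups: pd.Series | None = None,
    method: str = "tukey",
    k: float = 1.5,
    median_multiplier: float = 5.0,
    min_group_size: int = 4,
) -> set:
    """Flag populations with outlying total mutation counts.

    Within each group (treatment x species), the default rule flags counts
    above the Tukey fence Q3 + k*IQR; ``method="median"`` flags counts above
    ``median * median_multiplier``.  Groups smaller than ``min_group_size``
    are untestable — nothing flagged, a warning logged.
    """
    if groups is None:
        groups = pd.Series("all", index=counts.index)
    flagged: set = set()
    for g, sub in counts.groupby(groups):
        if len(sub) < min_group_size:
            logger.warning("mutator group %r has %d < %d populations; none flagged",
                           g, len(sub), min_group_size)
            continue
        if method == "tukey":
            q1, q3 = np.percentile(sub, [25, 75])
            fence = q3 + k * (q3 - q1)
        elif method == "median":
            fence = float(np.median(sub)) * median_multiplier
        else:
            raise ValueError("method must be 'tukey' or 'median'")
        flagged |= set(sub.index[sub > fence])
    return flagged


# ---------------------------------------------------------------------------
# unique alleles and domains

def unique_allele_spectrum(
    calls: pd.DataFrame,
    gene_id: str,
    annotation: GenomeAnnotation | None = None,
    domain_map: DomainMap | None = None,
) -> pd.DataFrame:
    """Distinct alleles of one gene with recurrence and domain assignment.

    Alleles are deduplicated by (position, ref, alt); ``n_populations`` is
    the number of populations carrying that exact allele.  When an
    annotation is given, residue numbers are derived from gene coordinates
    (strand-aware) and, with a :class:`DomainMap`, each allele is assigned
    to its domain ('outside' with a warning if beyond the mapped protein).
    """
    sub = calls[calls.gene_id == gene_id]
    if len(sub) == 0:
        return pd.DataFrame(
            columns=["position", "ref", "alt", "vtype", "effect", "n_populations",
                     "residue", "domain"]
        )
    spectrum = (
        sub.groupby(["position", "ref", "alt"], sort=True)
        .agg(
            vtype=("vtype", "first"),
            effect=("effect", "first"),
            n_populations=("population_id", "nunique"),
        )
        .reset_index()
    )
    if annotation is not None:
        gene = annotation.gene(gene_id)
        if gene.strand == "-":
            nt_offset = gene.end - spectrum["position"]
        else:
            nt_offset = spectrum["position"] - gene.start
        spectrum["residue"] = (nt_offset // 3 + 1).astype(int)
        if domain_map is not None:
            spectrum["domain"] = spectrum["residue"].map(domain_map.domain_of)
            n_out = int((spectrum["domain"] == "outside").sum())
            if n_out:
                logger.warning(
                    "%d alleles of %s fall outside the domain map", n_out, gene_id
                )
        else:
            spectrum["domain"] = pd.NA
    else:
        spectrum["residue"] = pd.NA
        spectrum["domain"] = pd.NA
    return spectrum


def domain_totals(spectrum: pd.DataFrame) -> pd.Series:
    """Unique alleles per domain (requires a domain-annotated spectrum)."""
    if "domain" not in spectrum or spectrum["domain"].isna().all():
        return pd.Series(dtype=int)
    return spectrum.groupby("domain").size()
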