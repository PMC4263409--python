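"""Model/Results interface over the analysis pipeline.

Two fitted-model entry points in the statsmodels idiom:

* :class:`ParallelEvolutionModel` — built from an
  :class:`~parevo.dataset.ExperimentDataset`; ``fit()`` runs the variant
  cascade (frequency floor, effect selection, MA blacklist, Levene filter)
  and the parallelism/enrichment statistics, returning a
  :class:`ParallelEvolutionResults` with the ranked gene table, mutator
  flags, subsystem scores, per-stage accounting and a ``summary()`` report.
* :class:`ProteomicsDifferentialModel` — built from a
  :class:`~parevo.simulate.PeptideMatrix`; ``fit()`` rolls peptides up to
  proteins, tests each against the ancestor and applies the dual
  significance threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import filtering, parallelism, proteomics, subsystems
from .dataset import ExperimentDataset
from .simulate import PeptideMatrix

__all__ = [
    "PipelineConfig",
    "ParallelEvolutionModel",
    "ParallelEvolutionResults",
    "ProteomicsDifferentialModel",
    "ProteomicsResults",
]


@dataclass
class PipelineConfig:
    """Every stage parameter, serialized verbatim into the provenance log."""

    min_freq: float = 0.05
    nonsynonymous_only: bool = True
    ma_min_lines: int = 4
    #: species the MA blacklist applies to; None = all
    blacklist_species: tuple | None = None
    levene_enabled: bool = True
    #: species the Levene filter applies to; None = all
    levene_species: tuple | None = None
    levene_alpha: float = 0.05
    levene_center: str = "mean"
    levene_min_per_group: int = 2
    levene_absent_as_zero: bool = True
    #: gene products removed outright (e.g. core proteins), empty by default
    gene_product_blacklist: tuple = ()
    #: populations dropped from every statistic (kept in the tables)
    exclude_populations: tuple = ()
    mutator_method: str = "tukey"
    mutator_k: float = 1.5
    exclude_mutators: bool = True
    histogram_cap: int | None = 120
    # proteomics
    rollup_method: str = "mean_of_centered"
    anova_design: str = "two_group"
    p_max: float = 0.01
    min_abs_log2fc: float = 0.7
    p_adjust: str | None = None  # 'bh' for Benjamini-Hochberg
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must lie in (0,1]")
        if self.ma_min_lines < 1:
            raise ValueError("ma_min_lines must be >= 1")
        if not 0 < self.levene_alpha < 1:
            raise ValueError("levene_alpha must lie in (0,1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("blacklist_species", "levene_species", "gene_product_blacklist",
                    "exclude_populations"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ParallelEvolutionResults:
    """Everything the fitted pipeline computed, plus per-stage accounting."""

    config: PipelineConfig
    dataset: ExperimentDataset
    filtered_calls: pd.DataFrame
    stage_counts: list  # [{stage, n_in, n_removed, n_out, ...}, ...]
    blacklist: set
    levene_audit: pd.DataFrame
    matrix: pd.DataFrame
    gene_summary: pd.DataFrame
    histogram: pd.DataFrame
    mutators: set
    mutation_counts: pd.DataFrame  # per population, with species/treatment
    subsystem_scores: dict  # (species, treatment) -> DataFrame
    treatment_summary: pd.DataFrame  # Table-1-style means with 95% CI

    def top_genes(self, n: int = 10) -> pd.DataFrame:
        return self.gene_summary.head(n)

    def cumulative_frequency(
        self, gene_id: str, species: str | None = None, treatment: str | None = None
    ) -> parallelism.GeneFrequencySummary:
        """Cumulative within-gene allele frequency per population.

        Restrict with ``species``/``treatment`` — a gene exists in one
        genome, so unrestricted means average in zeros from the other
        species' populations.
        """
        pops = self._parallelism_populations()
        if species is not None:
            pops = pops[pops.species == species]
        if treatment is not None:
            pops = pops[pops.treatment == treatment]
        return parallelism.cumulative_gene_frequency(
            self.filtered_calls, gene_id, pops.reset_index(drop=True),
            self.dataset.annotation,
        )

    def allele_spectrum(self, gene_id: str, domain_map=None) -> pd.DataFrame:
        return parallelism.unique_allele_spectrum(
            self.filtered_calls, gene_id, self.dataset.annotation, domain_map
        )

    def _parallelism_populations(self) -> pd.DataFrame:
        pops = self.dataset.analyzed_populations()
        if self.config.exclude_mutators:
            pops = pops[~pops.population_id.isin(self.mutators)]
        return pops.reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Parallel-evolution analysis", "=" * 27, ""]
        lines.append("Per-stage variant accounting:")
        for rec in self.stage_counts:
            lines.append(
                f"  {rec['stage']:<22} in={rec['n_in']:<6} removed={rec['n_removed']:<6}"
                f" out={rec['n_out']}"
            )
        lines.append("")
        lines.append("Per-treatment mutation counts (mean +/- 95% CI):")
        lines.append(self.treatment_summary.to_string(index=False, float_format="%.1f"))
        lines.append("")
        if self.mutators:
            lines.append(f"Mutator populations: {', '.join(sorted(self.mutators))}")
            lines.append("")
        lines.append("Most parallel genes:")
        lines.append(self.top_genes(8).to_string(index=False))
        return "\n".join(lines)


class ParallelEvolutionModel:
    """The variant cascade and convergence statistics as a fittable model."""

    def __init__(self, dataset: ExperimentDataset, config: PipelineConfig | None = None):
        self.dataset = dataset
        self.config = config or PipelineConfig()

    @classmethod
    def from_directory(cls, indir, config: PipelineConfig | None = None):
        return cls(ExperimentDataset.read(indir), config)

    def fit(self) -> ParallelEvolutionResults:
        cfg = self.config
        ds = self.dataset
        pops = ds.populations.copy()
        if cfg.exclude_populations:
            pops.loc[pops.population_id.isin(cfg.exclude_populations), "excluded"] = True
        # fresh provenance copy so fitting never mutates the input dataset
        ds = ExperimentDataset(ds.annotation, pops, ds.variants, ds.truth,
                               list(ds.provenance))
        stage_counts: list = []

        def record(stage, before, after, **extra):
            stage_counts.append(
                {"stage": stage, "n_in": int(len(before)),
                 "n_removed": int(len(before) - len(after)),
                 "n_out": int(len(after)), **extra}
            )
            ds.log(stage, n_in=len(before), n_out=len(after), **extra)

        calls = ds.evolved_calls()
        floored = filtering.apply_frequency_floor(calls, cfg.min_freq)
        record("frequency_floor", calls, floored, min_freq=cfg.min_freq)

        if cfg.nonsynonymous_only:
            selected = filtering.select_nonsynonymous(floored)
            record("nonsynonymous_selection", floored, selected)
        else:
            selected = floored

        if cfg.gene_product_blacklist:
            products = ds.annotation.genes.set_index("gene_id")["product"]
            banned = set(
                products.index[products.isin(set(cfg.gene_product_blacklist))]
            )
            kept = selected[~selected.gene_id.isin(banned)]
            record("gene_product_blacklist", selected, kept, n_genes=len(banned))
            selected = kept

        species_col = ds.populations.set_index("population_id")["species"]
        ma_calls = filtering.apply_frequency_floor(ds.ma_calls(), cfg.min_freq)
        if cfg.blacklist_species is not None:
            ma_calls = ma_calls[
                ma_calls.population_id.map(species_col).isin(cfg.blacklist_species)
            ]
        blacklist = filtering.build_ma_blacklist(ma_calls, cfg.ma_min_lines)
        after_bl, bl_counts = filtering.apply_blacklist(
            selected, blacklist, ds.populations
        )
        record("ma_blacklist", selected, after_bl,
               n_sites=len(blacklist), **bl_counts)

        levene_audit = pd.DataFrame()
        final = after_bl
        if cfg.levene_enabled:
            target = after_bl
            if cfg.levene_species is not None:
                in_scope = target.population_id.map(species_col).isin(cfg.levene_species)
                scope, rest = target[in_scope], target[~in_scope]
            else:
                scope, rest = target, target.iloc[0:0]
            kept, removed, levene_audit = filtering.levene_artifact_filter(
                ds, scope,
                alpha=cfg.levene_alpha,
                min_per_group=cfg.levene_min_per_group,
                center=cfg.levene_center,
                absent_as_zero=cfg.levene_absent_as_zero,
            )
            final = pd.concat([kept, rest], ignore_index=True)
            record("levene_filter", target, final,
                   n_sites_removed=len(removed), alpha=cfg.levene_alpha)
        final = final.reset_index(drop=True)

        # per-population counts and mutator flags (on the filtered calls)
        pops = ds.analyzed_populations()
        counts = (
            final.groupby("population_id").size()
            .reindex(pops.population_id, fill_value=0)
        )
        meta = pops.set_index("population_id")
        group = meta["species"] + ":" + meta["treatment"]
        mutators = parallelism.flag_mutators(
            counts, group, method=cfg.mutator_method, k=cfg.mutator_k
        )

        # parallelism over non-mutator analyzed populations
        par_pops = pops[~pops.population_id.isin(mutators)] if cfg.exclude_mutators else pops
        par_calls = final[final.population_id.isin(set(par_pops.population_id))]
        matrix = parallelism.gene_mutation_matrix(par_calls, ds.annotation, par_pops)
        gene_summary = parallelism.parallelism_summary(matrix, par_pops, par_calls)
        histogram = parallelism.parallelism_histogram(matrix, cap=cfg.histogram_cap)

        # subsystem scores per species x treatment
        sub_scores = {}
        for (sp, tr), sub in par_pops.groupby(["species", "treatment"]):
            sub_calls = par_calls[par_calls.population_id.isin(set(sub.population_id))]
            ann = ds.annotation
            sp_genes = ann.genes[ann.genes.gene_id.str.startswith(f"{sp}_")]
            if len(sp_genes) == 0:  # single shared catalogue
                sp_ann = ann
            else:
                from .annotation import GenomeAnnotation
                sp_ann = GenomeAnnotation(sp_genes.reset_index(drop=True))
            m = parallelism.gene_mutation_matrix(sub_calls, sp_ann, sub)
            sub_scores[(sp, tr)] = subsystems.subsystem_score(m, sp_ann)

        mutation_counts = meta.assign(n_mutations=counts).reset_index()
        treatment_summary = _treatment_summary(mutation_counts, mutators)

        return ParallelEvolutionResults(
            config=cfg,
            dataset=ds,
            filtered_calls=final,
            stage_counts=stage_counts,
            blacklist=blacklist,
            levene_audit=levene_audit,
            matrix=matrix,
            gene_summary=gene_summary,
            histogram=histogram,
            mutators=mutators,
            mutation_counts=mutation_counts,
            subsystem_scores=sub_scores,
            treatment_summary=treatment_summary,
        )


def _treatment_summary(mutation_counts: pd.DataFrame, mutators: set) -> pd.DataFrame:
    """Mean mutation count per species x treatment with normal 95% CI."""
    rows = []
    for (sp, tr), sub in mutation_counts.groupby(["species", "treatment"]):
        for label, s in (
            ("all", sub),
            ("non-mutator", sub[~sub.population_id.isin(mutators)]),
        ):
            n = len(s)
            mean = s.n_mutations.mean() if n else float("nan")
            sd = s.n_mutations.std(ddof=1) if n > 1 else float("nan")
            rows.append(
                {
                    "species": sp,
                    "treatment": tr,
                    "populations": label,
                    "n": n,
                    "mean_mutations": mean,
                    "ci95_halfwidth": 1.96 * sd / n**0.5 if n > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proteomics

@dataclass
class ProteomicsResults:
    config: PipelineConfig
    protein_matrix: pd.DataFrame
    records: pd.DataFrame
    heatmap_table: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.records[self.records.significant]

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Proteomics differential abundance",
            "=" * 33,
            f"proteins tested:      {int(self.records.testable.sum())} of {len(self.records)}",
            f"significant:          {c['n_significant']}"
            f" (p <= {self.config.p_max}, |log2FC| > {self.config.min_abs_log2fc})",
            f"  increased:          {c['n_up']}",
            f"  decreased:          {c['n_down']}",
        ]
        return "\n".join(lines)


class ProteomicsDifferentialModel:
    """Peptide roll-up + ancestor-vs-evolved differential test as a model."""

    def __init__(
        self,
        peptides: PeptideMatrix,
        protein_classes: pd.Series | None = None,
        config: PipelineConfig | None = None,
    ):
        self.peptides = peptides
        self.protein_classes = protein_classes
        self.config = config or PipelineConfig()

    def fit(self) -> ProteomicsResults:
        cfg = self.config
        protein_matrix = proteomics.rollup_proteins(
            self.peptides, method=cfg.rollup_method
        )
        records = proteomics.differential_test(
            protein_matrix, self.peptides.sample_groups, design=cfg.anova_design
        )
        records = proteomics.significance_filter(
            records, p_max=cfg.p_max, min_abs_log2fc=cfg.min_abs_log2fc,
            p_adjust=cfg.p_adjust,
        )
        heat = proteomics.functional_heatmap_table(records, self.protein_classes)
        return ProteomicsResults(
            config=cfg,
            protein_matrix=protein_matrix,
            records=records,
            heatmap_table=heat,
            counts=proteomics.direction_counts(records),
        )
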