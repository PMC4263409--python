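"""Synthetic evolve-and-resequence experiments and proteomes.

The generator emulates the design the downstream analysis assumes: two
bacterial species each evolved as 12 replicate populations per medium
(LB/BHI), a panel of mutation-accumulation (MA) control lines per species,
one or two "global regulator" driver genes accumulating several
co-segregating alleles per population (cumulative frequency centred near
0.75), a loss-of-function-biased allele spectrum for one driver in one
medium, systematic artifact sites present at near-identical frequency in
every sample, and a peptide abundance matrix with planted up- and
down-regulated protein groups.

It is an arrival-count model, not a Wright–Fisher simulation: only
final-timepoint frequency tables are analyzed downstream, so mutation
counts are Poisson, frequencies are Beta/Dirichlet draws, and pooled
sequencing noise is binomial resampling at a fixed depth.  All randomness
flows from one master seed through named substreams, so any stage can be
regenerated alone.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .dataset import ExperimentDataset
from .variants import VARIANT_COLUMNS, empty_variants

__all__ = [
    "DriverSpec",
    "SimulationConfig",
    "PeptideMatrix",
    "simulate_genome",
    "simulate_experiment",
    "simulate_peptides",
    "generations_from_dilution",
    "generations_per_transfer_from_cells",
    "default_subsystem_catalogue",
    "make_planted_proteome",
]


# ---------------------------------------------------------------------------
# seeding

def substream(seed: int, *names) -> np.random.Generator:
    """Independent generator for a named stage under one master seed."""
    keys = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DriverSpec:
    """A repeatedly-hit adaptive target gene.

    ``hit_probability`` and ``lof_bias`` are per-treatment maps; a hit
    population carries ``1 + Poisson(allele_kappa)`` distinct alleles whose
    frequencies partition (Dirichlet) a cumulative frequency drawn from
    ``Beta(cumulative_beta)``.  ``lof_bias`` is the probability that an
    allele is loss-of-function (stop or frameshift) rather than a
    substitution.
    """

    name: str
    gene_index: int
    hit_probability: dict = field(default_factory=lambda: {"LB": 1.0, "BHI": 0.75})
    allele_kappa: float = 2.0
    cumulative_beta: tuple = (21.0, 7.0)  # mean 0.75, sd ~0.08
    lof_bias: dict = field(default_factory=dict)
    allele_pool_size: int = 40

    def __post_init__(self):
        for p in self.hit_probability.values():
            if not 0 <= p <= 1:
                raise ValueError("hit_probability outside [0,1]")
        for p in self.lof_bias.values():
            if not 0 <= p <= 1:
                raise ValueError("lof_bias outside [0,1]")
        if self.allele_kappa < 0:
            raise ValueError("allele_kappa must be >= 0")
        a, b = self.cumulative_beta
        if not (a > 0 and b > 0):
            raise ValueError("cumulative_beta parameters must be positive")


def _default_drivers() -> tuple:
    # arcA-like: hit in every LB population, most BHI populations, never LOF;
    # rpoS-like: less penetrant, strongly LOF-biased in BHI.
    return (
        DriverSpec(
            name="arcA_like",
            gene_index=10,
            hit_probability={"LB": 1.0, "BHI": 0.75},
            lof_bias={"LB": 0.0, "BHI": 0.0},
        ),
        DriverSpec(
            name="rpoS_like",
            gene_index=20,
            hit_probability={"LB": 0.5, "BHI": 0.75},
            lof_bias={"LB": 0.2, "BHI": 0.8},
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full design of one synthetic evolve-and-resequence experiment.

    Defaults are desk-scale (500/550 genes); ``n_genes_per_species=(4565,
    5068)`` reproduces genome-scale gene counts.
    """

    seed: int = 0
    n_genes_per_species: tuple = (500, 550)
    species_labels: tuple = ("sp1", "sp2")
    gene_length_dist: tuple = (5.63, 0.35)  # log-normal (mu, sigma), codons
    n_populations_per_treatment: int = 12
    treatments: tuple = ("LB", "BHI")
    n_ma_lines: int = 12
    neutral_rate: float = 15.0  # expected non-synonymous mutations / population
    synonymous_ratio: float = 1 / 3  # synonymous per non-synonymous
    mutator_populations: tuple = (("LB", 4), ("LB", 11), ("BHI", 6), ("BHI", 10))
    mutator_multiplier: float = 8.0
    driver_genes: tuple = field(default_factory=_default_drivers)
    artifact_sites: int = 30
    artifact_base_frequency: float = 0.12
    artifact_noise: float = 0.005
    ma_rate: float = 8.0
    detection_floor: float = 0.05
    coverage_depth: int = 200
    n_subsystems: int = 20

    def __post_init__(self):
        if min(self.neutral_rate, self.ma_rate, self.synonymous_ratio) < 0:
            raise ValueError("rates must be >= 0")
        if not self.treatments:
            raise ValueError("treatments must be non-empty")
        f0, sa = self.artifact_base_frequency, self.artifact_noise
        if not (0 < f0 - 5 * sa and f0 + 5 * sa < 1):
            raise ValueError("artifact_base_frequency +/- 5 sigma must lie in (0,1)")
        if not 0 < self.detection_floor <= 1:
            raise ValueError("detection_floor must lie in (0,1]")
        for d in self.driver_genes:
            if not all(0 <= d.gene_index < n for n in self.n_genes_per_species):
                raise ValueError(f"driver gene_index {d.gene_index} outside gene range")
        for t, _ in self.mutator_populations:
            if t not in self.treatments:
                raise ValueError(f"mutator treatment {t!r} not in treatments")


def default_subsystem_catalogue(n_subsystems: int = 20) -> dict:
    """subsystem -> category map with SEED-like category names."""
    categories = [
        "Carbohydrates",
        "Amino Acids and Derivatives",
        "Protein Metabolism",
        "Membrane Transport",
        "Stress Response",
        "Respiration",
    ]
    return {
        f"subsystem_{i:02d}": categories[i % len(categories)]
        for i in range(n_subsystems)
    }


# ---------------------------------------------------------------------------
# genome

def simulate_genome(
    n_genes: int,
    length_dist: tuple = (5.63, 0.35),
    subsystem_catalogue: dict | None = None,
    seed: int = 0,
    species: str = "sp1",
) -> GenomeAnnotation:
    """Tile ``n_genes`` genes along one contig with >=1 nt intergenic gaps.

    Gene lengths are log-normal in codons (so always divisible by 3);
    every gene is assigned one subsystem from the catalogue, so subsystems
    partition the gene set.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if subsystem_catalogue is None:
        subsystem_catalogue = default_subsystem_catalogue()
    rng = substream(seed, "genome", species)
    mu, sigma = length_dist
    codons = np.maximum(2, np.round(rng.lognormal(mu, sigma, n_genes))).astype(int)
    lengths = 3 * codons
    gaps = 1 + rng.poisson(80, n_genes)
    subsystems = list(subsystem_catalogue)
    assigned = rng.choice(len(subsystems), n_genes)
    start = 1
    rows = []
    contig = f"{species}_contig"
    for i in range(n_genes):
        start = start + int(gaps[i])
        end = start + int(lengths[i]) - 1
        sub = subsystems[assigned[i]]
        rows.append(
            {
                "gene_id": f"{species}_g{i:05d}",
                "contig": contig,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.8 else "-",
                "product": f"hypothetical protein {i}",
                "subsystem": sub,
                "category": subsystem_catalogue[sub],
            }
        )
        start = end + 1
    return GenomeAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# experiment

_BASES = np.array(list("ACGT"))


def _random_snp(rng) -> tuple:
    ref, alt = rng.choice(4, 2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _draw_effects(rng, n: int) -> np.ndarray:
    """Effect classes of neutral non-synonymous variants."""
    return rng.choice(
        ["nonsynonymous", "stop_gained", "frameshift"], n, p=[0.85, 0.05, 0.10]
    )


def _sample_sites(rng, annotation: GenomeAnnotation, n: int) -> pd.DataFrame:
    """Uniform coding positions: genes weighted by length, offset uniform."""
    genes = annotation.genes
    lengths = (genes.end - genes.start + 1).to_numpy()
    probs = lengths / lengths.sum()
    idx = rng.choice(len(genes), n, p=probs)
    offsets = rng.integers(0, lengths[idx])
    picked = genes.iloc[idx]
    return pd.DataFrame(
        {
            "contig": picked.contig.to_numpy(),
            "position": picked.start.to_numpy() + offsets,
            "gene_id": picked.gene_id.to_numpy(),
        }
    )


def _binomial_frequency(rng, f: np.ndarray, depth: int) -> np.ndarray:
    return rng.binomial(depth, np.clip(f, 0, 1)) / depth


def _variant_rows(sites, refs, alts, vtypes, effects, freqs, population_id):
    return pd.DataFrame(
        {
            "population_id": population_id,
            "contig": sites["contig"].to_numpy(),
            "position": sites["position"].to_numpy(),
            "ref": refs,
            "alt": alts,
            "vtype": vtypes,
            "gene_id": sites["gene_id"].to_numpy(),
            "effect": effects,
            "frequency": freqs,
        }
    )[VARIANT_COLUMNS]


def _driver_allele_pool(rng, spec: DriverSpec, gene: pd.Series, treatment: str) -> pd.DataFrame:
    """Candidate alleles for one driver gene in one medium.

    The pool is shared by all populations of the medium, so the same allele
    recurs across independently evolved replicates (the parallelism signal);
    a pool is medium-specific so allele identity never crosses treatments.
    """
    length = int(gene.end - gene.start + 1)
    n = min(spec.allele_pool_size, length)
    offsets = rng.choice(length, n, replace=False)
    lof_p = spec.lof_bias.get(treatment, 0.0)
    rows = []
    for off in offsets:
        if rng.random() < lof_p:
            if rng.random() < 0.5:
                ref, alt, vtype, effect = *_random_snp(rng), "snp", "stop_gained"
            else:
                ref = str(_BASES[rng.integers(4)])
                alt, vtype, effect = "-", "deletion", "frameshift"
        else:
            ref, alt = _random_snp(rng)
            vtype, effect = "snp", "nonsynonymous"
        rows.append(
            {
                "contig": gene.contig,
                "position": int(gene.start + off),
                "gene_id": gene.gene_id,
                "ref": ref,
                "alt": alt,
                "vtype": vtype,
                "effect": effect,
            }
        )
    return pd.DataFrame(rows).drop_duplicates(["position", "alt"]).reset_index(drop=True)


def _neutral_calls(rng, annotation, rate, syn_ratio, depth, floor, population_id):
    parts = []
    n_ns = rng.poisson(rate)
    if n_ns:
        sites = _sample_sites(rng, annotation, n_ns)
        effects = _draw_effects(rng, n_ns)
        refs, alts, vtypes = [], [], []
        for e in effects:
            if e == "frameshift":
                refs.append(str(_BASES[rng.integers(4)]))
                alts.append("-")
                vtypes.append("deletion")
            else:
                r, a = _random_snp(rng)
                refs.append(r)
                alts.append(a)
                vtypes.append("snp")
        parts.append((sites, refs, alts, vtypes, effects))
    n_syn = rng.poisson(rate * syn_ratio)
    if n_syn:
        sites = _sample_sites(rng, annotation, n_syn)
        refs, alts = zip(*(_random_snp(rng) for _ in range(n_syn)))
        parts.append(
            (sites, list(refs), list(alts), ["snp"] * n_syn, ["synonymous"] * n_syn)
        )
    out = []
    for sites, refs, alts, vtypes, effects in parts:
        raw = rng.beta(1, 9, len(sites))
        freqs = _binomial_frequency(rng, raw, depth)
        keep = freqs >= floor
        if keep.any():
            out.append(
                _variant_rows(
                    sites[keep].reset_index(drop=True),
                    np.asarray(refs)[keep],
                    np.asarray(alts)[keep],
                    np.asarray(vtypes)[keep],
                    np.asarray(effects)[keep],
                    freqs[keep],
                    population_id,
                )
            )
    return pd.concat(out, ignore_index=True) if out else empty_variants()


def simulate_experiment(
    config: SimulationConfig,
    genomes: tuple | None = None,
) -> ExperimentDataset:
    """Generate a complete two-species evolve-and-resequence dataset.

    Per evolved population: Poisson neutral variants (rate multiplied for
    mutator populations), driver-gene allele clusters, and the shared
    artifact sites.  Per MA line: private near-fixed variants plus the same
    artifact sites.  Every emitted variant is truth-labelled
    (driver/neutral/artifact/ma_private in ``dataset.truth``).
    """
    seed = config.seed
    if genomes is None:
        genomes = tuple(
            simulate_genome(
                n,
                config.gene_length_dist,
                default_subsystem_catalogue(config.n_subsystems),
                seed=seed,
                species=label,
            )
            for n, label in zip(config.n_genes_per_species, config.species_labels)
        )
    mutators = {(t, r): config.mutator_multiplier for t, r in config.mutator_populations}

    pop_rows, call_frames, truth_rows = [], [], []
    for annotation, species in zip(genomes, config.species_labels):
        contig = annotation.genes.contig.iloc[0]

        # shared artifact sites: every sample of this species carries them
        art_rng = substream(seed, "artifacts", species)
        art_sites = _sample_sites(art_rng, annotation, config.artifact_sites)
        art_sites = art_sites.drop_duplicates("position").reset_index(drop=True)
        art_alleles = [_random_snp(art_rng) for _ in range(len(art_sites))]
        for (_, s), (r, a) in zip(art_sites.iterrows(), art_alleles):
            truth_rows.append((s.contig, int(s.position), a, "artifact"))

        def artifact_calls(rng, population_id):
            if len(art_sites) == 0:
                return empty_variants()
            freqs = np.clip(
                config.artifact_base_frequency
                + rng.normal(0, config.artifact_noise, len(art_sites)),
                1e-4,
                1 - 1e-4,
            )
            refs = [r for r, _ in art_alleles]
            alts = [a for _, a in art_alleles]
            return _variant_rows(
                art_sites, refs, alts, ["snp"] * len(art_sites),
                ["nonsynonymous"] * len(art_sites), freqs, population_id,
            )

        # per-medium driver allele pools
        pools = {}
        for spec in config.driver_genes:
            gene = annotation.genes.iloc[spec.gene_index]
            for treatment in config.treatments:
                pools[(spec.name, treatment)] = _driver_allele_pool(
                    substream(seed, "driverpool", species, spec.name, treatment),
                    spec, gene, treatment,
                )

        # evolved populations
        for treatment in config.treatments:
            for rep in range(1, config.n_populations_per_treatment + 1):
                pid = f"{species}_{treatment}_{rep:02d}"
                mult = mutators.get((treatment, rep), 1.0)
                pop_rows.append((pid, species, treatment, rep, False, False))
                rng = substream(seed, "population", species, treatment, rep)
                calls = [
                    _neutral_calls(
                        rng, annotation, config.neutral_rate * mult,
                        config.synonymous_ratio, config.coverage_depth,
                        config.detection_floor, pid,
                    ),
                    artifact_calls(rng, pid),
                ]
                for spec in config.driver_genes:
                    p_hit = spec.hit_probability.get(treatment, 0.0)
                    if rng.random() >= p_hit:
                        continue
                    pool = pools[(spec.name, treatment)]
                    k = min(1 + rng.poisson(spec.allele_kappa), len(pool))
                    chosen = pool.iloc[rng.choice(len(pool), k, replace=False)]
                    total = rng.beta(*spec.cumulative_beta)
                    freqs = total * rng.dirichlet(np.ones(k))
                    keep = freqs >= config.detection_floor
                    chosen = chosen[keep]
                    if len(chosen) == 0:
                        continue
                    calls.append(
                        _variant_rows(
                            chosen.reset_index(drop=True),
                            chosen.ref.to_numpy(), chosen.alt.to_numpy(),
                            chosen.vtype.to_numpy(), chosen.effect.to_numpy(),
                            freqs[keep], pid,
                        )
                    )
                call_frames.extend(calls)

        # MA control lines
        for i in range(1, config.n_ma_lines + 1):
            pid = f"{species}_MA_{i:02d}"
            pop_rows.append((pid, species, "MA", i, True, False))
            rng = substream(seed, "maline", species, i)
            n = rng.poisson(config.ma_rate)
            if n:
                sites = _sample_sites(rng, annotation, n)
                effects = _draw_effects(rng, n)
                refs, alts, vtypes = [], [], []
                for e in effects:
                    if e == "frameshift":
                        refs.append(str(_BASES[rng.integers(4)]))
                        alts.append("-")
                        vtypes.append("deletion")
                    else:
                        r, a = _random_snp(rng)
                        refs.append(r)
                        alts.append(a)
                        vtypes.append("snp")
                freqs = rng.uniform(0.8, 1.0, n)
                call_frames.append(
                    _variant_rows(sites, refs, alts, vtypes, effects, freqs, pid)
                )
                for s, a in zip(sites.itertuples(index=False), alts):
                    truth_rows.append((s.contig, int(s.position), a, "ma_private"))
            call_frames.append(artifact_calls(rng, pid))

        # truth labels for drivers and neutrals of this species
        for (name, treatment), pool in pools.items():
            for row in pool.itertuples(index=False):
                truth_rows.append((row.contig, int(row.position), row.alt, "driver"))

    variants = (
        pd.concat([f for f in call_frames if f is not None and len(f)], ignore_index=True)
        if any(f is not None and len(f) for f in call_frames)
        else empty_variants()
    )
    populations = pd.DataFrame(
        pop_rows,
        columns=["population_id", "species", "treatment", "replicate", "is_ma", "excluded"],
    )

    # neutral = everything not otherwise labelled
    truth = pd.DataFrame(truth_rows, columns=["contig", "position", "alt", "role"])
    truth = truth.drop_duplicates(["contig", "position", "alt"])
    labelled = set(zip(truth.contig, truth.position, truth.alt))
    neutral_keys = {
        (c, int(p), a)
        for c, p, a in zip(variants.contig, variants.position, variants.alt)
        if (c, int(p), a) not in labelled
    }
    if neutral_keys:
        extra = pd.DataFrame(
            sorted(neutral_keys), columns=["contig", "position", "alt"]
        )
        extra["role"] = "neutral"
        truth = pd.concat([truth, extra], ignore_index=True)
    truth = truth.sort_values(["contig", "position", "alt"]).reset_index(drop=True)

    from .annotation import concat_annotations

    dataset = ExperimentDataset(
        annotation=concat_annotations(genomes),
        populations=populations,
        variants=variants.reset_index(drop=True),
        truth=truth,
    )
    dataset.log(
        "simulate",
        seed=seed,
        n_variants=len(variants),
        n_populations=len(populations),
    )
    return dataset


def truth_role_of(dataset: ExperimentDataset, calls: pd.DataFrame) -> pd.Series:
    """Truth role for each call row, via the (contig, position, alt) key."""
    if dataset.truth is None:
        raise ValueError("dataset carries no truth labels")
    key = dataset.truth.set_index(["contig", "position", "alt"])["role"]
    idx = pd.MultiIndex.from_arrays([calls.contig, calls.position, calls.alt])
    return pd.Series(key.reindex(idx).to_numpy(), index=calls.index)


# ---------------------------------------------------------------------------
# generation arithmetic

def generations_from_dilution(dilution_factor: float, n_transfers: int) -> tuple:
    """Generations implied by serial batch transfer at a fixed dilution.

    A culture diluted D-fold must double log2(D) times to regrow to
    saturation, so per-transfer generations are ``log2(D)`` and the total is
    ``n_transfers * log2(D)`` (100-fold daily dilution ~ 6.6 generations/day).
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    if n_transfers < 0:
        raise ValueError("n_transfers must be >= 0")
    per = math.log2(dilution_factor)
    return per, n_transfers * per


def generations_per_transfer_from_cells(cells_per_colony: float) -> float:
    """Doublings from one cell to a colony of ``cells_per_colony`` cells."""
    if cells_per_colony < 1:
        raise ValueError("cells_per_colony must be >= 1")
    return math.log2(cells_per_colony)


# ---------------------------------------------------------------------------
# proteomics

@dataclass
class PeptideMatrix:
    """Peptide-level log2 abundances with protein map and sample groups.

    ``abundances``: peptides x samples, NaN = not observed.
    ``protein_map``: peptide id -> protein id (every peptide maps once).
    ``sample_groups``: sample id -> group label ('ancestor' or a population).
    """

    abundances: pd.DataFrame
    protein_map: pd.Series
    sample_groups: pd.Series

    def __post_init__(self):
        unmapped = set(self.abundances.index) - set(self.protein_map.index)
        if unmapped:
            raise ValueError(f"peptides without protein mapping: {sorted(unmapped)[:5]}")
        if (self.sample_groups == "ancestor").sum() < 2:
            raise ValueError("need >=2 ancestor replicates")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundances.to_csv(outdir / "peptides.csv")
        self.protein_map.rename("protein").rename_axis("peptide").reset_index().to_csv(
            outdir / "peptide_map.tsv", sep="\t", index=False
        )
        self.sample_groups.rename("group").rename_axis("sample").reset_index().to_csv(
            outdir / "sample_groups.tsv", sep="\t", index=False
        )

    @classmethod
    def read(cls, peptides_csv, map_tsv, groups_tsv) -> "PeptideMatrix":
        ab = pd.read_csv(peptides_csv, index_col=0)
        pm = pd.read_csv(map_tsv, sep="\t").set_index("peptide")["protein"]
        gr = pd.read_csv(groups_tsv, sep="\t").set_index("sample")["group"]
        return cls(ab, pm, gr.loc[ab.columns])


def default_peptide_design(n_populations: int = 12, n_replicates: int = 3) -> dict:
    """Ancestor + evolved populations, each with replicate LC-MS runs."""
    design = {"ancestor": n_replicates}
    for i in range(1, n_populations + 1):
        design[f"pop{i:02d}"] = n_replicates
    return design


def make_planted_proteome(
    n_proteins: int = 488,
    n_up: int = 108,
    n_down: int = 58,
    effect_range: tuple = (0.9, 2.5),
    seed: int = 0,
) -> tuple:
    """Planted differential design: TCA-cycle-like up, chaperone-like down.

    Returns ``(planted_effects, protein_classes)``: a protein -> log2 effect
    map (0 for null proteins) and a protein -> functional class map.
    """
    if n_up + n_down > n_proteins:
        raise ValueError("more planted effects than proteins")
    rng = substream(seed, "proteome-design")
    proteins = [f"prot{i:04d}" for i in range(n_proteins)]
    order = rng.permutation(n_proteins)
    up = [proteins[i] for i in order[:n_up]]
    down = [proteins[i] for i in order[n_up : n_up + n_down]]
    lo, hi = effect_range
    effects = {p: 0.0 for p in proteins}
    classes = {p: "other" for p in proteins}
    for p in up:
        effects[p] = float(rng.uniform(lo, hi))
        classes[p] = "TCA cycle"
    for p in down:
        effects[p] = -float(rng.uniform(lo, hi))
        classes[p] = "chaperones"
    return effects, pd.Series(classes, name="class")


def simulate_peptides(
    n_proteins: int = 488,
    peptides_per_protein: float = 8.0,
    group_design: dict | None = None,
    planted_effects: dict | None = None,
    noise_sd: float = 0.1,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple:
    """Synthetic peptide log2 abundance matrix with planted group effects.

    Each peptide's log2 abundance is protein baseline + planted group
    effect + peptide offset + Normal(0, noise_sd); entries go missing
    independently at ``missing_rate``.  ``planted_effects`` maps protein ->
    scalar effect (applied to every non-ancestor group) or protein ->
    {group: effect}.  Returns ``(PeptideMatrix, truth)`` where truth is a
    protein-indexed Series of overall planted log2 effects.
    """
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0,1]")
    if group_design is None:
        group_design = default_peptide_design()
    if "ancestor" not in group_design or group_design["ancestor"] < 2:
        raise ValueError("group_design needs an ancestor group with >=2 replicates")
    if len(group_design) < 2:
        raise ValueError("group_design needs >=1 evolved group")
    planted_effects = planted_effects or {}

    rng = substream(seed, "peptides")
    proteins = [f"prot{i:04d}" for i in range(n_proteins)]
    n_pep = 1 + rng.poisson(max(peptides_per_protein - 1, 0), n_proteins)
    baselines = rng.normal(25.0, 2.0, n_proteins)

    samples, groups = [], []
    for g, n in group_design.items():
        for r in range(1, n + 1):
            samples.append(f"{g}_r{r}")
            groups.append(g)
    sample_groups = pd.Series(groups, index=samples, name="group")

    def effect_of(protein, group):
        if group == "ancestor":
            return 0.0
        e = planted_effects.get(protein, 0.0)
        if isinstance(e, dict):
            return float(e.get(group, 0.0))
        return float(e)

    pep_ids, pep_prot, rows = [], [], []
    for p, prot in enumerate(proteins):
        offsets = rng.normal(0, 1.0, n_pep[p])
        group_eff = np.array([effect_of(prot, g) for g in groups])
        for j in range(n_pep[p]):
            pep = f"{prot}_pep{j:02d}"
            pep_ids.append(pep)
            pep_prot.append(prot)
            rows.append(
                baselines[p]
                + offsets[j]
                + group_eff
                + (rng.normal(0, noise_sd, len(samples)) if noise_sd > 0 else 0.0)
            )
    ab = pd.DataFrame(np.vstack(rows), index=pep_ids, columns=samples)
    if missing_rate > 0:
        mask = rng.random(ab.shape) < missing_rate
        ab = ab.mask(mask)

    truth = pd.Series(
        {
            prot: (
                float(np.mean(list(planted_effects[prot].values())))
                if isinstance(planted_effects.get(prot), dict)
                else float(planted_effects.get(prot, 0.0))
            )
            for prot in proteins
        },
        name="planted_log2fc",
    )
    matrix = PeptideMatrix(ab, pd.Series(pep_prot, index=pep_ids), sample_groups)
    return matrix, truth
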