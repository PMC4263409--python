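# Methods

## Scope and model of the data

`parevo` analyses final-timepoint frequency tables from pooled sequencing
of experimentally evolved bacterial populations. It does not model
trajectories through time: every statistic is a function of the
(population, site, allele, frequency) table, the population design table
(species, medium, replicate, MA flag, exclusion flag) and a gene catalogue
with a gene → subsystem → category hierarchy. Read alignment, variant
calling and genome annotation are upstream of the package; the canonical
input is the tab-delimited variant dialect (`parevo.variants`), with a
VCF reader for convenience.

## The synthetic experiment generator

The generator produces data with the statistical structure the filters
assume, not a population-genetic simulation. This is a deliberate choice:
since only final frequencies are analysed, an arrival-count model is
sufficient and transparent, and its truth labels are exact.

* **Genomes.** Each species' genes tile one contig with ≥ 1 nt intergenic
  gaps. Gene lengths are log-normal in codons (μ = 5.63, σ = 0.35, a mean
  near 280 codons, typical of bacterial proteins); every gene gets one
  subsystem from a configurable catalogue, so subsystems partition the
  genome. Desk-scale defaults are 500/550 genes; genome scale (4565/5068)
  is a constructor argument away.
* **Neutral variants.** Counts per population are Poisson(λ), λ = 15
  non-synonymous arrivals by default (the observed order of magnitude in
  rich-medium evolution experiments of a few hundred generations), placed
  at length-weighted uniform coding positions. Frequencies are Beta(1, 9)
  (most hitchhikers are rare), resampled as Binomial(depth, f)/depth with
  depth = 200 to model pooled-sequencing sampling noise, and truncated at
  the detection floor of 0.05 — an undetected arrival is simply absent.
  Synonymous variants are added at a 1:3 ratio to non-synonymous purely to
  exercise the effect filter.
* **Mutators.** Two populations per medium (replicates 4/11 in LB, 6/10 in
  BHI) draw neutral counts at 8× λ.
* **Driver genes.** The arcA-like driver is hit with probability 1.0 in LB
  and 0.75 in BHI; the rpoS-like driver with probability 0.5/0.75 and a
  loss-of-function bias of 0.8 in BHI (alleles become stops or
  frameshifts). A hit population carries 1 + Poisson(2) distinct alleles
  whose frequencies are a flat-Dirichlet partition of a cumulative
  frequency drawn from Beta(21, 7) — mean 0.75, sd ≈ 0.08, matching the
  "most of the population carries some allele of this gene" regime.
  Alleles are drawn from a per-(gene, medium) candidate pool of 40 sites,
  so the same allele recurs across replicate populations of a medium (the
  recurrence the allele-spectrum panel displays) but never across media.
  The medium-specific pools follow from the medium-specific
  loss-of-function bias, and they keep genuinely adaptive sites out of the
  cross-medium Levene comparison: a site absent from one medium is
  untestable there and is retained, which is the filter's intent.
* **Artifacts.** A = 30 sites per species appear in *every* population and
  MA line of that species at frequency f₀ + N(0, σ_a), f₀ = 0.12,
  σ_a = 0.005, clipped to (0, 1) — the "same frequency everywhere"
  signature of systematic errors. No binomial resampling is added on top;
  σ_a already stands for the combined technical spread.
* **MA lines.** Each species has its own panel of 12 MA lines (the
  blacklist is keyed by contig and position, so a panel can only vouch for
  its own genome). Lines carry Poisson(8) private variants at frequencies
  Uniform(0.8, 1.0) — near-fixed but deliberately not 1.0, since colonies
  grown for DNA extraction can be slightly polymorphic.
* **Determinism.** All draws flow from one master seed through named
  substreams (`substream(seed, "population", species, medium, replicate)`
  etc.), so any stage regenerates alone and serialized datasets are
  byte-identical across runs.
* **Peptide matrices.** log2 abundance = protein baseline N(25, 2) +
  peptide offset N(0, 1) + planted group effect + N(0, noise_sd), with
  independent missingness. The planted design mirrors the proteome
  analysis the package targets: 488 proteins, 108 up-regulated
  (TCA-cycle-like class) and 58 down-regulated (chaperone-like), effect
  magnitudes Uniform(0.9, 2.5), ancestor + 12 populations × 3 replicates.

What the generator does **not** emulate: linkage and clonal interference,
time-resolved frequency trajectories, sequence context (no FASTQ, no real
codons at simulated sites), alignment-induced error structure beyond the
flat artifact model, and correlated peptide missingness. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
its own statistical assumptions — not that those assumptions exhaust real
sequencing pathologies.

## Filtering decisions

* The frequency floor is **inclusive** (≥ 0.05): a "minimum frequency" is
  read as attainable.
* The MA blacklist counts **lines, not calls** (two alleles of one site in
  one line count once) and is keyed by site, not allele: artifacts are a
  property of the locus. The default threshold is 4 lines.
* Levene's test uses the group **mean** as center by default (the
  original test); the median (Brown–Forsythe) is a config switch. The
  implementation is direct from the W formula; scipy's implementation is
  used in the test suite as an independent cross-check only. Degenerate
  inputs: zero spread in every group gives W = 0, p = 1 (no evidence of
  difference); zero within-group spread with non-zero between-group spread
  gives W = ∞, p = 0; any group with fewer than two observations makes the
  site untestable, and untestable sites are **retained** (conservative for
  discovery).
* A site enters the Levene comparison only when observed in ≥ 2
  populations of **each** medium; populations lacking the call contribute
  frequency 0 (absence is informative — it makes medium-restricted
  variants high-spread and ubiquitous artifacts low-spread). Dropping
  absent populations instead is a config option. α defaults to 0.05 and is
  logged; the filter can be restricted per species, since a blacklist-only
  strategy is preferable when MA controls exist for that genome.
* Per-population frequencies at a site are summed over alleles and capped
  at 1 for the Levene vectors only; everywhere else cumulative sums > 1
  are reported raw with an `exceeds_one` flag rather than capped, so data
  problems stay visible.
* Mutator populations are flagged per species × medium by Tukey fence
  (count > Q3 + 1.5·IQR; a median-multiple rule is available). Flagged
  populations are **excluded from parallelism counting by default**: with
  a mutation-rate multiplier of ~8 they would otherwise push neutral genes
  into multi-population presence counts and drown the convergence signal.
  They remain in the mutation-count report, which presents per-medium
  means with and without them (normal-approximation 95% CI,
  mean ± 1.96·sd/√n).

## Parallelism and enrichment

`n_populations` counts presence (≥ 1 call in the gene), `n_mutations` raw
calls — both readings of "mutations per gene" are reported side by side.
Ranking ties break lexicographically by gene id for reproducible output.
Histogram capping (the singleton bin dwarfs everything) affects display
metadata only; stored counts are never altered. The random-parallelism
probability is computed in log10 space so genome-scale designs do not
underflow. Allele spectra deduplicate by (position, ref, alt) and map
residues strand-aware onto optional domain intervals (the arcA-like
two-domain layout, receiver 1–123 / DNA-binding 124–238, ships as a
constant). Subsystem scores pool unannotated genes into an explicit
`unassigned` pseudo-subsystem so the gene-count-weighted mean score is
exactly 1 whenever subsystems partition the genome — an identity the test
suite checks to 1e-12. Hierarchical aggregation (gene → subsystem →
category) unions population sets, so parallelism is monotone up the
hierarchy.

## Proteomics

Samples are median-aligned over observed peptides, then rolled up per
protein by the centered-mean scheme: center each peptide by its
across-sample mean, average centered peptides per sample ignoring missing
values, add back the protein grand mean. This variant is deterministic and
peptide-order-free; a median-combining variant is selectable. The
differential test is one-way ANOVA, by default ancestor vs all evolved
samples pooled (the headline contrast), with a per-population multi-group
design selectable. Significance requires p ≤ 0.01 (boundary passes) and
|log2FC| > 0.7 (boundary fails); no multiple-testing correction is applied
by default, for fidelity to the dual-threshold procedure the package
implements — a correction switch exists. A protein must be observed in
≥ 2 ancestor replicates to be testable; proteins absent from the ancestor
are reported but never called significant. Undetected protein × population
cells stay missing in the heat-map table, never imputed as zero.

## Problem sizes

The test suite and `scripts/acceptance.py` run the generator at desk scale
(500/550 genes, 12 + 12 populations and 12 MA lines per species): large
enough that driver ranking, artifact recovery (20 independent experiments)
and mutator flagging are stable, small enough that the full suite runs in
about a minute. Calibration checks that need tighter Monte-Carlo error use
larger dedicated draws (10⁶ trials for the parallelism probability, 10⁴
proteins for the type-I rate).

## Known limitations

* Effect classification of real sequence data handles SNPs and simple
  indels against a supplied coding sequence; complex substitutions and
  splice-like edge cases are out of scope.
* The Levene filter assumes exactly the treatment structure given by the
  population table; with more than two media it tests all groups jointly.
* The per-species gene catalogue is recovered from gene-id prefixes when
  subsystem scores are computed per species; datasets with arbitrary gene
  ids fall back to the pooled catalogue.
* The mutator rule is an operational outlier fence, not an estimate of
  mutation rate.
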