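"""The variant-identification cascade.

Whole-population (pooled) sequencing at a low acceptance threshold admits
systematic false positives — reference errors, mis-resolved duplications,
repeat regions — that recur at near-identical frequencies across samples.
Two orthogonal filters remove them:

* **MA-control blacklist** — sites called in several independently evolved
  mutation-accumulation lines cannot all be real (relaxed selection makes
  repeated identical mutations vanishingly unlikely), so any site present
  in >= ``min_lines`` MA lines is removed from the evolved populations.
* **Levene's-test filter** — adaptive mutations arise at different times in
  different populations and therefore at different frequencies, while
  systematic artifacts sit at almost the same frequency everywhere.  Sites
  whose frequency spread does NOT differ between the two media (Levene's
  test, p >= alpha) are removed.

Both operate on sites (contig, position), not alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .dataset import ExperimentDataset
from .variants import NONSYNONYMOUS_EFFECTS, SiteKey

__all__ = [
    "LeveneResult",
    "apply_frequency_floor",
    "classify_effect",
    "select_nonsynonymous",
    "build_ma_blacklist",
    "apply_blacklist",
    "levene_statistic",
    "levene_artifact_filter",
]


# ---------------------------------------------------------------------------
# frequency floor and effect selection

def apply_frequency_floor(calls: pd.DataFrame, min_freq: float = 0.05) -> pd.DataFrame:
    """Keep calls with frequency >= ``min_freq`` (inclusive floor)."""
    if not 0 < min_freq <= 1:
        raise ValueError("min_freq must lie in (0, 1]")
    return calls[calls["frequency"] >= min_freq].copy()


def select_nonsynonymous(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep non-synonymous effects: substitutions, stops, indels in frame or not."""
    return calls[calls["effect"].isin(NONSYNONYMOUS_EFFECTS)].copy()


def classify_effect(
    gene_sequence: str,
    offset: int,
    ref: str,
    alt: str,
    genetic_code: int = 11,
) -> str:
    """Effect class of one mutation inside a coding sequence.

    ``offset`` is the 0-based position of the first affected base within
    ``gene_sequence`` (the coding strand).  SNPs are translated under the
    bacterial genetic code; indels are frameshift unless their length is a
    multiple of 3.  ``ref``/``alt`` use ``"-"`` for the empty allele.  A
    ``None`` gene sequence marks a position outside any gene: ``"intergenic"``.
    """
    if gene_sequence is None:
        return "intergenic"
    gene_sequence = gene_sequence.upper()
    ref = ref.upper().replace("-", "")
    alt = alt.upper().replace("-", "")
    if offset < 0 or offset >= len(gene_sequence):
        raise ValueError("offset outside gene")
    if ref and gene_sequence[offset : offset + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match gene sequence at offset {offset}"
        )
    if len(ref) != len(alt):  # indel
        return "frameshift" if (len(ref) - len(alt)) % 3 else "inframe_indel"
    if len(ref) != 1:
        raise ValueError("multi-base substitutions are not supported")
    if len(gene_sequence) % 3:
        raise ValueError("gene length not divisible by 3")
    codon_i = offset // 3
    codon = gene_sequence[3 * codon_i : 3 * codon_i + 3]
    mutant = codon[: offset % 3] + alt + codon[offset % 3 + 1 :]
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    aa_ref = str(Seq(codon).translate(table=genetic_code))
    aa_alt = str(Seq(mutant).translate(table=genetic_code))
    if mutant in table.stop_codons and codon not in table.stop_codons:
        return "stop_gained"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# MA blacklist

def build_ma_blacklist(ma_calls: pd.DataFrame, min_lines: int = 4) -> set:
    """Sites called in >= ``min_lines`` distinct MA lines.

    Counts lines (populations), not calls: two alleles of one site in one
    line count once.
    """
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    if len(ma_calls) == 0:
        return set()
    lines_per_site = ma_calls.groupby(["contig", "position"])["population_id"].nunique()
    return {
        SiteKey(c, int(p)) for (c, p) in lines_per_site[lines_per_site >= min_lines].index
    }


def apply_blacklist(
    calls: pd.DataFrame,
    blacklist: set,
    populations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove blacklisted sites; report removal counts (per treatment when
    a population table is supplied)."""
    if len(calls) == 0 or not blacklist:
        return calls.copy(), {"total_removed": 0}
    keys = {(b.contig, b.position) for b in blacklist}
    hit = pd.Series(
        [(c, int(p)) in keys for c, p in zip(calls.contig, calls.position)],
        index=calls.index,
    )
    removed = calls[hit]
    counts: dict = {"total_removed": int(hit.sum())}
    if populations is not None and len(removed):
        treatment_of = populations.set_index("population_id")["treatment"]
        per = removed["population_id"].map(treatment_of).value_counts()
        counts["per_treatment"] = {str(k): int(v) for k, v in per.items()}
    return calls[~hit].copy(), counts


# ---------------------------------------------------------------------------
# Levene's test

@dataclass(frozen=True)
class LeveneResult:
    site: SiteKey | None
    W: float
    df1: int
    df2: int
    p_value: float
    testable: bool


def levene_statistic(groups, center: str = "mean", site: SiteKey | None = None) -> LeveneResult:
    """Levene's test for equality of spread across groups.

    With :math:`Z_{ij} = |x_{ij} - c_i|` (``c_i`` the group mean, or median
    for the Brown–Forsythe variant),

    .. math::

        W = \\frac{N-k}{k-1}\\cdot
            \\frac{\\sum_i n_i(\\bar Z_i - \\bar Z)^2}
                 {\\sum_i \\sum_j (Z_{ij} - \\bar Z_i)^2}

    compared to the upper tail of :math:`F(k-1, N-k)`.  Degenerate spreads:
    0/0 gives ``W=0, p=1``; a positive numerator over a zero denominator
    gives ``W=inf, p=0``.  Groups with fewer than 2 observations make the
    result untestable.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    n = np.array([len(g) for g in groups])
    N = int(n.sum())
    df1, df2 = k - 1, N - k
    if (n < 2).any():
        return LeveneResult(site, np.nan, df1, df2, np.nan, testable=False)
    if center == "mean":
        centers = [g.mean() for g in groups]
    elif center == "median":
        centers = [np.median(g) for g in groups]
    else:
        raise ValueError("center must be 'mean' or 'median'")
    Z = [np.abs(g - c) for g, c in zip(groups, centers)]
    zbar_i = np.array([z.mean() for z in Z])
    zbar = np.concatenate(Z).mean()
    num = float((n * (zbar_i - zbar) ** 2).sum())
    den = float(sum(((z - zb) ** 2).sum() for z, zb in zip(Z, zbar_i)))
    if den == 0.0:
        if num == 0.0:
            return LeveneResult(site, 0.0, df1, df2, 1.0, testable=True)
        return LeveneResult(site, np.inf, df1, df2, 0.0, testable=True)
    W = (df2 / df1) * num / den
    p = float(stats.f.sf(W, df1, df2))
    return LeveneResult(site, float(W), df1, df2, p, testable=True)


def levene_artifact_filter(
    dataset: ExperimentDataset,
    calls: pd.DataFrame | None = None,
    group_by: str = "treatment",
    alpha: float = 0.05,
    min_per_group: int = 2,
    center: str = "mean",
    absent_as_zero: bool = True,
) -> tuple[pd.DataFrame, set, pd.DataFrame]:
    """Remove sites whose frequencies do NOT differ between treatments.

    For every site called in >= ``min_per_group`` analyzed populations in
    *each* treatment group (within its species), per-treatment frequency
    vectors are assembled — populations lacking the call contribute 0 when
    ``absent_as_zero`` (absence is informative: a treatment-restricted
    variant then has high spread, a ubiquitous artifact almost none) — and
    Levene's test is run.  Sites with p >= ``alpha`` are removed; untestable
    sites are retained.  Returns (kept calls, removed sites, audit table).
    """
    if calls is None:
        calls = dataset.evolved_calls()
    pops = dataset.analyzed_populations()
    treatments = pops[group_by].unique()
    if len(treatments) < 2:
        raise ValueError("Levene filter needs >=2 treatment groups")
    if len(calls) == 0:
        return calls.copy(), set(), pd.DataFrame(
            columns=["contig", "position", "W", "df1", "df2", "p_value", "testable", "removed"]
        )

    species_of = pops.set_index("population_id")["species"]
    group_of = pops.set_index("population_id")[group_by]
    pops_by_sg = {
        (sp, g): set(sub.population_id)
        for (sp, g), sub in pops.groupby(["species", group_by])
    }

    # one frequency per site per population (sum of allele frequencies,
    # capped at 1 so co-segregating alleles do not overflow)
    site_pop = (
        calls.assign(species=calls.population_id.map(species_of))
        .groupby(["species", "contig", "position", "population_id"])["frequency"]
        .sum()
        .clip(upper=1.0)
    )

    records = []
    removed_sites: set = set()
    for (sp, contig, position), sub in site_pop.groupby(level=[0, 1, 2]):
        freqs = sub.droplevel([0, 1, 2])
        observed_per_group = freqs.index.map(group_of).value_counts()
        eligible = all(
            observed_per_group.get(g, 0) >= min_per_group for g in treatments
        )
        if not eligible:
            records.append((contig, position, np.nan, 0, 0, np.nan, False, False))
            continue
        vectors = []
        for g in treatments:
            members = pops_by_sg.get((sp, g), set())
            if absent_as_zero:
                vec = freqs.reindex(sorted(members)).fillna(0.0).to_numpy()
            else:
                vec = freqs[freqs.index.isin(members)].to_numpy()
            vectors.append(vec)
        res = levene_statistic(vectors, center=center, site=SiteKey(contig, int(position)))
        remove = res.testable and res.p_value >= alpha
        if remove:
            removed_sites.add(SiteKey(contig, int(position)))
        records.append(
            (contig, position, res.W, res.df1, res.df2, res.p_value, res.testable, remove)
        )

    audit = pd.DataFrame(
        records,
        columns=["contig", "position", "W", "df1", "df2", "p_value", "testable", "removed"],
    )
    kept, _ = apply_blacklist(calls, removed_sites)
    return kept, removed_sites, audit
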