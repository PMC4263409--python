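"""Population proteomics: peptide roll-up and differential abundance.

Label-free LC-MS quantification yields peptide-level log2 abundances with
missing values.  The analysis (i) median-aligns samples, (ii) rolls peptides
up to proteins, (iii) tests each protein for ancestor-vs-evolved abundance
change by one-way ANOVA, and (iv) applies a dual threshold — p <= 0.01 and
|log2 fold change| > 0.7 — to call significant proteins, reported with
per-population fold changes for functional heat maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PeptideMatrix

__all__ = [
    "median_align",
    "rollup_proteins",
    "differential_test",
    "significance_filter",
    "functional_heatmap_table",
]


def median_align(abundances: pd.DataFrame) -> pd.DataFrame:
    """Shift each sample so its median over observed peptides is the grand median."""
    medians = abundances.median(axis=0, skipna=True)
    return abundances - medians + medians.mean()


def rollup_proteins(
    matrix: PeptideMatrix,
    method: str = "mean_of_centered",
    align: bool = True,
) -> pd.DataFrame:
    """Roll peptide abundances up to protein x sample log2 abundances.

    Default scheme: center each peptide by its across-sample mean, combine
    centered peptides per protein per sample (mean, ignoring missing), then
    add back the protein-level grand mean so values stay on the abundance
    scale.  ``method="median_of_centered"`` combines by median.  A protein
    is observed in a sample iff >=1 of its peptides is; single-peptide
    proteins reproduce their peptide exactly (after alignment).
    """
    if method not in ("mean_of_centered", "median_of_centered"):
        raise ValueError("unknown roll-up method")
    ab = median_align(matrix.abundances) if align else matrix.abundances
    centered = ab.sub(ab.mean(axis=1, skipna=True), axis=0)
    proteins = matrix.protein_map.loc[ab.index]
    grouped = centered.groupby(proteins.to_numpy())
    combined = grouped.median() if method == "median_of_centered" else grouped.mean()
    # protein grand mean over its peptides' means
    grand = ab.mean(axis=1, skipna=True).groupby(proteins.to_numpy()).mean()
    return combined.add(grand, axis=0)


def differential_test(
    protein_matrix: pd.DataFrame,
    sample_groups: pd.Series,
    design: str = "two_group",
    min_ancestor_obs: int = 2,
) -> pd.DataFrame:
    """Per-protein ANOVA of abundance between ancestor and evolved samples.

    ``design="two_group"`` pools all evolved samples against the ancestor
    (the headline comparison); ``design="per_population"`` keeps each
    evolved population as its own group.  Fold changes are in log2 units:
    overall = mean(evolved) - mean(ancestor); per population = mean of that
    population's replicates - mean(ancestor).  Proteins with fewer than
    ``min_ancestor_obs`` ancestor observations are reported untestable
    (NaN p and fold change) and never enter the significant set.
    """
    if design not in ("two_group", "per_population"):
        raise ValueError("design must be 'two_group' or 'per_population'")
    groups = sample_groups.loc[protein_matrix.columns]
    anc_cols = groups.index[groups == "ancestor"]
    evo_groups = [g for g in groups.unique() if g != "ancestor"]
    if len(anc_cols) < 2:
        raise ValueError("need >=2 ancestor samples")
    if not evo_groups:
        raise ValueError("need >=1 evolved group")

    records = []
    for protein, row in protein_matrix.iterrows():
        anc = row[anc_cols].dropna().to_numpy(dtype=float)
        evo = row[groups.index[groups != "ancestor"]].dropna().to_numpy(dtype=float)
        per_pop = {
            g: row[groups.index[groups == g]].dropna().to_numpy(dtype=float)
            for g in evo_groups
        }
        n_detected = sum(len(v) > 0 for v in per_pop.values())
        rec = {
            "protein": protein,
            "n_ancestor_obs": len(anc),
            "n_evolved_obs": len(evo),
            "n_populations_detected": n_detected,
        }
        if len(anc) < min_ancestor_obs or len(evo) == 0:
            rec.update(p_value=np.nan, log2fc=np.nan, testable=False)
            for g in evo_groups:
                rec[f"log2fc_{g}"] = np.nan
            records.append(rec)
            continue
        anc_mean = anc.mean()
        rec["log2fc"] = evo.mean() - anc_mean
        for g in evo_groups:
            rec[f"log2fc_{g}"] = (
                per_pop[g].mean() - anc_mean if len(per_pop[g]) else np.nan
            )
        if design == "two_group":
            test_groups = [anc, evo]
        else:
            test_groups = [anc] + [v for v in per_pop.values() if len(v)]
        if len(evo) < 2 or all(np.ptp(g) == 0 for g in test_groups):
            # no within-group spread anywhere: F undefined
            rec.update(p_value=np.nan, testable=False)
        else:
            f, p = stats.f_oneway(*test_groups)
            rec.update(p_value=float(p), F=float(f), testable=True)
        records.append(rec)
    out = pd.DataFrame(records).set_index("protein")
    return out


def significance_filter(
    records: pd.DataFrame,
    p_max: float = 0.01,
    min_abs_log2fc: float = 0.7,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Apply the dual significance threshold and assign directions.

    Significant iff ``p <= p_max`` (boundary passes) AND
    ``|log2fc| > min_abs_log2fc`` (boundary fails).  ``p_adjust="bh"``
    applies Benjamini-Hochberg across testable proteins before
    thresholding (off by default: the canonical procedure thresholds raw
    p-values).  Adds ``significant`` and ``direction`` (up/down/none)
    columns; untestable records are never significant.
    """
    out = records.copy()
    testable = out["testable"].fillna(False).astype(bool)
    pvals = out["p_value"].copy()
    if p_adjust is not None:
        if p_adjust != "bh":
            raise ValueError("p_adjust must be None or 'bh'")
        adj = stats.false_discovery_control(pvals[testable].to_numpy(), method="bh")
        pvals.loc[testable] = adj
        out["p_adjusted"] = pvals
    sig = (
        testable
        & (pvals <= p_max)
        & (out["log2fc"].abs() > min_abs_log2fc)
    )
    out["significant"] = sig.fillna(False)
    out["direction"] = np.where(
        out["significant"], np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    return out


def direction_counts(records: pd.DataFrame) -> dict:
    sig = records[records["significant"]]
    return {
        "n_significant": int(len(sig)),
        "n_up": int((sig["direction"] == "up").sum()),
        "n_down": int((sig["direction"] == "down").sum()),
    }


def functional_heatmap_table(
    records: pd.DataFrame,
    protein_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-population log2 fold changes of significant proteins, by class.

    Rows are significant proteins sorted by functional class then protein
    id; columns are the per-population fold changes.  Cells where the
    protein was not detected in a population stay NaN (displayed gray),
    never imputed as zero.  Unmapped proteins go to class 'other'.
    """
    sig = records[records["significant"]]
    fc_cols = [c for c in records.columns if c.startswith("log2fc_")]
    if len(sig) == 0:
        return pd.DataFrame(columns=["class", *fc_cols])
    table = sig[fc_cols].copy()
    if protein_classes is not None:
        table.insert(0, "class", protein_classes.reindex(table.index).fillna("other"))
    else:
        table.insert(0, "class", "other")
    table = table.rename_axis("protein").reset_index()
    return table.sort_values(["class", "protein"]).set_index("protein")
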