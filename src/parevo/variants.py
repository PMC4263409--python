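"""Variant-call tables: schema, validation and I/O.

One row per mutation observation in one population.  The canonical
interchange is a tab-delimited table with the columns in
:data:`VARIANT_COLUMNS`; a VCF dialect carrying an allele-frequency INFO tag
can also be read.  Frequencies live in (0, 1]; positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "population_id",
    "contig",
    "position",
    "ref",
    "alt",
    "vtype",
    "gene_id",
    "effect",
    "frequency",
]

VTYPES = {"snp", "insertion", "deletion"}
EFFECTS = {
    "synonymous",
    "nonsynonymous",
    "stop_gained",
    "frameshift",
    "inframe_indel",
    "intergenic",
}
#: effect classes retained by the non-synonymous selection
NONSYNONYMOUS_EFFECTS = {"nonsynonymous", "stop_gained", "frameshift", "inframe_indel"}


@dataclass(frozen=True)
class SiteKey:
    """A genomic site: (contig, 1-based position)."""

    contig: str
    position: int

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")


def empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population_id": pd.Series(dtype=str),
            "contig": pd.Series(dtype=str),
            "position": pd.Series(dtype=int),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "vtype": pd.Series(dtype=str),
            "gene_id": pd.Series(dtype=str),
            "effect": pd.Series(dtype=str),
            "frequency": pd.Series(dtype=float),
        }
    )


def validate_variants(calls: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; returns the (unmodified) frame."""
    missing = [c for c in VARIANT_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if len(calls):
        bad_eff = set(calls["effect"]) - EFFECTS
        if bad_eff:
            raise ValueError(f"unknown effect labels: {sorted(bad_eff)}")
        bad_vt = set(calls["vtype"]) - VTYPES
        if bad_vt:
            raise ValueError(f"unknown vtype labels: {sorted(bad_vt)}")
        f = calls["frequency"]
        if ((f <= 0) | (f > 1)).any():
            raise ValueError("frequencies must lie in (0, 1]")
        if (calls["position"] < 1).any():
            raise ValueError("positions must be >= 1")
    return calls


def site_index(calls: pd.DataFrame) -> pd.Series:
    """(contig, position) tuples, one per row — the blacklist/filter key."""
    return pd.Series(
        list(zip(calls["contig"], calls["position"])), index=calls.index
    )


def write_variants_tsv(calls: pd.DataFrame, path) -> None:
    validate_variants(calls)
    out = calls[VARIANT_COLUMNS].copy()
    # fixed float format so round trips are byte-stable
    out["frequency"] = out["frequency"].map(lambda x: f"{x:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    """Read the canonical tab-delimited variant table.

    Rows whose frequency falls outside (0, 1] are rejected individually with
    a logged line number; structural problems raise.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "population_id": str,
            "contig": str,
            "ref": str,
            "alt": str,
            "vtype": str,
            "gene_id": str,
            "effect": str,
        },
    )
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = (df["frequency"] <= 0) | (df["frequency"] > 1) | df["frequency"].isna()
    if bad.any():
        for idx in df.index[bad]:
            # +2: header line and 1-based numbering
            logger.warning(
                "%s line %d: frequency %r outside (0,1]; record rejected",
                path,
                idx + 2,
                df.at[idx, "frequency"],
            )
        df = df[~bad]
    df = df.reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    return validate_variants(df)


def read_variants_vcf(path, population_id: str, af_tag: str = "AF") -> pd.DataFrame:
    """Read one population's calls from a VCF.

    The record-level INFO field ``af_tag`` supplies the allele frequency;
    ``GENE`` and ``EFFECT`` INFO fields, when present, supply annotation.
    Indels are normalized to the internal representation: the shared anchor
    base is stripped so keys match the tab-delimited dialect.
    """
    import pysam

    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            afs = rec.info.get(af_tag)
            if afs is None:
                continue
            if not isinstance(afs, tuple):
                afs = (afs,)
            for alt, af in zip(rec.alts or (), afs):
                ref, a, pos = rec.ref, alt, rec.pos
                if len(ref) != len(a) and ref[0] == a[0]:
                    # VCF anchor-base convention -> internal left-stripped form
                    ref, a = ref[1:] or "-", a[1:] or "-"
                    pos = rec.pos + 1
                if len(ref) == len(a) == 1:
                    vtype = "snp"
                elif (ref == "-") or (len(a) > len(ref)):
                    vtype = "insertion"
                else:
                    vtype = "deletion"
                rows.append(
                    {
                        "population_id": population_id,
                        "contig": rec.chrom,
                        "position": pos,
                        "ref": ref,
                        "alt": a,
                        "vtype": vtype,
                        "gene_id": rec.info.get("GENE", "intergenic"),
                        "effect": rec.info.get("EFFECT", "intergenic"),
                        "frequency": float(af),
                    }
                )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if len(df) == 0:
        return empty_variants()
    return validate_variants(df)
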