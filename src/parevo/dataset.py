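"""The in-memory experiment: populations, their variant calls, provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import GenomeAnnotation
from .variants import (
    empty_variants,
    read_variants_tsv,
    validate_variants,
    write_variants_tsv,
)

POPULATION_COLUMNS = [
    "population_id",
    "species",
    "treatment",
    "replicate",
    "is_ma",
    "excluded",
]

TRUTH_COLUMNS = ["contig", "position", "alt", "role"]
TRUTH_ROLES = {"driver", "neutral", "artifact", "ma_private"}


@dataclass
class ExperimentDataset:
    """Populations plus their variant calls (and, for simulations, truth).

    ``populations`` holds one row per sequenced sample: evolved populations
    (``is_ma=False``) and mutation-accumulation control lines
    (``is_ma=True``).  ``excluded`` marks populations that carry calls but
    are omitted from every statistic (the analyzed set).  ``provenance``
    accumulates one record per pipeline event (stage, parameters, counts).
    """

    annotation: GenomeAnnotation
    populations: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in POPULATION_COLUMNS if c not in self.populations.columns]
        if missing:
            raise ValueError(f"population table missing columns: {missing}")
        if self.populations["population_id"].duplicated().any():
            raise ValueError("duplicate population ids")
        validate_variants(self.variants)
        known = set(self.populations["population_id"])
        unknown = set(self.variants["population_id"]) - known
        if unknown:
            raise ValueError(f"calls reference unknown populations: {sorted(unknown)[:5]}")
        if self.truth is not None and len(self.truth):
            bad = set(self.truth["role"]) - TRUTH_ROLES
            if bad:
                raise ValueError(f"unknown truth roles: {sorted(bad)}")

    # -- population subsets ----------------------------------------------
    def analyzed_populations(self) -> pd.DataFrame:
        """Evolved, non-excluded populations — the statistical universe."""
        p = self.populations
        return p[(~p.is_ma) & (~p.excluded)].reset_index(drop=True)

    def ma_populations(self) -> pd.DataFrame:
        p = self.populations
        return p[p.is_ma & ~p.excluded].reset_index(drop=True)

    def calls_for(self, population_ids) -> pd.DataFrame:
        ids = set(population_ids)
        return self.variants[self.variants.population_id.isin(ids)].reset_index(
            drop=True
        )

    def evolved_calls(self) -> pd.DataFrame:
        return self.calls_for(self.analyzed_populations().population_id)

    def ma_calls(self) -> pd.DataFrame:
        return self.calls_for(self.ma_populations().population_id)

    def with_variants(self, variants: pd.DataFrame) -> "ExperimentDataset":
        """Same experiment, different call set (filters return these)."""
        return ExperimentDataset(
            annotation=self.annotation,
            populations=self.populations,
            variants=variants.reset_index(drop=True),
            truth=self.truth,
            provenance=list(self.provenance),
        )

    def log(self, stage: str, **info) -> None:
        self.provenance.append({"stage": stage, **info})

    # -- I/O --------------------------------------------------------------
    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.annotation.to_gff3(outdir / "annotation.gff3")
        self.populations.to_csv(outdir / "populations.tsv", sep="\t", index=False)
        write_variants_tsv(self.variants, outdir / "variants.tsv")
        if self.truth is not None:
            self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir) -> "ExperimentDataset":
        indir = Path(indir)
        annotation = GenomeAnnotation.from_gff3(indir / "annotation.gff3")
        populations = pd.read_csv(
            indir / "populations.tsv", sep="\t", dtype={"population_id": str}
        )
        variants_path = indir / "variants.tsv"
        variants = read_variants_tsv(variants_path) if variants_path.exists() else empty_variants()
        truth_path = indir / "truth.tsv"
        truth = (
            pd.read_csv(truth_path, sep="\t", dtype={"contig": str, "alt": str})
            if truth_path.exists()
            else None
        )
        return cls(
            annotation=annotation,
            populations=populations,
            variants=variants,
            truth=truth,
        )
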