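"""Gene catalogues with functional hierarchy.

A :class:`GenomeAnnotation` is a thin wrapper around a pandas DataFrame of
genes (1-based closed coordinates, one contig per genome in the simulated
case) plus the gene -> subsystem -> category hierarchy used for functional
enrichment.  It reads/writes GFF3 (gene features, subsystem/category in the
attribute column) and a flat TSV.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field

import pandas as pd

GENE_COLUMNS = [
    "gene_id",
    "contig",
    "start",
    "end",
    "strand",
    "product",
    "subsystem",
    "category",
]

UNASSIGNED = "unassigned"


@dataclass
class GenomeAnnotation:
    """Gene catalogue for one genome.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id, contig, start, end, strand,
        product, subsystem, category``.  Coordinates are 1-based closed.
        Genes with no subsystem are pooled into ``"unassigned"`` so that
        subsystems always partition the gene set.
    """

    genes: pd.DataFrame
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))[:5]}")
        if (self.genes["end"] < self.genes["start"]).any():
            raise ValueError("gene with end < start")
        genes = self.genes.copy()
        for col in ("subsystem", "category"):
            blank = genes[col].isna() | (genes[col] == "")
            if blank.any():
                self.warnings.append(
                    f"{int(blank.sum())} genes lacked a {col}; set to '{UNASSIGNED}'"
                )
                genes.loc[blank, col] = UNASSIGNED
        self.genes = genes.reset_index(drop=True)
        self._by_id = self.genes.set_index("gene_id", drop=False)

    # -- basic queries ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def gene(self, gene_id: str) -> pd.Series:
        try:
            return self._by_id.loc[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene: {gene_id}") from None

    def gene_length(self, gene_id: str) -> int:
        g = self.gene(gene_id)
        return int(g.end - g.start + 1)

    def subsystem_sizes(self) -> pd.Series:
        """Number of genes per subsystem (partition of the gene set)."""
        return self.genes.groupby("subsystem").size()

    def subsystem_of(self) -> pd.Series:
        return self.genes.set_index("gene_id")["subsystem"]

    def category_of_subsystem(self) -> pd.Series:
        return self.genes.drop_duplicates("subsystem").set_index("subsystem")["category"]

    def locate(self, contig: str, position: int) -> str:
        """Gene id containing (contig, position), or ``"intergenic"``."""
        g = self.genes
        hit = g[(g.contig == contig) & (g.start <= position) & (position <= g.end)]
        if len(hit) == 0:
            return "intergenic"
        return str(hit.iloc[0].gene_id)

    # -- I/O --------------------------------------------------------------
    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig, sub in self.genes.groupby("contig", sort=False):
                fh.write(f"##sequence-region {contig} 1 {int(sub.end.max())}\n")
            for row in self.genes.itertuples(index=False):
                attrs = ";".join(
                    f"{k}={urllib.parse.quote(str(v), safe='')}"
                    for k, v in [
                        ("ID", row.gene_id),
                        ("product", row.product),
                        ("subsystem", row.subsystem),
                        ("category", row.category),
                    ]
                )
                fh.write(
                    f"{row.contig}\tparevo\tgene\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path, subsystem_map: pd.DataFrame | None = None) -> "GenomeAnnotation":
        """Read gene features from a GFF3 file.

        ``subsystem_map`` (columns gene_id, subsystem, category) overrides or
        supplies the functional hierarchy when the GFF3 attributes lack it.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9 or parts[2] != "gene":
                    continue
                attrs = {}
                for item in parts[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k] = urllib.parse.unquote(v)
                rows.append(
                    {
                        "gene_id": attrs.get("ID", f"{parts[0]}:{parts[3]}"),
                        "contig": parts[0],
                        "start": int(parts[3]),
                        "end": int(parts[4]),
                        "strand": parts[6],
                        "product": attrs.get("product", ""),
                        "subsystem": attrs.get("subsystem", ""),
                        "category": attrs.get("category", ""),
                    }
                )
        genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
        if subsystem_map is not None:
            m = subsystem_map.set_index("gene_id")
            genes["subsystem"] = genes["gene_id"].map(m["subsystem"]).fillna("")
            genes["category"] = genes["gene_id"].map(m["category"]).fillna("")
        return cls(genes)

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))

    def subsystem_map_frame(self) -> pd.DataFrame:
        """gene_id -> subsystem -> category table (the enrichment input)."""
        return self.genes[["gene_id", "subsystem", "category"]].copy()


def concat_annotations(annotations) -> GenomeAnnotation:
    """Stack per-species annotations into one catalogue (distinct contigs)."""
    return GenomeAnnotation(
        pd.concat([a.genes for a in annotations], ignore_index=True)
    )
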