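"""Core in-memory containers and plain-text I/O.

The package works with a genes x samples expression matrix on a log-like
scale, per-sample metadata (genotype, brain region), an optional detection
p-value matrix of the same shape, and a boolean mask of values removed by
per-gene outlier filtering.  All on-disk formats are tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPE_COL = "genotype"
REGION_COL = "region"

#: the two genotype labels used throughout: the selectively bred line and
#: its heterogeneous founder stock
SELECTED = "selected"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """Expression matrix plus sample metadata, detection p-values and mask.

    Parameters
    ----------
    values
        genes x samples DataFrame; index are gene (probe) ids, columns are
        sample ids.
    metadata
        one row per sample (index = sample id) with at least ``genotype``
        and ``region`` columns.  Rows correspond one-to-one with matrix
        columns, in the same order.
    detection
        optional genes x samples DataFrame of detection p-values.
    mask
        optional genes x samples boolean DataFrame; ``True`` marks a value
        removed by outlier filtering.  Masked entries are excluded from all
        downstream statistics.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    detection: pd.DataFrame | None = None
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError(
                "metadata rows must correspond one-to-one (and in order) "
                "with expression matrix columns"
            )
        for col in (GENOTYPE_COL, REGION_COL):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        if self.detection is not None and self.detection.shape != self.values.shape:
            raise ValueError("detection matrix shape must match expression matrix")
        if self.mask is not None and self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match expression matrix")

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def regions(self) -> list[str]:
        """Region labels in order of first appearance."""
        return list(dict.fromkeys(self.metadata[REGION_COL]))

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.metadata[GENOTYPE_COL]))

    def masked_values(self) -> pd.DataFrame:
        """Expression values with masked entries replaced by NaN."""
        if self.mask is None:
            return self.values
        return self.values.where(~self.mask)

    def region_samples(self, region: str) -> pd.Index:
        return self.metadata.index[self.metadata[REGION_COL] == region]

    def group_samples(self, region: str, genotype: str) -> pd.Index:
        m = self.metadata
        sel = (m[REGION_COL] == region) & (m[GENOTYPE_COL] == genotype)
        return m.index[sel]

    # -- transformations ---------------------------------------------------
    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        genes = pd.Index(genes)
        return ExpressionDataset(
            values=self.values.loc[genes],
            metadata=self.metadata,
            detection=None if self.detection is None else self.detection.loc[genes],
            mask=None if self.mask is None else self.mask.loc[genes],
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = pd.Index(samples)
        return ExpressionDataset(
            values=self.values[samples],
            metadata=self.metadata.loc[samples],
            detection=None if self.detection is None else self.detection[samples],
            mask=None if self.mask is None else self.mask[samples],
        )

    def with_mask(self, mask: pd.DataFrame) -> "ExpressionDataset":
        return replace(self, mask=mask)

    def to_raw_intensities(self) -> "ExpressionDataset":
        """Back-transform the log2-like scale to positive raw intensities (2^x)."""
        return replace(self, values=np.power(2.0, self.values))

    # -- I/O ---------------------------------------------------------------
    def write(self, out_dir: str | Path, prefix: str = "") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(self.values, out / f"{prefix}expression.tsv")
        write_metadata_tsv(self.metadata, out / f"{prefix}metadata.tsv")
        if self.detection is not None:
            write_expression_tsv(self.detection, out / f"{prefix}detection.tsv")
        if self.mask is not None:
            write_mask_tsv(self.mask, out / f"{prefix}mask.tsv")

    @classmethod
    def read(
        cls,
        expression: str | Path,
        metadata: str | Path,
        detection: str | Path | None = None,
        mask: str | Path | None = None,
    ) -> "ExpressionDataset":
        values = read_expression_tsv(expression)
        meta = read_metadata_tsv(metadata)
        det = None if detection is None else read_expression_tsv(detection)
        msk = None
        if mask is not None:
            msk = read_mask_tsv(mask, like=values)
        return cls(values=values, metadata=meta, detection=det, mask=msk)


# ---------------------------------------------------------------------------
# gene set collections (GMT)
# ---------------------------------------------------------------------------
@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], description: str = "",
            category: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        self.sets[name] = set(genes)
        self.descriptions[name] = description
        if category:
            self.categories[name] = category

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path, category: str = "") -> "GeneSetCollection":
        coll = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                coll.add(parts[0], parts[2:], description=parts[1], category=category)
        return coll


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------
@dataclass
class OrthologMap:
    """Source -> target gene id pairs with unmapped/ambiguous bookkeeping.

    ``resolve_one_to_one`` restricts the raw pair list to sources and targets
    appearing exactly once; many-to-many relations are dropped and counted.
    """

    pairs: list[tuple[str, str]]
    n_ambiguous: int = 0

    def resolve_one_to_one(self) -> "OrthologMap":
        src_counts: dict[str, int] = {}
        tgt_counts: dict[str, int] = {}
        for s, t in self.pairs:
            src_counts[s] = src_counts.get(s, 0) + 1
            tgt_counts[t] = tgt_counts.get(t, 0) + 1
        kept = [(s, t) for s, t in self.pairs
                if src_counts[s] == 1 and tgt_counts[t] == 1]
        return OrthologMap(pairs=kept, n_ambiguous=len(self.pairs) - len(kept))

    def as_dict(self) -> dict[str, str]:
        return dict(self.resolve_one_to_one().pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["source_id", "target_id"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("ortholog table needs two columns (source, target)")
        return cls(pairs=list(zip(df.iloc[:, 0], df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# plain TSV helpers
# ---------------------------------------------------------------------------
def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_mask_tsv(mask: pd.DataFrame, path: str | Path,
                   reasons: Mapping[tuple[str, str], str] | None = None) -> None:
    """Write the mask as a sparse (gene, sample, reason) triple list."""
    rows = []
    gi, si = np.nonzero(mask.to_numpy())
    for g, s in zip(gi, si):
        gene, sample = mask.index[g], mask.columns[s]
        rows.append((gene, sample, (reasons or {}).get((gene, sample), "outlier")))
    pd.DataFrame(rows, columns=["gene_id", "sample_id", "reason"]).to_csv(
        path, sep="\t", index=False)


def read_mask_tsv(path: str | Path, like: pd.DataFrame) -> pd.DataFrame:
    triples = pd.read_csv(path, sep="\t", dtype=str)
    mask = pd.DataFrame(False, index=like.index, columns=like.columns)
    for _, row in triples.iterrows():
        mask.loc[row["gene_id"], row["sample_id"]] = True
    return mask
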