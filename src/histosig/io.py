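"""Reading, writing and light preprocessing of expression tables and gene sets.

Expression data is expected to arrive already normalized on a log2 scale
(e.g. RMA output for Affymetrix arrays); this module never touches raw
intensities.  The only transformation it owns is per-gene median centering,
the convention used throughout for heatmap-style relative expression.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionParseError",
    "GmtParseError",
    "load_expression",
    "write_expression",
    "median_center_genes",
    "read_gmt",
    "write_gmt",
]

ANNOTATION_FIELDS = ("model", "genotype", "histology_label", "batch")


class ExpressionParseError(ValueError):
    """Malformed expression table (bad header, ragged row, non-numeric cell)."""


class GmtParseError(ValueError):
    """Malformed GMT line (fewer than three tab-separated fields)."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples, with sample annotations.

    ``values`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns.  ``annotations`` is indexed by sample ID; samples without
    annotations carry empty strings.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty expression matrix (zero genes or samples)")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")
        if self.annotations is None:
            self.annotations = _empty_annotations(self.values.columns)
        else:
            # keep only samples present in the matrix; fill gaps with empty
            ann = self.annotations.reindex(self.values.columns)
            for col in ANNOTATION_FIELDS:
                if col not in ann.columns:
                    ann[col] = ""
            self.annotations = ann[list(ANNOTATION_FIELDS)].fillna("")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present].copy(), self.annotations.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)].copy(), self.annotations.loc[list(samples)].copy()
        )


def _empty_annotations(sample_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {c: [""] * len(sample_ids) for c in ANNOTATION_FIELDS},
        index=pd.Index(sample_ids, name="sample_id"),
    )


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: set[str] = set()
        unique = []
        for g in self.genes:
            if g in seen:
                continue
            seen.add(g)
            unique.append(g)
        if len(unique) != len(self.genes):
            warnings.warn(
                f"gene set {self.name!r}: duplicate genes dropped (first occurrence kept)",
                stacklevel=3,
            )
            self.genes = unique

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> GeneSet (GMT file in memory)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} does not match set name {gs.name!r}")

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def load_expression(path, annotation_path=None) -> ExpressionMatrix:
    """Load a tab-delimited genes-x-samples table, collapsing duplicate genes.

    First column holds gene IDs, the header row sample IDs.  Duplicate gene
    rows are collapsed to the row with the highest variance across samples.
    An optional annotation table (tab-delimited, first column sample ID) is
    attached; samples without a row get empty annotations.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ExpressionParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ExpressionParseError(f"{path}: header must name at least one sample")
        sample_ids = header[1:]
        n = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != n + 1:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: expected {n + 1} fields, got {len(row)}"
                )
            vals = []
            for j, cell in enumerate(row[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ExpressionParseError(
                        f"{path}: line {lineno}, column {j}: non-numeric value {cell!r}"
                    ) from None
            gene_ids.append(row[0])
            rows.append(vals)
    if not gene_ids:
        raise ExpressionParseError(f"{path}: no gene rows")
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=gene_ids, columns=sample_ids)
    values = collapse_duplicate_genes(values)
    annotations = None
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    return ExpressionMatrix(values, annotations)


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene ID, the row with highest variance across samples."""
    if not values.index.has_duplicates:
        return values
    variances = values.var(axis=1, ddof=1).to_numpy()
    keep = np.ones(len(values), dtype=bool)
    positions = pd.Series(np.arange(len(values)), index=values.index)
    for gene in values.index[values.index.duplicated()].unique():
        idx = positions[gene].to_numpy()
        best = idx[int(np.argmax(variances[idx]))]
        for i in idx:
            if i != best:
                keep[i] = False
    return values.iloc[keep]


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    ann = ann.set_index(ann.columns[0])
    ann.index.name = "sample_id"
    if ann.index.has_duplicates:
        raise ExpressionParseError(f"{path}: duplicate sample ids in annotation table")
    return ann


def write_expression(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def median_center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (row medians become 0)."""
    centered = m.values.sub(m.values.median(axis=1), axis=0)
    return ExpressionMatrix(centered, m.annotations.copy())


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, genes... per line."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path}: line {lineno}: expected >= 3 fields")
            name, description, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets.values():
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
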