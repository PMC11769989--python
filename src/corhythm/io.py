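"""Tabular I/O and the shared data model.

The pipeline works on three containers:

* :class:`ExpressionMatrix` — a gene × sample grid of counts or
  transformed expression values, with optional per-gene annotations
  (notably a ``chromosome`` flag used to drop Y-linked genes).
* :class:`SampleTable` — per-sample metadata: species, sex, brain region
  and time-of-day in hours after the group's circadian reference
  (lights-on/ZT0 for mouse, sunrise for human).
* :class:`GeneSetCollection` — named gene sets parsed from a GMT file,
  used as pathway definitions for over-representation analysis.

All on-disk formats are plain text: TSV with a header row (CSV accepted
via ``sep=","``) and the standard 3+ field GMT dialect. Gene identifiers
are opaque strings; cross-species comparison assumes the caller supplies
matched identifiers (e.g. upper-cased symbols).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

VALUE_KINDS = ("raw_counts", "log2cpm", "normalized_log2")
SPECIES = ("mouse", "human")
SEXES = ("M", "F")

METADATA_COLUMNS = ("sample_id", "species", "sex", "region", "time_h")


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression grid.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    value_kind
        One of ``raw_counts``, ``log2cpm``, ``normalized_log2``.
    gene_annotations
        Optional per-gene annotation table (index = gene ids); the
        ``chromosome`` column is consulted by the expression filter.
    """

    values: pd.DataFrame
    value_kind: str = "raw_counts"
    gene_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if self.value_kind == "raw_counts":
            if (arr < 0).any():
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw counts must be integral")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def y_flagged(self) -> set[str]:
        """Gene ids annotated as Y-chromosomal."""
        ann = self.gene_annotations
        if ann is None or "chromosome" not in ann.columns:
            return set()
        return set(ann.index[ann["chromosome"].astype(str) == "Y"])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        ann = self.gene_annotations
        if ann is not None:
            ann = ann.loc[ann.index.intersection(gene_ids)]
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.value_kind, ann)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.value_kind, self.gene_annotations
        )


@dataclass
class SampleTable:
    """Validated per-sample metadata with a derived ``group`` label."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        _check_unique(df["sample_id"], "sample")
        bad_sp = set(df["species"]) - set(SPECIES)
        if bad_sp:
            raise ValidationError(f"unknown species token(s): {sorted(bad_sp)}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex token(s): {sorted(bad_sex)}")
        t = pd.to_numeric(df["time_h"], errors="coerce")
        if t.isna().any():
            row = df.loc[t.isna(), "sample_id"].iloc[0]
            raise ValidationError(f"non-numeric time_h for sample {row!r}")
        df = df.copy()
        df["time_h"] = np.asarray(t, dtype=float) % 24.0
        df["group"] = (
            df["species"].astype(str)
            + "_"
            + df["sex"].astype(str)
            + "_"
            + df["region"].astype(str)
        )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def select(self, **criteria) -> "SampleTable":
        """Subset rows by equality on metadata columns (e.g. species='mouse')."""
        df = self.frame
        for col, val in criteria.items():
            df = df[df[col] == val]
        return SampleTable(df.copy())

    def times_for(self, sample_ids) -> np.ndarray:
        s = self.frame.set_index("sample_id")["time_h"]
        return s.loc[list(sample_ids)].to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway definitions) with their source file name."""

    sets: dict[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_counts(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes × samples count table (first column gene ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        orig_na = df[col].isna()
        bad = coerced.isna() & ~orig_na
        if bad.any():
            gene = df.index[bad][0]
            raise ValidationError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        if coerced.isna().any():
            gene = df.index[coerced.isna()][0]
            raise ValidationError(f"missing value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df, value_kind="raw_counts")


def read_metadata(path, sep: str = "\t") -> SampleTable:
    """Read sample metadata (sample_id, species, sex, region, time_h)."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return SampleTable(df)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, provenance=str(path))


def write_counts(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = expr.values
    if expr.value_kind == "raw_counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep=sep, index_label="gene_id")


def write_metadata(samples: SampleTable, path, sep: str = "\t") -> None:
    cols = list(METADATA_COLUMNS)
    samples.frame[cols].to_csv(path, sep=sep, index=False)


def write_gene_annotations(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    if expr.gene_annotations is not None:
        expr.gene_annotations.to_csv(path, sep=sep, index_label="gene_id")


def read_gene_annotations(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df
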