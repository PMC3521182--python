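"""Reading and writing expression matrices, labels and probe→gene mappings.

The on-disk convention is the dominant microarray text format: a tab-delimited
matrix with feature (probe or gene) IDs in the first column and sample IDs in
the header row.  In memory an expression matrix is a pandas DataFrame with
features as rows and samples as columns; class labels are a boolean Series
aligned with the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "read_id_mapping",
    "collapse_to_genes",
    "intersect_features",
]


class ExpressionIOError(ValueError):
    """Raised for malformed expression matrix / label / mapping files."""


@dataclass
class LabeledDataset:
    """An expression matrix (features × samples) plus a binary label per sample.

    ``labels`` is a boolean Series (True = positive class) indexed by sample ID;
    on construction it is reordered to match ``matrix.columns`` and validated.
    """

    matrix: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        cols = self.matrix.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ExpressionIOError(f"duplicate sample ID {dup!r}")
        missing = cols.difference(self.labels.index)
        if len(missing):
            raise ExpressionIOError(f"samples without labels: {list(missing[:5])}")
        self.labels = self.labels.reindex(cols).astype(bool)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def require_both_classes(self) -> "LabeledDataset":
        npos = self.n_positive
        if npos == 0 or npos == self.n_samples:
            raise ExpressionIOError("training use requires both classes present")
        return self


def read_expression_matrix(
    path: str | Path,
    *,
    missing: str = "error",
    transpose: bool = False,
) -> pd.DataFrame:
    """Load a tab-delimited expression matrix.

    Parameters
    ----------
    path
        TSV file: first column feature IDs, first row sample IDs, numeric cells.
    missing
        ``"error"`` (default) rejects any empty or non-numeric cell, naming it;
        ``"impute-sample-median"`` replaces such cells with the median of the
        observed values in the same sample (column).
    transpose
        Set when the file stores samples as rows (the matrix is transposed
        after loading so the in-memory orientation is always features × samples).
    """
    if missing not in ("error", "impute-sample-median"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ExpressionIOError(f"duplicate sample ID {sid!r} in header of {path.name}")
        seen.add(sid)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = sample_ids  # undo any pandas dedup-renaming of the header
    raw = raw.replace("", np.nan)
    values = raw.apply(pd.to_numeric, errors="coerce")

    bad = values.isna() | ~np.isfinite(values.fillna(0.0))
    if bad.to_numpy().any():
        if missing == "error":
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ExpressionIOError(
                f"non-numeric or missing cell at feature {values.index[i]!r}, "
                f"sample {values.columns[j]!r} in {path.name}"
            )
        values = values.mask(bad)
        values = values.fillna(values.median(axis=0))
        if values.isna().to_numpy().any():
            raise ExpressionIOError(f"a sample in {path.name} has no observed values to impute from")
    if transpose:
        values = values.T
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ExpressionIOError(f"duplicate sample ID {dup!r} in {path.name}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    return values


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a features × samples matrix as TSV (first column = feature IDs)."""
    matrix.to_csv(path, sep="\t", index_label="")


def read_labels(path: str | Path, *, positive_label: str = "1") -> pd.Series:
    """Load a two-column TSV of (sample_id, label) into a boolean Series.

    Labels are compared case-insensitively to ``positive_label``; anything else
    is the negative class.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ExpressionIOError(f"label file must have exactly two columns, got {df.shape[1]}")
    sample_ids = df.iloc[:, 0].astype(str)
    if sample_ids.duplicated().any():
        dup = sample_ids[sample_ids.duplicated()].iloc[0]
        raise ExpressionIOError(f"duplicate sample ID {dup!r} in label file")
    labels = df.iloc[:, 1].str.strip().str.lower() == positive_label.lower()
    labels.index = sample_ids
    labels.name = "label"
    return labels


def write_labels(labels: pd.Series, path: str | Path, *, positive_label: str = "1", negative_label: str = "0") -> None:
    out = labels.map({True: positive_label, False: negative_label})
    out.to_csv(path, sep="\t", header=False)


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV of (source_feature_id, target_gene_id).

    Many sources may map to one target; a source mapping to two distinct
    targets is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ExpressionIOError(f"mapping file must have exactly two columns, got {df.shape[1]}")
    mapping: dict[str, str] = {}
    for src, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if src in mapping and mapping[src] != tgt:
            raise ExpressionIOError(f"source ID {src!r} maps to both {mapping[src]!r} and {tgt!r}")
        mapping[src] = tgt
    return mapping


def collapse_to_genes(matrix: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to gene-level rows by the per-sample maximum.

    Probes absent from ``mapping`` are dropped; when several probes map to one
    gene, each sample's representative value is the maximum over those probes
    (the GSEA-recommended collapse used for cross-platform harmonisation).
    """
    keep = matrix.index[matrix.index.isin(mapping.keys())]
    if len(keep) == 0:
        raise ExpressionIOError("no matrix feature appears in the ID mapping")
    sub = matrix.loc[keep]
    genes = pd.Index([mapping[p] for p in keep])
    collapsed = sub.groupby(genes, sort=True).max()
    collapsed.index.name = None
    return collapsed


def intersect_features(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two matrices to their shared feature IDs, in identical order."""
    shared = a.index[a.index.isin(b.index)]
    if len(shared) == 0:
        raise ExpressionIOError("feature sets are disjoint")
    return a.loc[shared], b.loc[shared]
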