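"""Expression-table loading, patient-level sample merging, and expression filters.

The pipeline works on two expression tables: an FPKM-scale gene table whose
rows are mRNAs and lncRNAs, and an RPM-scale miRNA table.  Both are plain TSV
(first column = RNA id, header row = sample ids) and are combined into a
single :class:`ExpressionMatrix` with a class label per row.

Replicate samples of the same patient are merged by arithmetic mean, and
lowly/invariantly expressed RNAs are removed with three criteria applied per
row over the merged samples:

(a) value > 0 in strictly more than ``frac_nonzero`` of samples,
(b) value > ``min_level`` in strictly more than ``frac_above`` of samples,
(c) log2 of the interquartile range strictly above ``min_log2_iqr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class ParseError(ValueError):
    """An input table could not be parsed."""


@dataclass
class ExpressionMatrix:
    """An RNA x sample grid of non-negative expression values.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by unique RNA id, columns by unique sample id.  mRNA and
        lncRNA rows are on an FPKM-like scale, miRNA rows on an RPM-like
        scale.
    rna_class : pandas.Series
        One of ``mRNA | lncRNA | miRNA`` per row id, aligned with
        ``values.index``.
    """

    values: pd.DataFrame
    rna_class: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate RNA ids: {dup[:10]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:10]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = v.index.difference(self.rna_class.index)
        if len(missing):
            raise ValidationError(
                f"RNA ids without a class label: {missing.tolist()[:10]}"
            )
        self.rna_class = self.rna_class.reindex(v.index)
        bad = set(self.rna_class.unique()) - set(RNA_CLASSES)
        if bad:
            raise ValidationError(f"unknown RNA classes: {sorted(bad)}")

    # -- conveniences ----------------------------------------------------
    @property
    def rna_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def ids_of_class(self, rna_class: str) -> list[str]:
        return self.rna_class.index[self.rna_class == rna_class].tolist()

    def class_counts(self) -> dict[str, int]:
        c = self.rna_class.value_counts()
        return {k: int(c.get(k, 0)) for k in RNA_CLASSES}

    def row(self, rna_id: str) -> np.ndarray:
        return self.values.loc[rna_id].to_numpy(dtype=float)

    def subset(self, rna_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = [r for r in self.values.index if r in set(rna_ids)]
        return ExpressionMatrix(self.values.loc[idx], self.rna_class.loc[idx])

    def write_tsv(self, path: str | Path, float_format: str = "%.10g") -> None:
        self.values.to_csv(path, sep="\t", float_format=float_format,
                           index_label="rna_id")


@dataclass(frozen=True)
class FilterCriteria:
    """The three expression filters with their default thresholds.

    ``log_iqr_mode`` selects the reading of the variation criterion:
    ``"log2_of_iqr"`` (default) takes log2 of the raw-scale IQR, so the
    criterion is equivalent to IQR > 2**min_log2_iqr (~1.494 at the default);
    ``"iqr_of_log2"`` takes the IQR of log2(x + 1).  Quartiles use the
    linear-interpolation quantile definition (numpy default).
    """

    frac_nonzero: float = 0.75
    min_level: float = 5.0
    frac_above: float = 0.25
    min_log2_iqr: float = 0.58
    log_iqr_mode: str = "log2_of_iqr"

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_nonzero <= 1.0 and 0.0 < self.frac_above <= 1.0):
            raise ValidationError("filter fractions must lie in (0, 1]")
        if self.min_log2_iqr < 0:
            raise ValidationError("min_log2_iqr must be >= 0")
        if self.log_iqr_mode not in ("log2_of_iqr", "iqr_of_log2"):
            raise ValidationError(f"unknown log_iqr_mode: {self.log_iqr_mode}")


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # pandas messages name the line
        raise ParseError(f"malformed TSV {path}: {exc}") from exc


def read_class_map(path: str | Path) -> pd.Series:
    """Read a two-column ``rna_id <TAB> rna_class`` table into a Series."""
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"class map {path} needs two columns (id, class)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.has_duplicates:
        raise ValidationError(f"duplicate ids in class map {path}")
    return s


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id <TAB> patient_id`` table into a dict."""
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"sample map {path} needs two columns (sample, patient)")
    if df.iloc[:, 0].duplicated().any():
        raise ValidationError(f"duplicate sample ids in sample map {path}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_table(
    path: str | Path, class_map: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Load a TSV expression table and attach RNA class labels.

    Rows whose id is absent from ``class_map`` are rejected (dropped with a
    logged count); all remaining rows must satisfy the
    :class:`ExpressionMatrix` invariants.
    """
    # duplicate sample ids in the header would be silently mangled by pandas
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if len(cols) != len(set(cols)):
        raise ValidationError(f"duplicate sample ids in header of {path}")

    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"non-numeric values in column {col!r} of {path}")
    class_map = pd.Series(dict(class_map)) if not isinstance(class_map, pd.Series) else class_map
    unknown = df.index.difference(class_map.index)
    if len(unknown):
        log.warning("%d row(s) of %s absent from the class map; rejected",
                    len(unknown), path)
        df = df.drop(index=unknown)
    return ExpressionMatrix(df, class_map.reindex(df.index))


def combine_matrices(*matrices: ExpressionMatrix) -> ExpressionMatrix:
    """Stack gene and miRNA matrices sharing the same sample set."""
    base = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != base:
            raise ValidationError("matrices to combine must share sample columns")
    values = pd.concat([m.values for m in matrices], axis=0)
    classes = pd.concat([m.rna_class for m in matrices])
    return ExpressionMatrix(values, classes)


# ---------------------------------------------------------------------------
# operations


def merge_patient_samples(
    matrix: ExpressionMatrix, sample_to_patient: Mapping[str, str]
) -> ExpressionMatrix:
    """Average replicate samples of the same patient into one column.

    Patients appear in the order of their first sample; single-sample
    patients pass through unchanged (up to the column relabel).
    """
    missing = [s for s in matrix.sample_ids if s not in sample_to_patient]
    if missing:
        raise ValidationError(f"samples missing from the patient map: {missing}")
    patients = [sample_to_patient[s] for s in matrix.sample_ids]
    order = list(dict.fromkeys(patients))  # first-occurrence order
    merged = matrix.values.T.groupby(pd.Series(patients, index=matrix.values.columns)).mean().T
    merged = merged[order]
    n_dup = len(patients) - len(order)
    if n_dup:
        log.info("merged %d replicate sample(s) into patient means", n_dup)
    return ExpressionMatrix(merged, matrix.rna_class)


def _row_passes(row: np.ndarray, criteria: FilterCriteria) -> bool:
    if not np.mean(row > 0) > criteria.frac_nonzero:
        return False
    if not np.mean(row > criteria.min_level) > criteria.frac_above:
        return False
    if criteria.log_iqr_mode == "log2_of_iqr":
        iqr = np.quantile(row, 0.75) - np.quantile(row, 0.25)
        if iqr <= 0:
            return False  # log2(0) = -inf fails any non-negative threshold
        return np.log2(iqr) > criteria.min_log2_iqr
    lg = np.log2(row + 1.0)
    return (np.quantile(lg, 0.75) - np.quantile(lg, 0.25)) > criteria.min_log2_iqr


def filter_expressed(
    matrix: ExpressionMatrix,
    criteria: FilterCriteria | None = None,
    keep_list: set[str] | None = None,
) -> ExpressionMatrix:
    """Retain rows passing all three expression criteria (and the keep-list).

    ``keep_list``, when given, additionally restricts the output to listed
    ids — the stand-in for annotation-based exclusions (e.g. mRNAs lacking a
    3'-UTR annotation) that are decided upstream of this package.
    """
    if matrix.n_samples < 2:
        raise ValidationError("filtering needs at least 2 samples")
    criteria = criteria or FilterCriteria()
    arr = matrix.values.to_numpy(dtype=float)
    mask = np.fromiter(
        (_row_passes(arr[i], criteria) for i in range(arr.shape[0])),
        dtype=bool, count=arr.shape[0],
    )
    if keep_list is not None:
        mask &= matrix.values.index.isin(keep_list)
    out = ExpressionMatrix(matrix.values.loc[mask], matrix.rna_class.loc[mask])
    log.info("expression filter retained %s of %d rows",
             out.class_counts(), matrix.values.shape[0])
    return out
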