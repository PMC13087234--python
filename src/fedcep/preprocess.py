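"""EHR table preprocessing: impute -> one-hot encode -> min-max normalize.

The table moves through four tagged states: raw, imputed (no missing cells),
encoded (all feature columns numeric; categoricals expanded to indicators),
and normalized (every feature value in [0, 1]). Per-column min/max from the
normalization step are stored on the table so unseen records can be mapped
into the same feature space at inference time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import LABEL_COLUMN

RAW, IMPUTED, ENCODED, NORMALIZED = "raw", "imputed", "encoded", "normalized"


@dataclass
class EHRTable:
    """A typed patient-record table with an explicit preprocessing state."""

    data: pd.DataFrame
    state: str = RAW
    label_column: str = LABEL_COLUMN
    categorical_columns: tuple[str, ...] | None = None
    #: per-column (min, max) recorded at normalization, for reuse at inference
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: category vocabulary per original categorical column, recorded at encoding
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.categorical_columns is None:
            self.categorical_columns = tuple(
                c for c in self.data.columns
                if c != self.label_column and self.data[c].dtype == object
            )

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != self.label_column]

    @property
    def features(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data[self.label_column].to_numpy(dtype=int)


@dataclass
class PreprocessReport:
    imputed_cells: int = 0
    indicator_columns: list[str] = field(default_factory=list)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"imputed_cells": self.imputed_cells,
             "indicator_columns": self.indicator_columns,
             "ranges": {k: list(v) for k, v in self.ranges.items()}},
            sort_keys=True)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def _impute_column(values: list, numeric: bool, name: str) -> tuple[list, int]:
    n = len(values)
    present = [i for i, v in enumerate(values) if not _is_missing(v)]
    if not present:
        raise DataError(f"column {name!r} is entirely missing")
    out = list(values)
    imputed = 0
    present_arr = np.asarray(present)
    for i in range(n):
        if not _is_missing(values[i]):
            continue
        imputed += 1
        below = present_arr[present_arr < i]
        above = present_arr[present_arr > i]
        prev = int(below[-1]) if below.size else None
        nxt = int(above[0]) if above.size else None
        if prev is None:
            out[i] = values[nxt]
        elif nxt is None:
            out[i] = values[prev]
        elif numeric:
            out[i] = (values[prev] + values[nxt]) / 2.0
        else:
            # nearer neighbour by row distance; tie -> the preceding one
            out[i] = values[prev] if (i - prev) <= (nxt - i) else values[nxt]
    return out, imputed


def impute_missing(table: EHRTable, report: PreprocessReport | None = None) -> EHRTable:
    """Fill missing cells from the nearest non-missing vertical neighbours.

    A numeric gap takes the mean of the nearest non-missing value above and
    below it (row order as given); a boundary cell with a single available
    neighbour copies it. Categorical gaps copy the nearer neighbour, ties
    resolved to the preceding one. The label column is never touched.
    """
    df = table.data.copy()
    total = 0
    for col in table.feature_columns:
        numeric = col not in table.categorical_columns
        vals, k = _impute_column(list(df[col]), numeric, col)
        total += k
        df[col] = vals
        if numeric:
            df[col] = df[col].astype(float)
    if report is not None:
        report.imputed_cells = total
    return EHRTable(df, IMPUTED, table.label_column, table.categorical_columns)


def one_hot_encode(table: EHRTable, report: PreprocessReport | None = None,
                   categories: dict[str, tuple[str, ...]] | None = None) -> EHRTable:
    """Expand each categorical column into lexicographically ordered indicators.

    Column ``c`` with observed categories ``{a, b}`` becomes ``c=a``, ``c=b``;
    exactly one indicator is 1 per row. With an explicit ``categories``
    vocabulary (inference on unseen records) an unknown category yields an
    all-zero indicator vector.
    """
    df = table.data
    out: dict[str, np.ndarray] = {}
    vocab: dict[str, tuple[str, ...]] = {}
    indicator_cols: list[str] = []
    for col in df.columns:
        if col == table.label_column or col not in table.categorical_columns:
            out[col] = df[col].to_numpy()
            continue
        cats = (categories or {}).get(col)
        if cats is None:
            cats = tuple(sorted(set(map(str, df[col]))))
        vocab[col] = cats
        values = df[col].astype(str).to_numpy()
        for cat in cats:
            name = f"{col}={cat}"
            out[name] = (values == cat).astype(float)
            indicator_cols.append(name)
    if report is not None:
        report.indicator_columns = indicator_cols
    new = EHRTable(pd.DataFrame(out), ENCODED, table.label_column, categorical_columns=())
    new.categories = vocab
    return new


def min_max_normalize(table: EHRTable, report: PreprocessReport | None = None,
                      ranges: dict[str, tuple[float, float]] | None = None) -> EHRTable:
    """Map each feature column through (x - min) / (max - min).

    A constant column maps to all zeros. When ``ranges`` is given (inference),
    the stored training min/max is reused and results are clipped to [0, 1].
    """
    df = table.data.copy()
    fitted: dict[str, tuple[float, float]] = {}
    reuse = ranges is not None
    for col in table.feature_columns:
        x = df[col].to_numpy(dtype=float)
        lo, hi = (ranges[col] if reuse else (float(np.min(x)), float(np.max(x))))
        fitted[col] = (lo, hi)
        if hi > lo:
            y = (x - lo) / (hi - lo)
        else:
            y = np.zeros_like(x)
        df[col] = np.clip(y, 0.0, 1.0) if reuse else y
    if report is not None:
        report.ranges = fitted
    new = EHRTable(df, NORMALIZED, table.label_column, categorical_columns=())
    new.ranges = fitted
    new.categories = table.categories
    return new


def preprocess_pipeline(table: EHRTable) -> tuple[EHRTable, PreprocessReport]:
    """impute -> encode -> normalize, with a report of what each stage did."""
    if table.n_rows == 0:
        raise DataError("cannot preprocess an empty table")
    report = PreprocessReport()
    out = min_max_normalize(
        one_hot_encode(impute_missing(table, report), report), report)
    return out, report


def transform_like(train: EHRTable, raw: EHRTable) -> EHRTable:
    """Map unseen raw records into a fitted table's feature space.

    Reuses the training vocabulary (unknown category -> all-zero indicators)
    and the training min/max (values clipped to [0, 1]).
    """
    imputed = impute_missing(raw)
    encoded = one_hot_encode(imputed, categories=train.categories)
    # align column order/sets with the training table
    for col in train.feature_columns:
        if col not in encoded.data.columns:
            encoded.data[col] = 0.0
    encoded.data = encoded.data[[*train.feature_columns, train.label_column]]
    return min_max_normalize(encoded, ranges=train.ranges)
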