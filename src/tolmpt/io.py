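"""CSV input/output for cohort datasets.

Schema: one row per subject with columns ``subject_id``, optional ``group``,
the four cell counts ``n_LL, n_GA, n_SD, n_HH`` (canonical cell order), and
``trials`` (problems per cell, identical for all rows).  Any additional
numeric column is read as a covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Dataset

__all__ = ["read_dataset", "write_dataset"]

COUNT_COLUMNS = ("n_LL", "n_GA", "n_SD", "n_HH")
REQUIRED_COLUMNS = ("subject_id",) + COUNT_COLUMNS + ("trials",)


class DatasetFormatError(ValueError):
    """Raised for malformed cohort CSV files, with the offending row named."""


def read_dataset(path) -> Dataset:
    """Read a cohort CSV, validating counts against the trials-per-cell column."""
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise DatasetFormatError(f"{path}: no subjects")

    for col in COUNT_COLUMNS + ("trials",):
        series = frame[col]
        if series.isna().any():
            row = int(np.nonzero(series.isna().to_numpy())[0][0]) + 2  # 1-based + header
            raise DatasetFormatError(f"{path}: column {col!r} is missing at row {row}")
        try:
            numeric = series.to_numpy(dtype=float)
        except (ValueError, TypeError):
            raise DatasetFormatError(f"{path}: column {col!r} is not numeric")
        as_int = np.round(numeric).astype(np.int64)
        off = np.nonzero(as_int != numeric)[0]
        if off.size:
            raise DatasetFormatError(f"{path}: column {col!r} is not integer at row {int(off[0]) + 2}")
        frame[col] = as_int

    trials = frame["trials"].to_numpy()
    if len(np.unique(trials)) != 1:
        raise DatasetFormatError(f"{path}: all rows must share the same trials value")
    T = int(trials[0])
    if T < 1:
        raise DatasetFormatError(f"{path}: trials must be >= 1")

    counts = frame[list(COUNT_COLUMNS)].to_numpy()
    bad_rows = np.nonzero((counts < 0) | (counts > T))[0]
    if bad_rows.size:
        row = int(bad_rows[0]) + 2
        raise DatasetFormatError(f"{path}: count outside 0..{T} at row {row}")

    group = frame["group"].to_numpy() if "group" in frame.columns else None
    reserved = set(REQUIRED_COLUMNS) | {"group"}
    covariates = {
        col: frame[col].to_numpy(dtype=float)
        for col in frame.columns
        if col not in reserved and pd.api.types.is_numeric_dtype(frame[col])
    }
    return Dataset(
        counts=counts,
        T=T,
        group=group,
        covariates=covariates,
        subject_ids=frame["subject_id"].to_numpy(),
    )


def write_dataset(dataset: Dataset, path) -> None:
    """Write a cohort to CSV in the schema ``read_dataset`` expects."""
    frame = pd.DataFrame(dataset.counts, columns=list(COUNT_COLUMNS))
    ids = dataset.subject_ids if dataset.subject_ids is not None else np.arange(1, dataset.N + 1)
    frame.insert(0, "subject_id", ids)
    if dataset.group is not None:
        frame.insert(1, "group", dataset.group)
    frame["trials"] = dataset.T
    for name, values in dataset.covariates.items():
        frame[name] = values
    frame.to_csv(path, index=False)
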