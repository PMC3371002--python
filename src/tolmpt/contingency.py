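"""2x2 contingency-table tests for class-by-group association.

The Pearson chi-square deliberately applies no continuity correction; the
Fisher exact test uses the two-sided probability-mass convention (sum over
all tables with fixed margins whose probability does not exceed the observed
table's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ContingencyResult", "pearson_chi2_2x2", "fisher_exact_2x2", "association_tests"]


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson and Fisher results for one 2x2 table."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p_value: float
    fisher_p_two_tailed: float


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("table entries must be nonnegative integers")
    return arr.astype(np.int64)


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) and its p-value."""
    arr = _validate_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero margin; the chi-square test is undefined")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p-value (probability-mass convention)."""
    arr = _validate_table(table)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def association_tests(table) -> ContingencyResult:
    """Both tests on one table, as reported for class-by-diagnosis splits."""
    arr = _validate_table(table)
    chi2, p = pearson_chi2_2x2(arr)
    fisher_p = fisher_exact_2x2(arr)
    return ContingencyResult(
        table=tuple(tuple(int(v) for v in row) for row in arr),
        chi2=chi2,
        df=1,
        p_value=p,
        fisher_p_two_tailed=fisher_p,
    )
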