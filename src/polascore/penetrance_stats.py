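"""Count reconstruction from rounded percentages and the paper-style tests.

Penetrance tables print a percentage and a sample size per genotype/region;
the underlying integer count is recovered by brute-force nearest-percentage
search.  Genotype pairs are compared with an uncorrected Pearson chi-square
on the reconstructed 2x2 table; residual distributions are compared with a
classical pooled-variance two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateTableError,
    DegenerateVarianceError,
    InsufficientDataError,
)
from .measurements_io import PCT_COUNT_TOLERANCE, PhenotypeRecord, Region

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "TestMethod",
    "reconstruct_count",
    "pearson_chi2",
    "student_t",
    "enhancement_test",
]

#: Largest |printed pct - 100*c/n| (percentage points) reconstruction accepts
#: silently; covers one-decimal rounding plus small transcription slack.
RECONSTRUCTION_TOLERANCE = PCT_COUNT_TOLERANCE


class TestMethod(str, Enum):
    pearson_chi2 = "pearson_chi2"
    student_t = "student_t"
    welch_t = "welch_t"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts: rows are groups (e.g. genotypes), columns outcomes."""

    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        flat = [c for row in self.counts for c in row]
        if any(c < 0 for c in flat):
            raise ValueError("counts must be non-negative")
        if any(sum(row) == 0 for row in self.counts):
            raise DegenerateTableError("each row must have a positive total")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: TestMethod
    detail: dict = field(default_factory=dict, compare=False)


def reconstruct_count(pct: float, n: int, tol: float = RECONSTRUCTION_TOLERANCE) -> int:
    """Recover the integer count behind a printed percentage.

    Returns the ``c`` in ``0..n`` minimizing ``|pct - 100 c / n|``, breaking
    ties toward the smaller count.  A warning (not an error) is raised when the
    best achievable discrepancy exceeds ``tol`` percentage points, which flags
    a percentage inconsistent with its printed sample size.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    candidates = 100.0 * np.arange(n + 1) / n
    discrepancy = np.abs(candidates - pct)
    c = int(np.argmin(discrepancy))  # argmin takes the first (smaller) tie
    if discrepancy[c] > tol:
        warnings.warn(
            f"reconstruct_count({pct}, {n}): best count {c} gives "
            f"{candidates[c]:.2f}%, off by {discrepancy[c]:.3f} points",
            stacklevel=2,
        )
    return c


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table (df = 1)."""
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(col == 0):
        warnings.warn("pearson_chi2: a column margin is zero; no association testable")
        return TestResult(0.0, 1, 1.0, TestMethod.pearson_chi2)
    expected = np.outer(row, col) / total
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic, 1, p, TestMethod.pearson_chi2)


def student_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> TestResult:
    """Two-sided two-sample t-test, pooled variance by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, len(a) + len(b) - 2, 1.0, TestMethod.student_t)
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = int(res.df) if welch else len(a) + len(b) - 2
    return TestResult(
        float(res.statistic),
        df,
        float(res.pvalue),
        TestMethod.welch_t if welch else TestMethod.student_t,
    )


def _record_for(
    records: Sequence[PhenotypeRecord], genotype: str, region: Region
) -> PhenotypeRecord:
    hits = [r for r in records if r.genotype == genotype and r.region == region]
    if not hits:
        raise KeyError(f"no record for genotype {genotype!r}, region {region.value}")
    if len(hits) > 1:
        raise ValueError(f"multiple records for {genotype!r}/{region.value}")
    return hits[0]


def _missing_count(record: PhenotypeRecord) -> int:
    if record.count_missing is not None:
        return record.count_missing
    return reconstruct_count(record.pct_missing, record.n)


def enhancement_test(
    records: Sequence[PhenotypeRecord],
    genotype_a: str,
    genotype_b: str,
    region: Region | str,
) -> TestResult:
    """Chi-square comparison of missing-phenotype penetrance between two genotypes.

    Counts are taken from ``count_missing`` when present, otherwise
    reconstructed from the printed percentage.  The reconstructed 2x2 table is
    attached to the result's ``detail`` for auditability.
    """
    region = Region(region)
    rec_a = _record_for(records, genotype_a, region)
    rec_b = _record_for(records, genotype_b, region)
    miss_a, miss_b = _missing_count(rec_a), _missing_count(rec_b)
    table = ContingencyTable2x2(
        row_labels=(genotype_a, genotype_b),
        col_labels=("missing", "present"),
        counts=((miss_a, rec_a.n - miss_a), (miss_b, rec_b.n - miss_b)),
    )
    result = pearson_chi2(table)
    return TestResult(
        result.statistic,
        result.df,
        result.p_value,
        result.method,
        detail={
            "region": region.value,
            "counts": table.counts,
            "row_labels": table.row_labels,
            "col_labels": table.col_labels,
        },
    )
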