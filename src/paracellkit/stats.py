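"""Summary statistics and the variance-gated multiple-comparison procedure.

The workflow mirrors common practice in epithelial physiology papers:
data are reported as mean +/- SEM, homogeneity of variances is screened
with Bartlett's test, and each treatment group is compared against a
designated reference group by a two-sided two-sample t test with
Bonferroni correction (raw p multiplied by the number of comparisons
actually performed, capped at 1).

When Bartlett rejects equal variances the pairwise comparisons are still
emitted, computed with Welch's t test and flagged (``variance_ok=False``,
``test='welch'``) so downstream consumers can decide what to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateDesignError, OutOfRangeError

__all__ = [
    "MeanSem",
    "PairwiseComparison",
    "ComparisonReport",
    "mean_sem",
    "bartlett_test",
    "pairwise_bonferroni",
    "compare_groups",
]


@dataclass(frozen=True)
class MeanSem:
    mean: float
    sem: float
    n: int
    degenerate_n: bool = False


@dataclass(frozen=True)
class PairwiseComparison:
    group: str
    t_stat: float
    raw_p: float
    adjusted_p: float
    significant: bool
    test: str = "student"
    skipped: bool = False


@dataclass(frozen=True)
class ComparisonReport:
    reference: str
    alpha: float
    bartlett_stat: float
    bartlett_p: float
    variance_ok: bool
    pairwise: tuple[PairwiseComparison, ...] = field(default_factory=tuple)


def mean_sem(values: Sequence[float]) -> MeanSem:
    """Sample mean and SEM (sample SD with n-1 denominator over sqrt(n)).

    n = 1 is allowed: SEM is reported as 0 with ``degenerate_n=True``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DegenerateDesignError("mean_sem of an empty sample")
    if arr.size == 1:
        return MeanSem(float(arr[0]), 0.0, 1, degenerate_n=True)
    return MeanSem(float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size)), int(arr.size))


def bartlett_test(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Bartlett's chi-square statistic (k-1 df) and upper-tail p-value."""
    if len(groups) < 2:
        raise DegenerateDesignError("Bartlett's test needs >= 2 groups")
    arrays = []
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise DegenerateDesignError(f"group {name!r} has n < 2")
        if arr.std(ddof=1) == 0:
            raise DegenerateDesignError(f"group {name!r} has zero variance: statistic undefined")
        arrays.append(arr)
    stat, p = _sps.bartlett(*arrays)
    return float(stat), float(p)


def pairwise_bonferroni(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[PairwiseComparison]:
    """Each non-reference group vs the reference, Bonferroni-adjusted.

    The correction multiplier m counts only the comparisons actually
    performed (skipped groups with n < 2 do not inflate m).
    """
    if reference not in groups:
        raise OutOfRangeError(f"reference group {reference!r} not among groups")
    if not 0 < alpha < 1:
        raise OutOfRangeError(f"alpha must be in (0,1), got {alpha}")
    ref = np.asarray(list(groups[reference]), dtype=float)
    if ref.size < 2:
        raise DegenerateDesignError(f"reference group {reference!r} has n < 2")

    performed: list[tuple[str, float, float]] = []
    skipped: list[str] = []
    for name, vals in groups.items():
        if name == reference:
            continue
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            skipped.append(name)
            continue
        t, p = _sps.ttest_ind(arr, ref, equal_var=equal_var)
        performed.append((name, float(t), float(p)))

    m = len(performed)
    out: list[PairwiseComparison] = []
    test_name = "student" if equal_var else "welch"
    for name, t, p in performed:
        adj = min(1.0, p * m)
        out.append(PairwiseComparison(name, t, p, adj, adj < alpha, test=test_name))
    for name in skipped:
        out.append(
            PairwiseComparison(name, math.nan, math.nan, math.nan, False, test_name, skipped=True)
        )
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Full procedure: Bartlett gate, then Bonferroni-corrected t tests.

    Pooled-variance t is used when Bartlett does not reject at ``alpha``;
    otherwise Welch's t, with ``variance_ok=False`` in the report.
    """
    stat, p = bartlett_test(groups)
    variance_ok = p >= alpha
    pairwise = pairwise_bonferroni(groups, reference, alpha=alpha, equal_var=variance_ok)
    return ComparisonReport(
        reference=reference,
        alpha=alpha,
        bartlett_stat=stat,
        bartlett_p=p,
        variance_ok=variance_ok,
        pairwise=tuple(pairwise),
    )
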