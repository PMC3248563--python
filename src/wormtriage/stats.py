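"""Small statistical helpers shared by the triage and expression modules."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientReplicatesError

__all__ = [
    "TestResult",
    "student_t_test",
    "two_proportion_z_test",
    "round_half_away",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None


def student_t_test(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sample two-sided t-test; classic pooled-variance Student by default.

    ``welch=True`` drops the equal-variance assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError("t-test needs >= 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate samples: identical means are indistinguishable, distinct
        # means are separated with certainty
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, float(df))
        return TestResult(math.inf if a.mean() > b.mean() else -math.inf, 0.0, float(df))
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else float(res.df)
    return TestResult(float(res.statistic), float(res.pvalue), float(df))


def two_proportion_z_test(
    k1: int, n1: int, k2: int, n2: int
) -> TestResult:
    """Two-sided two-proportion z-test with a pooled variance estimate.

    Degenerate pooled proportions (0 or 1 in both groups combined) yield
    z = 0, p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise InsufficientReplicatesError("z-test needs n >= 1 in both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return TestResult(0.0, 1.0)
    z = (p1 - p2) / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return TestResult(z, min(p, 1.0))


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (5.5 -> 6, -5.5 -> -6)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))
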