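"""Group-comparison tests: Welch's unequal-variance t-test and the
Mann-Whitney U test with exact small-sample p-values.

Both statistics are computed from first principles here.  The Welch t
statistic and Welch-Satterthwaite degrees of freedom are evaluated
directly and the two-sided p obtained from the t distribution; the df is
reported real-valued (not rounded or pooled).  The Mann-Whitney test uses
the exact null distribution of U — built by the classic rank-sum
recurrence N(n1, n2, u) = N(n1-1, n2, u-n2) + N(n1, n2-1, u) — whenever
both samples are small and no ties span the groups, and otherwise falls
back to the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for degenerate samples (too small, zero variance with equal means)."""


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str  # exact | normal_approx_tie_corrected


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's independent-samples t-test (two-sided).

    t = (mean(a) - mean(b)) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("samples must be finite")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0:
        if diff == 0:
            raise StatsError("zero variance in both samples with equal means")
        # deterministic separation: infinite evidence
        return WelchResult(t=float(np.sign(diff)) * float("inf"), df=float(na + nb - 2), p=0.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0))


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value, for tie-free samples.

    Returns counts for U = 0 .. n1*n2; the total is C(n1+n2, n1).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)  # shifted by n2: largest obs in sample 1
    b = _u_counts(n1, n2 - 1)  # largest obs in sample 2
    size = n1 * n2 + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def exact_u_cdf(u: float, n1: int, n2: int) -> float:
    """P(U <= u) under the exact tie-free null distribution."""
    counts = _u_counts(n1, n2)
    total = sum(counts)
    return sum(counts[: int(np.floor(u)) + 1]) / total


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_max: int = 20
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The reported U is the count of (a, b) pairs with a > b (ties counting
    one half).  Exact enumeration is used when both n <= exact_max and no
    tie spans the two groups; otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    cross_ties = bool(set(a.tolist()) & set(b.tolist()))
    if n1 <= exact_max and n2 <= exact_max and not cross_ties:
        p = min(1.0, 2.0 * exact_u_cdf(min(u1, u2), n1, n2))
        return MannWhitneyResult(U=float(u1), p=p, method="exact")

    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        # all observations identical: no evidence either way
        return MannWhitneyResult(U=float(u1), p=1.0, method="normal_approx_tie_corrected")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * float(sps.norm.sf(z))
    return MannWhitneyResult(
        U=float(u1), p=min(p, 1.0), method="normal_approx_tie_corrected"
    )
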