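"""Exact minimum-hypergeometric (mHG) statistic on binary vectors.

The mHG statistic of a ranked binary vector is the minimum, over all prefixes,
of the hypergeometric tail probability of the observed prefix one-count.  Since
prefixes are dependent, the raw minimum is not a p-value; the exact corrected
p-value is obtained from the cumulative distribution of the statistic under
uniform random placement of the B ones among N positions, computed by a lattice
dynamic program over the (prefix length, one-count) grid.

All numbers here are floating point; a rational-arithmetic enumeration oracle
used in the test suite certifies the dynamic program on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "MHGResult",
    "hypergeometric_tail",
    "tail_table",
    "mhg_statistic",
    "mhg_exact_pvalue",
    "mhg_test",
]

#: relative slack used when comparing floating-point tail probabilities against
#: a score threshold; far below the spacing of distinct achievable tails.
_REL_TOL = 1e-9


@dataclass(frozen=True)
class MHGResult:
    """Outcome of an mHG evaluation.

    Attributes
    ----------
    score : float
        Minimum hypergeometric tail over all prefixes, in (0, 1].
    threshold_n : int
        Smallest prefix length attaining the minimum (1..N).
    b_at_threshold : int
        Number of '1' labels within that prefix.
    pvalue : float or None
        Exact corrected p-value (None until computed).
    """

    score: float
    threshold_n: int
    b_at_threshold: int
    pvalue: Optional[float] = None

    def with_pvalue(self, pvalue: float) -> "MHGResult":
        return MHGResult(self.score, self.threshold_n, self.b_at_threshold, pvalue)


def _validate_nbnb(N: int, B: int, n, b) -> None:
    n = np.asarray(n)
    b = np.asarray(b)
    if N < 1 or not (0 <= B <= N):
        raise ValueError(f"invalid (N={N}, B={B})")
    if np.any(n < 0) or np.any(n > N):
        raise ValueError("prefix length n out of [0, N]")
    if np.any(b < 0) or np.any(b > np.minimum(n, B)):
        raise ValueError("prefix one-count b out of [0, min(n, B)]")


def hypergeometric_tail(N: int, B: int, n, b):
    """Upper hypergeometric tail P(X >= b) for X ~ HG(N, B, n).

    Equals ``sum_{i=b}^{min(n,B)} C(n,i) C(N-n,B-i) / C(N,B)``.  Vectorised
    over ``n`` and ``b``; raises on invalid bounds.
    """
    _validate_nbnb(N, B, n, b)
    out = hypergeom.sf(np.asarray(b) - 1, N, B, n)
    if np.ndim(out) == 0:
        return float(out)
    return out


@lru_cache(maxsize=128)
def tail_table(N: int, B: int) -> np.ndarray:
    """Table ``T[n, b]`` of hypergeometric tails for all valid prefixes.

    Shape (N+1, B+1); invalid cells (b > min(n, B)) hold 0 so that taking a
    minimum over achievable cells is still safe via explicit masking by the
    caller (the mHG routines below only index valid cells).
    """
    n = np.arange(N + 1)[:, None]
    b = np.arange(B + 1)[None, :]
    T = hypergeom.sf(b - 1, N, B, n)
    T[b > np.minimum(n, B)] = 0.0
    T.setflags(write=False)
    return T


def _as_labels(v: Sequence[int]) -> np.ndarray:
    labels = np.asarray(v, dtype=np.int64)
    if labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels must be a non-empty 1D binary sequence")
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be 0/1")
    return labels


def mhg_statistic(v: Sequence[int]) -> MHGResult:
    """Minimum hypergeometric tail over all prefixes of a binary vector.

    Degenerate vectors (B = 0 or B = N) return score 1 at threshold 1 by
    convention.  Ties in the minimum resolve to the smallest prefix length.
    """
    labels = _as_labels(v)
    N = labels.size
    B = int(labels.sum())
    if B == 0 or B == N:
        return MHGResult(1.0, 1, int(labels[0]))
    T = tail_table(N, B)
    b_n = np.cumsum(labels)
    tails = T[np.arange(1, N + 1), b_n]
    i = int(np.argmin(tails))
    return MHGResult(float(tails[i]), i + 1, int(b_n[i]))


def mhg_exact_pvalue(N: int, B: int, s: float) -> float:
    """Exact P(mHG <= s) under uniform placement of B ones among N slots.

    A path on the (n, b) lattice from (0, 0) to (N, B) describes one label
    arrangement; the arrangement attains mHG <= s iff the path touches a cell
    whose hypergeometric tail is <= s.  The DP sweeps prefix lengths carrying
    the probability of reaching each (n, b) without having touched such a cell;
    the complement of the surviving mass at (N, B) is the p-value.
    Probabilities (not path counts) are carried to avoid overflow.
    """
    if not s > 0:
        raise ValueError("score s must be in (0, 1]")
    if N < 1 or not (0 <= B <= N):
        raise ValueError(f"invalid (N={N}, B={B})")
    if B == 0 or B == N:
        # single arrangement; its mHG is 1 by convention
        return 1.0 if s >= 1 else 0.0
    T = tail_table(N, B)
    thr = s * (1.0 + _REL_TOL)
    b_axis = np.arange(B + 1, dtype=np.float64)
    # f[b] = P(reach (n, b) with every visited tail > s); the p-value is the
    # mass absorbed by rejection cells, accumulated directly so that tiny
    # p-values suffer no 1-minus-survival cancellation
    f = np.zeros(B + 1)
    f[0] = 1.0
    absorbed = 0.0
    for n in range(1, N + 1):
        remaining = N - (n - 1)
        p_one = (B - b_axis) / remaining  # P(next label is 1 | state (n-1, b))
        f_new = np.empty(B + 1)
        f_new[0] = f[0] * (1.0 - p_one[0])
        f_new[1:] = f[1:] * (1.0 - p_one[1:]) + f[:-1] * p_one[:-1]
        valid = b_axis <= min(n, B)
        reject = valid & (T[n, :] <= thr)
        absorbed += float(f_new[reject].sum())
        f_new[reject] = 0.0
        f_new[~valid] = 0.0
        f = f_new
    return float(min(1.0, absorbed))


def mhg_test(v: Sequence[int]) -> MHGResult:
    """mHG statistic plus its exact corrected p-value for one binary vector."""
    labels = _as_labels(v)
    res = mhg_statistic(labels)
    N = labels.size
    B = int(labels.sum())
    if B == 0 or B == N:
        return res.with_pvalue(1.0)
    return res.with_pvalue(mhg_exact_pvalue(N, B, res.score))
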