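"""Labelled point clouds, bisector arrangements and pivot generation.

A pivot is an arbitrary point in the embedding space; ranking the labelled
bins by Euclidean distance from it yields the binary vector scored by the mHG
statistic.  The perpendicular bisecting hyperplane between each ('1', '0')
point pair tessellates space into convex cells over which that ranking is
constant, so one pivot per cell covers every distinct ranking.  The sampling
strategy generates one representative pivot per d-tuple of bisectors by
perturbing their intersection point ("bottom-most" cell representative).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .mhg import MHGResult, mhg_statistic, tail_table

__all__ = [
    "LabeledCloud",
    "Bisector",
    "BisectorSet",
    "PivotScore",
    "DegenerateTupleError",
    "build_bisectors",
    "rank_by_distance",
    "score_pivot",
    "sample_pivot_from_tuple",
    "enumerate_sample_pivots",
    "default_epsilon",
]


class DegenerateTupleError(ValueError):
    """Raised when a bisector tuple has no unique intersection point."""


@dataclass
class LabeledCloud:
    """Embedded genomic bins with binary labels: the dataset D = {x_i, y_i}.

    coords are N points in 2 or 3 dimensions; labels are 0/1 per point; chrom
    and bin_index give the genomic identity of each point (bin_index strictly
    increasing within each chromosome).
    """

    coords: np.ndarray
    labels: np.ndarray
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be (N, d) with d in {2, 3}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.coords.shape[0],):
            raise ValueError("labels must be length-N")
        if np.any((self.labels != 0) & (self.labels != 1)):
            raise ValueError("labels must be 0/1")
        n = self.coords.shape[0]
        if self.chrom is None:
            self.chrom = np.array(["chr1"] * n, dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.bin_index is None:
            self.bin_index = np.arange(n, dtype=np.int64)
        else:
            self.bin_index = np.asarray(self.bin_index, dtype=np.int64)
        for c in np.unique(self.chrom.astype(str)):
            bi = self.bin_index[self.chrom.astype(str) == c]
            if bi.size > 1 and np.any(np.diff(bi) <= 0):
                raise ValueError(f"bin_index not strictly increasing on {c}")

    @property
    def N(self) -> int:
        return self.coords.shape[0]

    @property
    def B(self) -> int:
        return int(self.labels.sum())

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def with_labels(self, labels) -> "LabeledCloud":
        return LabeledCloud(self.coords, labels, self.chrom, self.bin_index)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.coords.min(axis=0), self.coords.max(axis=0)


@dataclass(frozen=True)
class Bisector:
    """Hyperplane equidistant from one '1'-labelled and one '0'-labelled point.

    coeffs holds (a, b[, c], d) of a·X + b·Y [+ c·Z] + d = 0 with unit normal
    pointing toward the positive point: the plane value is positive exactly
    where a pivot is strictly closer to the generating '1' point ("satisfied").
    """

    coeffs: tuple
    pos_idx: int
    neg_idx: int

    @property
    def normal(self) -> np.ndarray:
        return np.asarray(self.coeffs[:-1])

    @property
    def offset(self) -> float:
        return self.coeffs[-1]


class BisectorSet:
    """Vectorised container of bisectors (unit normals and offsets)."""

    def __init__(self, normals: np.ndarray, offsets: np.ndarray,
                 pos_idx: np.ndarray, neg_idx: np.ndarray):
        self.normals = np.asarray(normals, dtype=np.float64)
        self.offsets = np.asarray(offsets, dtype=np.float64)
        self.pos_idx = np.asarray(pos_idx, dtype=np.int64)
        self.neg_idx = np.asarray(neg_idx, dtype=np.int64)

    def __len__(self) -> int:
        return self.normals.shape[0]

    def __getitem__(self, i: int) -> Bisector:
        return Bisector(tuple(self.normals[i]) + (float(self.offsets[i]),),
                        int(self.pos_idx[i]), int(self.neg_idx[i]))

    def __iter__(self) -> Iterator[Bisector]:
        return (self[i] for i in range(len(self)))

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Signed plane values, shape (n_points, n_bisectors)."""
        pts = np.atleast_2d(points)
        return pts @ self.normals.T + self.offsets

    def satisfied(self, pivot: np.ndarray) -> np.ndarray:
        """True where the pivot is strictly closer to the '1' point."""
        return self.values_at(pivot)[0] > 0


@dataclass(frozen=True)
class PivotScore:
    """A scored pivot: mHG result plus the ball radius realising it."""

    pivot: np.ndarray
    result: MHGResult
    radius: float


def build_bisectors(cloud: LabeledCloud) -> BisectorSet:
    """All perpendicular bisectors between oppositely labelled points.

    One bisector per ('1', '0') pair, ordered lexicographically by
    (pos_idx, neg_idx); coincident opposite-label pairs are skipped with a
    warning (no defined bisector).  Count is B(N-B) minus skipped pairs.
    """
    if cloud.N < 2:
        raise ValueError("need at least two points")
    pos = np.flatnonzero(cloud.labels == 1)
    neg = np.flatnonzero(cloud.labels == 0)
    if pos.size == 0 or neg.size == 0:
        return BisectorSet(np.empty((0, cloud.d)), np.empty(0),
                           np.empty(0, int), np.empty(0, int))
    pi, ni = np.meshgrid(pos, neg, indexing="ij")
    pi, ni = pi.ravel(), ni.ravel()
    xp, xn = cloud.coords[pi], cloud.coords[ni]
    diff = xp - xn
    norm = np.linalg.norm(diff, axis=1)
    ok = norm > 0
    if not np.all(ok):
        warnings.warn(f"skipping {int((~ok).sum())} coincident opposite-label "
                      "pair(s) with no defined bisector")
        pi, ni, xp, xn, diff, norm = (a[ok] for a in (pi, ni, xp, xn, diff, norm))
    normals = diff / norm[:, None]
    mid = 0.5 * (xp + xn)
    offsets = -np.einsum("ij,ij->i", normals, mid)
    return BisectorSet(normals, offsets, pi, ni)


def rank_by_distance(pivot, cloud: LabeledCloud) -> tuple[np.ndarray, np.ndarray]:
    """Binary vector induced by ranking points by distance from the pivot.

    Returns (ranked labels, permutation).  Distance ties break by input index
    (stable sort), a measure-zero event for embedded data.
    """
    pivot = np.asarray(pivot, dtype=np.float64)
    if not np.all(np.isfinite(pivot)):
        raise ValueError("pivot must be finite")
    dist = np.linalg.norm(cloud.coords - pivot, axis=1)
    order = np.argsort(dist, kind="stable")
    return cloud.labels[order], order


def score_pivot(pivot, cloud: LabeledCloud) -> PivotScore:
    """mHG score of one pivot, with the ball radius of the optimal prefix."""
    pivot = np.asarray(pivot, dtype=np.float64)
    lam, order = rank_by_distance(pivot, cloud)
    res = mhg_statistic(lam)
    radius = float(np.linalg.norm(cloud.coords[order[res.threshold_n - 1]] - pivot))
    return PivotScore(pivot, res, radius)


def default_epsilon(cloud: LabeledCloud) -> float:
    """Default perturbation step: 1e-6 of the bounding-box diagonal."""
    lo, hi = cloud.bounding_box()
    diag = float(np.linalg.norm(hi - lo))
    return 1e-6 * diag if diag > 0 else 1e-6


def _pc_point(A: np.ndarray, off: np.ndarray, p: np.ndarray,
              eps: float) -> np.ndarray:
    """The perturbed-intersection cell representative.

    Generic path (every bisector has a nonzero X coefficient): perturb Y by
    +eps, re-solve every bisector for X and average — the cell's bottom-most
    representative with respect to Y.  When some bisector has a zero X
    coefficient the roles of coordinates are permuted per bisector (each
    solves its own largest-coefficient axis, all other axes perturbed), which
    reduces to the generic construction whenever that one applies.
    """
    d = A.shape[1]
    if np.min(np.abs(A[:, 0])) > 1e-12:
        q = p.copy()
        q[1] += eps
        solved = -(A[:, 1:] @ q[1:] + off) / A[:, 0]
        q[0] = float(np.mean(solved))
        return q
    dep = np.argmax(np.abs(A), axis=1)
    if np.any(np.abs(A[np.arange(d), dep]) <= 1e-12):
        raise DegenerateTupleError("bisector with zero normal")
    q = p + eps
    pts = np.repeat(q[None, :], d, axis=0)
    for i in range(d):
        li = dep[i]
        rest = A[i] @ q - A[i, li] * q[li] + off[i]
        pts[i, li] = -rest / A[i, li]
    return pts.mean(axis=0)


def sample_pivot_from_tuple(bisectors: Sequence[Bisector] | BisectorSet,
                            eps: float,
                            indices: Optional[Sequence[int]] = None) -> np.ndarray:
    """Cell representative from d bisectors: perturbed intersection point.

    Solves the d x d linear system for the intersection, takes an eps-step
    off each bisector (re-solving each for its dependent coordinate) and
    averages the resulting points — yielding a point strictly inside one
    adjacent cell.  Raises DegenerateTupleError for parallel/degenerate
    tuples.
    """
    if isinstance(bisectors, BisectorSet):
        idx = np.asarray(indices if indices is not None else range(len(bisectors)))
        A = bisectors.normals[idx]
        off = bisectors.offsets[idx]
    else:
        A = np.stack([np.asarray(b.coeffs[:-1], float) for b in bisectors])
        off = np.array([b.coeffs[-1] for b in bisectors], float)
    d = A.shape[1]
    if A.shape[0] != d:
        raise ValueError(f"need exactly {d} bisectors in {d}D")
    if abs(np.linalg.det(A)) < 1e-12:
        raise DegenerateTupleError("bisectors do not meet at a unique point")
    p = np.linalg.solve(A, -off)
    return _pc_point(A, off, p, eps)


def enumerate_sample_pivots(cloud: LabeledCloud,
                            eps: Optional[float] = None,
                            max_pivots: Optional[int] = None,
                            seed: Optional[int] = None) -> np.ndarray:
    """One pivot per non-degenerate d-tuple of bisectors.

    In general position yields C(m, d) pivots with m = B(N-B) bisectors.
    When ``max_pivots`` is given and the full enumeration exceeds it, that
    many tuples are drawn at random (seeded) instead — the large-instance
    scaling device; degenerate tuples are skipped.
    Returns an array of shape (n_pivots, d).
    """
    if cloud.N < 2:
        raise ValueError("need at least two points")
    if eps is None:
        eps = default_epsilon(cloud)
    bis = build_bisectors(cloud)
    m, d = len(bis), cloud.d
    if m < d:
        return np.empty((0, d))
    from math import comb
    total = comb(m, d)
    if max_pivots is not None and total > max_pivots:
        rng = np.random.default_rng(seed)
        # d distinct bisectors per tuple via random-key selection
        keys = rng.random((max_pivots, m))
        tuples = np.argpartition(keys, d, axis=1)[:, :d].astype(np.int64)
    else:
        tuples = np.fromiter(itertools.chain.from_iterable(
            itertools.combinations(range(m), d)), dtype=np.int64,
            count=total * d).reshape(total, d)
    A = bis.normals[tuples]               # (T, d, d)
    off = bis.offsets[tuples]             # (T, d)
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} degenerate bisector tuple(s)")
    A, off = A[ok], off[ok]
    if A.shape[0] == 0:
        return np.empty((0, d))
    p = np.linalg.solve(A, -off[..., None])[..., 0]   # (T, d) intersections
    generic = np.abs(A[:, :, 0]).min(axis=1) > 1e-12  # paper path: solve X, bump Y
    q = p.copy()
    qg, Ag, offg = q[generic], A[generic], off[generic]
    qg[:, 1] += eps
    num = np.einsum("tij,tj->ti", Ag, qg) + offg
    num -= Ag[:, :, 0] * qg[:, 0][:, None]            # drop stale X contribution
    qg[:, 0] = (-num / Ag[:, :, 0]).mean(axis=1)
    q[generic] = qg
    for t in np.flatnonzero(~generic):                # rare axis-degenerate tuples
        q[t] = _pc_point(A[t], off[t], p[t], eps)
    return q
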