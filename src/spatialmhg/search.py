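"""Search strategies minimising the spatial mHG objective over pivots.

Two heuristics, as in the field: an exhaustive/sub-sampled enumeration of
cell-representative pivots derived from bisector tuples, and an octree
branch-and-bound over space with a sound per-cube lower bound on the best
achievable score.  Both return upper bounds on the true spatial optimum; a
brute-force oracle for tiny instances provides test ground truth.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np

from .geometry import (BisectorSet, LabeledCloud, PivotScore, build_bisectors,
                       default_epsilon, enumerate_sample_pivots)
from .mhg import MHGResult, mhg_exact_pvalue, tail_table

__all__ = [
    "SearchResult",
    "GridCube",
    "ScoreContext",
    "smhg_sample",
    "smhg_grid",
    "cube_lower_bound",
    "exhaustive_oracle",
    "ResourceGuardError",
]


class ResourceGuardError(RuntimeError):
    """Raised when a brute-force routine would exceed sane desk-scale limits."""


@dataclass
class SearchResult:
    """Best pivot found by one strategy."""

    best: PivotScore
    method: str
    pivots_evaluated: int
    opt_trace: list = field(default_factory=list)
    chrom: Optional[str] = None

    @property
    def score(self) -> float:
        return self.best.result.score

    def with_pvalue(self) -> "SearchResult":
        """Attach the exact per-pivot corrected p-value to the best result."""
        r = self.best.result
        if r.pvalue is None:
            N, B = self._nb
            p = 1.0 if B in (0, N) else mhg_exact_pvalue(N, B, r.score)
            self.best = PivotScore(self.best.pivot, r.with_pvalue(p), self.best.radius)
        return self

    _nb: tuple = (0, 0)


class ScoreContext:
    """Batch pivot scorer for one labelled cloud (caches the tail table)."""

    def __init__(self, cloud: LabeledCloud):
        self.cloud = cloud
        self.N = cloud.N
        self.B = cloud.B
        self._degenerate = self.B in (0, self.N)
        if not self._degenerate:
            self.T = tail_table(self.N, self.B)

    def score_batch(self, pivots: np.ndarray):
        """Score many pivots at once.

        Returns (scores, threshold_n, b_at_threshold, radius) arrays.
        """
        pivots = np.atleast_2d(np.asarray(pivots, dtype=np.float64))
        P = pivots.shape[0]
        if self._degenerate:
            d0 = np.linalg.norm(self.cloud.coords - pivots[:, None, :], axis=2)
            rad = np.sort(d0, axis=1)[:, 0] if self.N else np.zeros(P)
            return (np.ones(P), np.ones(P, int), np.full(P, int(self.cloud.labels[0]) if self.N else 0),
                    rad)
        dist = np.linalg.norm(self.cloud.coords[None, :, :] - pivots[:, None, :], axis=2)
        order = np.argsort(dist, axis=1, kind="stable")
        lam = self.cloud.labels[order]
        b_n = np.cumsum(lam, axis=1)
        tails = self.T[np.arange(1, self.N + 1)[None, :], b_n]
        k = np.argmin(tails, axis=1)
        rows = np.arange(P)
        score = tails[rows, k]
        thr = k + 1
        b_thr = b_n[rows, k]
        radius = np.take_along_axis(dist, order, axis=1)[rows, k]
        return score, thr, b_thr, radius

    def score_one(self, pivot) -> PivotScore:
        s, n, b, r = self.score_batch(np.asarray(pivot)[None, :])
        return PivotScore(np.asarray(pivot, float),
                          MHGResult(float(s[0]), int(n[0]), int(b[0])), float(r[0]))

    def best_of(self, pivots: np.ndarray, chunk: int = 50_000) -> PivotScore:
        pivots = np.atleast_2d(pivots)
        best: Optional[PivotScore] = None
        for start in range(0, pivots.shape[0], chunk):
            block = pivots[start:start + chunk]
            s, n, b, r = self.score_batch(block)
            # ties on the score resolve to the tightest ball
            i = int(np.lexsort((r, s))[0])
            if best is None or (s[i], r[i]) < (best.result.score, best.radius):
                best = PivotScore(block[i],
                                  MHGResult(float(s[i]), int(n[i]), int(b[i])),
                                  float(r[i]))
        return best


def _finish(res: SearchResult, cloud: LabeledCloud) -> SearchResult:
    res._nb = (cloud.N, cloud.B)
    return res


def smhg_sample(cloud: LabeledCloud,
                eps: Optional[float] = None,
                max_pivots: Optional[int] = None,
                seed: Optional[int] = None) -> SearchResult:
    """Sampling search: every tuple-derived pivot plus every bead pivot.

    Bead pivots are always included so degenerate instances (too few
    bisectors) are still covered.  ``max_pivots`` sub-samples tuples on large
    instances (seeded); exhaustive otherwise.
    """
    ctx = ScoreContext(cloud)
    if cloud.N < 2 or ctx._degenerate:
        best = ctx.score_one(cloud.coords[0])
        return _finish(SearchResult(best, "sample", 1), cloud)
    pivots = enumerate_sample_pivots(cloud, eps=eps, max_pivots=max_pivots, seed=seed)
    allp = np.vstack([pivots, cloud.coords]) if pivots.size else cloud.coords
    best = ctx.best_of(allp)
    return _finish(SearchResult(best, "sample", allp.shape[0]), cloud)


@dataclass
class GridCube:
    """One octree node: an axis-aligned cube with its bound bookkeeping."""

    center: np.ndarray
    half_width: float
    depth: int
    active_bisectors: np.ndarray  # indices into the cloud's BisectorSet
    bound: float = 0.0
    score: float = 1.0


def _corners(center: np.ndarray, hw: float) -> np.ndarray:
    d = center.size
    signs = np.array(list(itertools.product((-1.0, 1.0), repeat=d)))
    return center[None, :] + hw * signs


def _active_subset(bis: BisectorSet, active: np.ndarray,
                   corners: np.ndarray) -> np.ndarray:
    """Bisectors from `active` whose plane meets the cube with given corners
    (exact sign test at the corners)."""
    if active.size == 0:
        return active
    vals = corners @ bis.normals[active].T + bis.offsets[active]
    pos = (vals > 0).any(axis=0)
    neg = (vals < 0).any(axis=0)
    zero = (vals == 0).any(axis=0)
    return active[(pos & neg) | zero]


def cube_lower_bound(b_n: np.ndarray, k: int, N: int, B: int,
                     T: np.ndarray) -> float:
    """Sound lower bound on the score of any pivot inside a cube.

    Given the cube-center ranking's prefix one-counts ``b_n`` and the number
    ``k`` of active bisectors not satisfied at the center, the best any pivot
    in the cube could do is promote up to ``k`` additional '1's immediately
    after each prefix (without exceeding B).  The bound is the minimum tail
    over all such optimistically extended prefixes, including the empty one.
    """
    if B in (0, N):
        return 1.0
    n = np.arange(0, N + 1)
    b = np.concatenate([[0], b_n])
    j = np.minimum(k, B - b)
    return float(T[n + j, b + j].min())


def smhg_grid(cloud: LabeledCloud,
              budget: int = 100_000,
              slack: float = 0.10,
              max_depth: int = 24,
              prune: bool = True) -> SearchResult:
    """Octree branch-and-bound search for the minimising pivot.

    The root cube is the data bounding box expanded by ``slack`` x diagonal
    per side (pivots outside the convex hull are admissible).  Cubes are
    processed best-first by their lower bound; a cube whose bound exceeds the
    best score seen so far is pruned, and a cube intersected by no bisector
    has constant ranking and is a leaf.  Deterministic given its arguments.
    """
    if cloud.N < 2:
        raise ValueError("need at least two points")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    ctx = ScoreContext(cloud)
    lo, hi = cloud.bounding_box()
    diag = float(np.linalg.norm(hi - lo))
    center0 = 0.5 * (lo + hi)
    hw0 = 0.5 * float(np.max(hi - lo)) + slack * max(diag, 1.0e-9)
    if ctx._degenerate:
        best = ctx.score_one(center0)
        return _finish(SearchResult(best, "grid", 1), cloud)
    bis = build_bisectors(cloud)
    T = ctx.T

    state = {"best": None, "opt": np.inf, "evals": 0, "trace": []}

    def evaluate(center: np.ndarray, hw: float, depth: int,
                 parent_active: np.ndarray) -> Optional[GridCube]:
        corners = _corners(center, hw)
        active = _active_subset(bis, parent_active, corners)
        dist = np.linalg.norm(cloud.coords - center, axis=1)
        order = np.argsort(dist, kind="stable")
        b_n = np.cumsum(cloud.labels[order])
        tails = T[np.arange(1, cloud.N + 1), b_n]
        i = int(np.argmin(tails))
        score = float(tails[i])
        state["evals"] += 1
        radius = float(dist[order[i]])
        better = score < state["opt"] or (
            score == state["opt"] and state["best"] is not None
            and radius < state["best"].radius)
        if better:
            # ties on the score resolve to the tightest ball
            state["opt"] = score
            state["best"] = PivotScore(center,
                                       MHGResult(score, i + 1, int(b_n[i])),
                                       radius)
            if not state["trace"] or score < state["trace"][-1][1]:
                state["trace"].append((state["evals"], score))
        if active.size:
            vals = bis.values_at(center[None, :])[0, active]
            k = int((vals <= 0).sum())
        else:
            k = 0
        bound = cube_lower_bound(b_n, k, cloud.N, cloud.B, T)
        return GridCube(center, hw, depth, active, bound=bound, score=score)

    root = evaluate(center0, hw0, 0, np.arange(len(bis)))
    heap: list = []
    counter = itertools.count()
    heapq.heappush(heap, (root.bound, root.depth, next(counter), root))
    offsets = np.array(list(itertools.product((-0.5, 0.5), repeat=cloud.d)))
    while heap and state["evals"] < budget:
        _, _, _, cube = heapq.heappop(heap)
        if prune and cube.bound > state["opt"]:
            continue
        if cube.active_bisectors.size == 0 or cube.depth >= max_depth:
            continue  # ranking constant inside, or depth cap
        chw = 0.5 * cube.half_width
        for off in offsets:
            if state["evals"] >= budget:
                break
            child = evaluate(cube.center + off * cube.half_width, chw,
                             cube.depth + 1, cube.active_bisectors)
            if prune and child.bound > state["opt"]:
                continue
            heapq.heappush(heap, (child.bound, child.depth, next(counter), child))
    return _finish(SearchResult(state["best"], "grid", state["evals"],
                                state["trace"]), cloud)


def exhaustive_oracle(cloud: LabeledCloud,
                      eps: Optional[float] = None,
                      grid_points: int = 200,
                      slack: float = 0.10,
                      max_n: int = 16) -> SearchResult:
    """Brute-force ground truth for tiny instances (test oracle).

    Scores every tuple-derived pivot, every bead pivot, and a dense
    ``grid_points**d`` lattice over the slack-expanded bounding box; returns
    the global minimum over all pivots encountered.
    """
    if cloud.N > max_n:
        raise ResourceGuardError(f"exhaustive oracle limited to N <= {max_n}")
    if grid_points ** cloud.d > 4_000_000:
        raise ResourceGuardError("grid too dense; lower grid_points")
    ctx = ScoreContext(cloud)
    if ctx._degenerate or cloud.N < 2:
        best = ctx.score_one(cloud.coords[0])
        return _finish(SearchResult(best, "oracle", 1), cloud)
    pivots = [enumerate_sample_pivots(cloud, eps=eps), cloud.coords]
    lo, hi = cloud.bounding_box()
    diag = float(np.linalg.norm(hi - lo))
    lo = lo - slack * diag
    hi = hi + slack * diag
    axes = [np.linspace(lo[j], hi[j], grid_points) for j in range(cloud.d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pivots.append(np.stack([m.ravel() for m in mesh], axis=1))
    best: Optional[PivotScore] = None
    n_eval = 0
    for block in pivots:
        if block.size == 0:
            continue
        for start in range(0, block.shape[0], 50_000):
            chunk = block[start:start + 50_000]
            cand = ctx.best_of(chunk)
            n_eval += chunk.shape[0]
            if best is None or cand.result.score < best.result.score:
                best = cand
    return _finish(SearchResult(best, "oracle", n_eval), cloud)
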