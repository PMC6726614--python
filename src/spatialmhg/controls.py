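"""Statistical controls for spatial enrichment results.

Three safeguards accompany every spatial scan: the bead control (pivots
restricted to the embedded bins themselves, i.e. the earlier pivot-on-genome
approach), the 1D genomic-order control (ranking by sequence distance per
chromosome, catching enrichments explainable by linear genome order alone),
and a label-shuffle simulation yielding an empirical corrected p-value.
Benjamini-Hochberg q-values summarise families of results, and two
permutation tests assess set-level spatial proximity questions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .geometry import LabeledCloud, PivotScore
from .mhg import MHGResult, tail_table
from .search import ScoreContext, SearchResult, _finish, smhg_grid, smhg_sample

__all__ = [
    "ControlReport",
    "SimulationControl",
    "bead_control",
    "genomic_1d_control",
    "simulation_control",
    "fdr_qvalues",
    "assignment_permutation_test",
    "cross_set_proximity_test",
]


@dataclass
class SimulationControl:
    """Empirical shuffle p-value with its raw counts."""

    p_sim: float
    r: int           # shuffles with statistic <= observed
    n_shuffles: int
    observed: float  # the observed min-over-heuristics score

    def __str__(self) -> str:  # the field's reporting convention
        if self.r == 0:
            return f"P_sim < {1.0 / self.n_shuffles:g}"
        return f"P_sim = {self.p_sim:g}"


@dataclass
class ControlReport:
    bead: SearchResult
    one_d: list
    p_sim: Optional[SimulationControl] = None
    q_value: Optional[float] = None


def bead_control(cloud: LabeledCloud) -> SearchResult:
    """Minimum mHG over pivots restricted to the data points themselves.

    Each bead ranks itself first at distance zero (its own label counted).
    """
    ctx = ScoreContext(cloud)
    best = ctx.best_of(cloud.coords)
    return _finish(SearchResult(best, "bead", cloud.N), cloud)


def genomic_1d_control(cloud: LabeledCloud) -> list[SearchResult]:
    """Per-chromosome scan ranking bins by genomic (1D) distance.

    For every bead on a chromosome, same-chromosome bins are ranked by
    |bin_index difference| (ties: upstream bin first) and scored with the
    per-chromosome N and B.  Chromosomes with < 2 bins are skipped.
    Inter-chromosomal genomic distance is undefined, hence the restriction.
    """
    out: list[SearchResult] = []
    chroms = cloud.chrom.astype(str)
    for c in dict.fromkeys(chroms):  # preserve input order
        sel = np.flatnonzero(chroms == c)
        if sel.size < 2:
            continue
        labels = cloud.labels[sel]
        bi = cloud.bin_index[sel]
        Nc, Bc = sel.size, int(labels.sum())
        sub = LabeledCloud(cloud.coords[sel], labels,
                           cloud.chrom[sel], bi)
        if Bc in (0, Nc):
            ctx = ScoreContext(sub)
            best = ctx.score_one(sub.coords[0])
            res = _finish(SearchResult(best, "1d", Nc), sub)
            res.chrom = c
            out.append(res)
            continue
        T = tail_table(Nc, Bc)
        best: Optional[PivotScore] = None
        for j in range(Nc):
            dgen = np.abs(bi - bi[j])
            order = np.lexsort((bi, dgen))  # ties -> smaller bin_index first
            b_n = np.cumsum(labels[order])
            tails = T[np.arange(1, Nc + 1), b_n]
            i = int(np.argmin(tails))
            if best is None or tails[i] < best.result.score:
                radius = float(dgen[order[i]])
                best = PivotScore(sub.coords[j],
                                  MHGResult(float(tails[i]), i + 1, int(b_n[i])),
                                  radius)
        res = _finish(SearchResult(best, "1d", Nc), sub)
        res.chrom = c
        out.append(res)
    return out


def _search_statistic(cloud: LabeledCloud, grid_kwargs: dict,
                      sample_kwargs: dict, fast: bool) -> float:
    s = smhg_sample(cloud, **sample_kwargs).score
    if fast:
        return s
    g = smhg_grid(cloud, **grid_kwargs).score
    return min(s, g)


def simulation_control(cloud: LabeledCloud,
                       n_shuffles: int = 100,
                       seed: Optional[int] = None,
                       observed: Optional[float] = None,
                       grid_kwargs: Optional[dict] = None,
                       sample_kwargs: Optional[dict] = None,
                       fast: bool = False) -> SimulationControl:
    """Label-shuffle simulation: empirical survival function of the search.

    Each of ``n_shuffles`` uniform permutations of the label vector is
    searched with both heuristics; the statistic is min of the two scores.
    P_sim = (r + 1) / (n_shuffles + 1) where r counts shuffles at least as
    extreme as the observed statistic (never exactly zero); the raw counts
    are kept so "P_sim < 1/n" can be reported when r = 0.  ``fast`` restricts
    the shuffles to the sampling heuristic only (off by default).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    grid_kwargs = dict(grid_kwargs or {})
    sample_kwargs = dict(sample_kwargs or {})
    rng = np.random.default_rng(seed)
    if "max_pivots" in sample_kwargs and "seed" not in sample_kwargs:
        sample_kwargs["seed"] = int(rng.integers(2**31 - 1))
    if observed is None:
        observed = _search_statistic(cloud, grid_kwargs, sample_kwargs, fast)
    r = 0
    for _ in range(n_shuffles):
        shuffled = cloud.with_labels(rng.permutation(cloud.labels))
        stat = _search_statistic(shuffled, grid_kwargs, sample_kwargs, fast)
        if stat <= observed:
            r += 1
    return SimulationControl((r + 1) / (n_shuffles + 1), r, n_shuffles,
                             float(observed))


def fdr_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone, each >= its p)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pairwise_stat(coords: np.ndarray, statistic: str) -> float:
    from scipy.spatial.distance import pdist
    d = pdist(coords)
    return float(np.median(d) if statistic == "median" else np.mean(d))


def assignment_permutation_test(cloud: LabeledCloud,
                                positive_bins: Sequence[int],
                                candidate_bins: Sequence[int],
                                n_perm: int = 10_000,
                                statistic: str = "median",
                                seed: Optional[int] = None) -> float:
    """Are the positive bins mutually closer than random candidate subsets?

    Null: draw |positive| bins uniformly without replacement from the
    candidates and take the median (or mean) pairwise Euclidean distance.
    Returns the empirical CDF at the observed statistic with the
    (r + 1)/(n + 1) convention (small distances are extreme).
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    pos = np.asarray(sorted(positive_bins), dtype=int)
    cand = np.asarray(sorted(candidate_bins), dtype=int)
    if pos.size < 2:
        raise ValueError("need at least two positive bins")
    if not np.isin(pos, cand).all():
        raise ValueError("positive_bins must be a subset of candidate_bins")
    if cand.size < pos.size:
        raise ValueError("not enough candidate bins")
    obs = _pairwise_stat(cloud.coords[pos], statistic)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        # sorted draw keeps the statistic invariant to draw order (exact ties)
        draw = np.sort(rng.choice(cand, size=pos.size, replace=False))
        if _pairwise_stat(cloud.coords[draw], statistic) <= obs:
            r += 1
    return (r + 1) / (n_perm + 1)


def cross_set_proximity_test(cloud: LabeledCloud,
                             fixed_set: Sequence[int],
                             observed_set: Sequence[int],
                             n_perm: int = 10_000,
                             seed: Optional[int] = None) -> float:
    """Is a second bin set unusually close to a fixed one?

    Null: draw |observed_set| bins uniformly from all bins excluding the
    fixed set; statistic = mean over all cross-pair Euclidean distances
    between the two sets.  Returns the empirical CDF at the observed set's
    statistic ((r + 1)/(n + 1) convention).
    """
    fixed = np.asarray(sorted(fixed_set), dtype=int)
    obs_set = np.asarray(sorted(observed_set), dtype=int)
    if fixed.size == 0 or obs_set.size == 0:
        raise ValueError("both sets must be nonempty")
    pool = np.setdiff1d(np.arange(cloud.N), fixed)
    if pool.size < obs_set.size:
        raise ValueError("not enough bins outside the fixed set")
    fc = cloud.coords[fixed]

    def cross_mean(idx: np.ndarray) -> float:
        diffs = fc[:, None, :] - cloud.coords[idx][None, :, :]
        return float(np.linalg.norm(diffs, axis=2).mean())

    obs = cross_mean(obs_set)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        draw = np.sort(rng.choice(pool, size=obs_set.size, replace=False))
        if cross_mean(draw) <= obs:
            r += 1
    return (r + 1) / (n_perm + 1)
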