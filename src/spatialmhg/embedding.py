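"""Smoothed nonmetric MDS embedding of binned Hi-C contact maps.

Contact counts are converted to dissimilarities by a monotone-decreasing
transform, embedded in 3D by nonmetric multidimensional scaling (weighted
SMACOF with isotonic regression, so that unobserved zero-count pairs are
excluded from the stress rather than imputed), and then smoothed: embedded
distances between genomically consecutive bins (the discrete derivative along
each chromosome) are Z-scored, outlying jumps are flagged as discontinuities
and corrected by linear interpolation between valid genomic neighbours,
alternating with NMDS refinement until the configuration is smooth.

The resulting configuration is an abstract latent space that preserves the
ordinality of measured proximities; it is not a physical structure model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "ContactMap",
    "DissimilarityMatrix",
    "EmbeddingConfig",
    "Embedding3D",
    "counts_to_dissimilarity",
    "nmds_embed",
    "detect_discontinuities",
    "interpolate_outliers",
    "snmds",
    "procrustes_align",
]


@dataclass
class ContactMap:
    """Symmetric nonnegative binned contact counts with bin metadata."""

    counts: np.ndarray
    bins: pd.DataFrame  # columns chrom, start, end; ordered by (chrom, start)
    resolution: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape != (n, n):
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-8, atol=1e-8):
            raise ValueError("counts must be symmetric")
        if len(self.bins) != n:
            raise ValueError("bin table length must match matrix size")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarities with a mask for unobserved pairs."""

    values: np.ndarray
    observed: np.ndarray  # boolean; False = missing (excluded from the loss)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if np.any(self.values < 0) or np.any(np.diag(self.values) != 0):
            raise ValueError("dissimilarities must be nonnegative, zero diagonal")


@dataclass
class EmbeddingConfig:
    n_dims: int = 3
    nmds_max_iter: int = 300
    stress_tol: float = 1e-6
    smooth_z_threshold: float = 3.0
    smooth_max_iter: int = 10
    seed: int = 0


@dataclass
class Embedding3D:
    """One point per genomic bin in the embedding space (unitless)."""

    coords: np.ndarray
    chrom: np.ndarray
    bin_index: np.ndarray
    stress: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bin_index = np.asarray(self.bin_index, dtype=np.int64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]


def _bins_meta(bins: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    chrom = bins["chrom"].to_numpy(dtype=object)
    bin_index = np.zeros(len(bins), dtype=np.int64)
    for c in pd.unique(bins["chrom"]):
        sel = (bins["chrom"] == c).to_numpy()
        bin_index[sel] = np.arange(int(sel.sum()))
    return chrom, bin_index


def counts_to_dissimilarity(cmap: ContactMap, transform: str = "inverse",
                            alpha: float = 1.0) -> DissimilarityMatrix:
    """Monotone-decreasing map of contact counts to dissimilarities.

    'inverse': d = (1 + c)^-1 rescaled to [0, 1]; 'power': (1 + c)^-alpha;
    'rank': reversed count ranks.  Zero-count pairs are marked unobserved
    (sparse Hi-C zeros are missing data, not maximal distance).
    """
    c = cmap.counts
    n = cmap.n_bins
    off = ~np.eye(n, dtype=bool)
    if not np.any(c[off] > 0):
        raise ValueError("contact map has no nonzero off-diagonal counts")
    observed = (c > 0) & off
    if transform == "inverse":
        d = 1.0 / (1.0 + c)
    elif transform == "power":
        d = (1.0 + c) ** (-alpha)
    elif transform == "rank":
        iu = np.triu_indices(n, 1)
        r = rankdata(-c[iu], method="average")
        d = np.zeros_like(c)
        d[iu] = r
        d = d + d.T
    else:
        raise ValueError(f"unknown transform {transform!r}")
    vals = d[observed]
    lo, hi = vals.min(), vals.max()
    scale = hi - lo if hi > lo else 1.0
    d = (d - lo) / scale
    d[~observed] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    return DissimilarityMatrix(d, observed)


def _classical_mds_init(D: DissimilarityMatrix, n_dims: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Deterministic initial configuration: classical scaling on the
    dissimilarities with missing entries imputed at the observed maximum."""
    vals = D.values.copy()
    if D.observed.any():
        vals[~D.observed] = D.values[D.observed].max()
    np.fill_diagonal(vals, 0.0)
    n = vals.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (vals ** 2) @ J
    w, V = np.linalg.eigh(Bmat)
    idx = np.argsort(w)[::-1][:n_dims]
    X = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    if X.shape[1] < n_dims:
        X = np.pad(X, ((0, 0), (0, n_dims - X.shape[1])))
    # tiny seeded jitter breaks exact degeneracies deterministically
    X = X + 1e-9 * rng.standard_normal(X.shape)
    return X


def nmds_embed(D: DissimilarityMatrix, config: Optional[EmbeddingConfig] = None,
               chrom: Optional[np.ndarray] = None,
               bin_index: Optional[np.ndarray] = None,
               init: Optional[np.ndarray] = None) -> Embedding3D:
    """Nonmetric MDS by weighted SMACOF with isotonic disparities.

    Minimises normalised stress between embedded distances and a monotone
    (isotonic) transform of the input dissimilarities, restricted to observed
    pairs.  Deterministic given the config seed; a non-convergence after
    ``nmds_max_iter`` returns the configuration with a warning flag.
    """
    config = config or EmbeddingConfig()
    n = D.values.shape[0]
    if n < 4:
        raise ValueError("need at least 4 bins to embed")
    W = D.observed.astype(float)
    W[np.diag_indices(n)] = 0.0
    rng = np.random.default_rng(config.seed)
    X = init.copy() if init is not None else _classical_mds_init(D, config.n_dims, rng)
    iu = np.triu_indices(n, 1)
    wvec = W[iu]
    obs = wvec > 0
    dvals = D.values[iu][obs]
    order = np.argsort(dvals, kind="stable")
    iso = IsotonicRegression(increasing=True)
    V = np.diag(W.sum(axis=1)) - W
    Vp = np.linalg.pinv(V)
    last_stress = np.inf
    stress = np.inf
    converged = False
    for _ in range(config.nmds_max_iter):
        diff = X[:, None, :] - X[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        dobs = dist[iu][obs]
        dhat = iso.fit_transform(dvals[order], dobs[order])
        inv = np.empty_like(dhat)
        inv[order] = dhat
        # scale disparities to the distances (stress-1 normalisation)
        denom = float(np.sum(inv ** 2))
        if denom > 0:
            inv = inv * np.sqrt(np.sum(dobs ** 2) / denom)
        num = float(np.sum((dobs - inv) ** 2))
        den = float(np.sum(dobs ** 2))
        stress = np.sqrt(num / den) if den > 0 else 0.0
        if abs(last_stress - stress) < config.stress_tol:
            converged = True
            break
        last_stress = stress
        # Guttman transform with weights
        dh = np.zeros((n, n))
        dh[iu[0][obs], iu[1][obs]] = inv
        dh = dh + dh.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dh / np.where(dist > 0, dist, 1.0), 0.0)
        Bm = -W * ratio
        Bm[np.diag_indices(n)] = -Bm.sum(axis=1)
        X = Vp @ (Bm @ X)
    if not converged:
        warnings.warn("NMDS did not converge within nmds_max_iter")
    if chrom is None:
        chrom = np.array(["chr1"] * n, dtype=object)
    if bin_index is None:
        bin_index = np.arange(n, dtype=np.int64)
    return Embedding3D(X, chrom, bin_index, stress=float(stress),
                       converged=converged)


def _consecutive_derivatives(emb: Embedding3D):
    """Per-chromosome consecutive-bin embedded distances.

    Yields (chrom, positions i of the left bin, distances); chromosomes with
    fewer than 3 bins are skipped.
    """
    chroms = emb.chrom.astype(str)
    for c in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == c)
        if sel.size < 3:
            continue
        sel = sel[np.argsort(emb.bin_index[sel], kind="stable")]
        d = np.linalg.norm(np.diff(emb.coords[sel], axis=0), axis=1)
        yield c, sel, d


def detect_discontinuities(emb: Embedding3D, z_threshold: float = 3.0) -> list[int]:
    """Bins flanked by an outlying genomic-neighbour jump.

    Derivatives are computed within chromosomes and Z-scored against the
    pooled distribution of all consecutive distances; a bin is flagged when
    any adjacent derivative has Z > z_threshold.  Zero pooled variance means
    no outliers.
    """
    per_chrom = list(_consecutive_derivatives(emb))
    if not per_chrom:
        return []
    pooled = np.concatenate([d for _, _, d in per_chrom])
    mu, sd = float(pooled.mean()), float(pooled.std())
    if sd == 0:
        return []
    flagged: set[int] = set()
    for _, sel, d in per_chrom:
        z = (d - mu) / sd
        for j in np.flatnonzero(z > z_threshold):
            flagged.add(int(sel[j]))
            flagged.add(int(sel[j + 1]))
    return sorted(flagged)


def interpolate_outliers(emb: Embedding3D, outliers: Sequence[int]) -> Embedding3D:
    """Replace flagged bins by linear interpolation along the chromosome.

    Runs of consecutive outliers are spaced evenly on the segment between the
    nearest valid genomic neighbours; chromosome-terminal runs are linearly
    extrapolated from the two nearest valid bins.  A chromosome whose bins
    are all flagged is left unchanged with a warning.
    """
    out = set(int(i) for i in outliers)
    if any(i < 0 or i >= emb.n_bins for i in out):
        raise IndexError("outlier index out of bounds")
    coords = emb.coords.copy()
    chroms = emb.chrom.astype(str)
    for c in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == c)
        sel = sel[np.argsort(emb.bin_index[sel], kind="stable")]
        flags = np.array([int(i) in out for i in sel])
        if not flags.any():
            continue
        if flags.all():
            warnings.warn(f"all bins flagged on {c}; left unchanged")
            continue
        valid = np.flatnonzero(~flags)
        pos = np.arange(sel.size, dtype=float)
        for k in range(coords.shape[1]):
            interp = np.interp(pos, pos[valid], coords[sel[valid], k])
            coords[sel[flags], k] = interp[flags]
        # linear extrapolation for terminal runs (np.interp clamps)
        if valid.size >= 2:
            first, second = valid[0], valid[1]
            slope0 = (coords[sel[second]] - coords[sel[first]]) / (second - first)
            for j in range(first):
                if flags[j]:
                    coords[sel[j]] = coords[sel[first]] + (j - first) * slope0
            last, prev = valid[-1], valid[-2]
            slope1 = (coords[sel[last]] - coords[sel[prev]]) / (last - prev)
            for j in range(last + 1, sel.size):
                if flags[j]:
                    coords[sel[j]] = coords[sel[last]] + (j - last) * slope1
    return replace(emb, coords=coords)


def snmds(cmap: ContactMap, config: Optional[EmbeddingConfig] = None,
          transform: str = "inverse", alpha: float = 1.0) -> Embedding3D:
    """Smoothed NMDS: embed, then iteratively correct genomic discontinuities.

    Pipeline: counts -> dissimilarities -> NMDS, then rounds of
    {detect discontinuities, interpolate, NMDS refinement initialised at the
    corrected configuration} up to ``smooth_max_iter``.  The returned
    configuration always ends with correction passes, so it carries no
    derivative above the Z threshold (the refinement may otherwise restore a
    jump that the contact map itself encodes); hitting the round cap is
    reported via a warning.
    """
    config = config or EmbeddingConfig()
    D = counts_to_dissimilarity(cmap, transform=transform, alpha=alpha)
    chrom, bin_index = _bins_meta(cmap.bins)
    emb = nmds_embed(D, config, chrom=chrom, bin_index=bin_index)
    converged = False
    for _ in range(config.smooth_max_iter):
        outliers = detect_discontinuities(emb, config.smooth_z_threshold)
        if not outliers:
            converged = True
            break
        emb = interpolate_outliers(emb, outliers)
        if not detect_discontinuities(emb, config.smooth_z_threshold):
            converged = True
            break
        emb = nmds_embed(D, config, chrom=chrom, bin_index=bin_index,
                         init=emb.coords)
    if not converged:
        warnings.warn("smoothing round cap reached; applying final correction passes")
    # final correction-only passes guarantee a smooth returned configuration
    for _ in range(emb.n_bins):
        outliers = detect_discontinuities(emb, config.smooth_z_threshold)
        if not outliers:
            break
        emb = interpolate_outliers(emb, outliers)
    return emb


def procrustes_align(ref: Embedding3D, mov: Embedding3D,
                     allow_reflection: bool = True) -> tuple[Embedding3D, float]:
    """Similarity-transform alignment of one embedding onto another.

    Finds translation, rotation (optionally excluding reflections) and scale
    of ``mov`` minimising the sum of squared distances to ``ref``; returns
    the transformed embedding and the disparity (residual sum of squares
    normalised by the reference's centred sum of squares).
    """
    if ref.n_bins != mov.n_bins or ref.coords.shape != mov.coords.shape:
        raise ValueError("embeddings must have matching bins")
    A = ref.coords - ref.coords.mean(axis=0)
    Bc = mov.coords - mov.coords.mean(axis=0)
    M = A.T @ Bc
    U, S, Vt = np.linalg.svd(M)
    d = np.ones(M.shape[0])
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    denom = float(np.sum(Bc ** 2))
    scale = float(np.sum(S * d)) / denom if denom > 0 else 1.0
    aligned = scale * Bc @ R.T + ref.coords.mean(axis=0)
    ref_ss = float(np.sum(A ** 2))
    disparity = float(np.sum((aligned - ref.coords) ** 2)) / ref_ss if ref_ss else 0.0
    return replace(mov, coords=aligned), disparity
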