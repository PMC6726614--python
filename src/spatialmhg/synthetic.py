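"""Synthetic data emulating the statistical structure the method assumes.

A multi-chromosome polymer is drawn as a smoothed confined random walk; a
contact map follows distance-decay Poisson counts (expected count
proportional to d^-alpha); label hotspots plant a co-localization event to
recover; and injected discontinuities emulate the embedding artifacts the
smoothing stage corrects.  All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .embedding import ContactMap, Embedding3D
from .geometry import LabeledCloud

__all__ = [
    "SyntheticSpec",
    "generate_polymer",
    "generate_contact_map",
    "plant_hotspot",
    "inject_discontinuities",
    "make_cloud",
]


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic genome.

    step is the random-walk step in embedding units; alpha the contact decay
    exponent; depth the expected total read count of the map.
    """

    n_chrom: int = 2
    bins_per_chrom: int = 100
    step: float = 1.0
    alpha: float = 1.0
    depth: float = 1e6
    hotspot_radius: float = 3.0
    n_positive_inside: int = 8
    n_positive_outside: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.bins_per_chrom < 2:
            raise ValueError("need >= 1 chromosome with >= 2 bins")
        if self.step <= 0 or self.depth <= 0 or self.hotspot_radius <= 0:
            raise ValueError("step, depth and hotspot radius must be positive")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    out = np.empty_like(x)
    for k in range(x.shape[1]):
        out[:, k] = np.convolve(np.pad(x[:, k], (window // 2, window - 1 - window // 2),
                                       mode="edge"), kernel, mode="valid")
    return out


def generate_polymer(spec: SyntheticSpec, smooth_window: int = 5) -> Embedding3D:
    """Smoothed 3D random-walk chromosomes confined to a common ball."""
    rng = np.random.default_rng(spec.seed)
    n = spec.bins_per_chrom
    radius = spec.step * np.sqrt(n) * 1.5  # confinement ball
    coords, chrom, bin_index = [], [], []
    for c in range(spec.n_chrom):
        steps = rng.standard_normal((n, 3)) * spec.step
        walk = np.cumsum(steps, axis=0)
        walk = _smooth(walk, smooth_window) if n > 2 else walk
        walk -= walk.mean(axis=0)
        # territory offset inside the ball, then rescale to stay confined
        offset = rng.standard_normal(3)
        offset *= 0.4 * radius / max(np.linalg.norm(offset), 1e-12)
        walk = walk + offset
        r = np.linalg.norm(walk, axis=1).max()
        if r > radius:
            walk *= radius / r
        coords.append(walk)
        chrom.extend([f"chr{c + 1}"] * n)
        bin_index.extend(range(n))
    return Embedding3D(np.vstack(coords), np.array(chrom, dtype=object),
                       np.array(bin_index, dtype=np.int64))


def _bins_table(emb: Embedding3D, resolution: int = 10_000) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": emb.chrom.astype(str),
        "start": emb.bin_index * resolution,
        "end": (emb.bin_index + 1) * resolution,
    })


def generate_contact_map(truth: Embedding3D, alpha: float = 1.0,
                         depth: float = 1e6,
                         seed: Optional[int] = 0,
                         resolution: int = 10_000) -> ContactMap:
    """Poisson contact counts with power-law distance decay.

    counts_ij ~ Poisson(k d_ij^-alpha), k set so the expected total
    off-diagonal count equals ``depth``; symmetric with zero diagonal.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = truth.coords
    n = X.shape[0]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        decay = np.where(d[iu] > 0, d[iu] ** (-alpha), 0.0)
    k = depth / (2.0 * decay.sum())
    rng = np.random.default_rng(seed)
    upper = rng.poisson(k * decay).astype(float)
    counts = np.zeros((n, n))
    counts[iu] = upper
    counts = counts + counts.T
    return ContactMap(counts, _bins_table(truth, resolution), resolution)


def plant_hotspot(truth: Embedding3D,
                  center: np.ndarray,
                  radius: float,
                  n_positive_inside: int,
                  n_positive_outside: int = 0,
                  seed: Optional[int] = 0) -> np.ndarray:
    """Binary labels with positives concentrated in a spatial ball.

    ``n_positive_inside`` bins are drawn uniformly from bins within
    ``radius`` of ``center`` and ``n_positive_outside`` uniformly from the
    rest; raises if either pool is too small.
    """
    center = np.asarray(center, dtype=float)
    dist = np.linalg.norm(truth.coords - center, axis=1)
    inside = np.flatnonzero(dist <= radius)
    outside = np.flatnonzero(dist > radius)
    if n_positive_inside > inside.size:
        raise ValueError(f"only {inside.size} bins inside the ball")
    if n_positive_outside > outside.size:
        raise ValueError(f"only {outside.size} bins outside the ball")
    rng = np.random.default_rng(seed)
    labels = np.zeros(truth.n_bins, dtype=np.int64)
    labels[rng.choice(inside, size=n_positive_inside, replace=False)] = 1
    if n_positive_outside:
        labels[rng.choice(outside, size=n_positive_outside, replace=False)] = 1
    return labels


def inject_discontinuities(emb: Embedding3D, k: int, magnitude: float,
                           seed: Optional[int] = 0) -> tuple[Embedding3D, np.ndarray]:
    """Teleport k non-adjacent interior bins by a random direction x magnitude.

    Returns the corrupted embedding and the displaced bin indices.  Interior
    (non-terminal) bins only, pairwise non-adjacent, so interpolation stays
    well posed.
    """
    if k >= emb.n_bins:
        raise ValueError("k must be smaller than the bin count")
    chroms = emb.chrom.astype(str)
    interior = []
    for c in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == c)
        sel = sel[np.argsort(emb.bin_index[sel], kind="stable")]
        interior.extend(sel[1:-1])
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for i in rng.permutation(np.asarray(interior, dtype=int)):
        if all(abs(int(i) - j) > 1 for j in chosen):
            chosen.append(int(i))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError("not enough non-adjacent interior bins")
    coords = emb.coords.copy()
    if magnitude != 0:
        for i in chosen:
            direction = rng.standard_normal(coords.shape[1])
            direction /= max(np.linalg.norm(direction), 1e-12)
            coords[i] += magnitude * direction
    return replace(emb, coords=coords), np.array(sorted(chosen), dtype=int)


def make_cloud(emb: Embedding3D, labels: np.ndarray) -> LabeledCloud:
    """Bundle an embedding and a label vector into a scan-ready cloud."""
    return LabeledCloud(emb.coords, labels, emb.chrom, emb.bin_index)
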