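"""Mapping annotations, CGH profiles and differential Hi-C onto bin labels.

Every spatial scan consumes a binary label per genomic bin.  Interval or
gene-set annotations label a bin when any member overlaps it; sets reaching
fewer than four labelled bins are rejected (too few positives for a
meaningful hypergeometric prefix minimum).  Array-CGH log-ratios and
reference/variant Hi-C pairs are turned into labels by Z-score binarisation.
Coordinates are 0-based half-open throughout (BED native).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embedding import ContactMap

__all__ = [
    "GenomeBinning",
    "AnnotationSet",
    "MappedAnnotation",
    "CGHProfile",
    "MIN_POSITIVE_BINS",
    "map_annotation_to_bins",
    "binarize_cgh",
    "differential_hic_labels",
]

#: annotation sets mapping to fewer positive bins than this are rejected
MIN_POSITIVE_BINS = 4


@dataclass
class GenomeBinning:
    """Fixed-size tiling of chromosomes into half-open bins."""

    chrom_sizes: dict
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        self._offsets = {}
        total = 0
        for c, size in self.chrom_sizes.items():
            self._offsets[c] = total
            total += self.n_bins_chrom(c)
        self._total = total

    def n_bins_chrom(self, chrom: str) -> int:
        return -(-int(self.chrom_sizes[chrom]) // self.bin_size)

    @property
    def n_bins(self) -> int:
        return self._total

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for c, size in self.chrom_sizes.items():
            for b in range(self.n_bins_chrom(c)):
                rows.append((c, b * self.bin_size,
                             min((b + 1) * self.bin_size, int(size))))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global bin indices overlapping [start, end) by >= 1 bp."""
        if chrom not in self.chrom_sizes:
            raise KeyError(chrom)
        if end <= start:
            return np.empty(0, dtype=int)
        first = max(0, start // self.bin_size)
        last = min(self.n_bins_chrom(chrom) - 1, (end - 1) // self.bin_size)
        if last < first:
            return np.empty(0, dtype=int)
        return self._offsets[chrom] + np.arange(first, last + 1)

    def bin_of(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(chrom)
        return self._offsets[chrom] + pos // self.bin_size


@dataclass
class AnnotationSet:
    """A named set of genomic intervals inducing a binary bin labelling."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end


@dataclass
class MappedAnnotation:
    """Typed result of mapping an annotation set onto bins."""

    name: str
    labels: np.ndarray
    B: int
    accepted: bool
    reason: Optional[str] = None


def map_annotation_to_bins(ann: AnnotationSet,
                           binning: GenomeBinning,
                           rule: str = "overlap") -> MappedAnnotation:
    """Label a bin 1 iff it overlaps at least one annotation interval.

    'overlap' labels every bin touched by >= 1 bp; 'midpoint' assigns each
    interval to the single bin holding its midpoint.  Intervals on unknown
    chromosomes are skipped with a warning.  Sets with B < 4 are returned
    rejected rather than raising.  Idempotent and order-independent.
    """
    labels = np.zeros(binning.n_bins, dtype=np.int64)
    unknown = 0
    for row in ann.intervals.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        if chrom not in binning.chrom_sizes:
            unknown += 1
            continue
        if rule == "overlap":
            labels[binning.bins_overlapping(chrom, start, end)] = 1
        elif rule == "midpoint":
            labels[binning.bin_of(chrom, (start + end) // 2)] = 1
        else:
            raise ValueError(f"unknown rule {rule!r}")
    if unknown:
        warnings.warn(f"{unknown} interval(s) on unknown chromosomes skipped")
    B = int(labels.sum())
    if B < MIN_POSITIVE_BINS:
        return MappedAnnotation(ann.name, labels, B, False,
                                f"B={B} < {MIN_POSITIVE_BINS}")
    return MappedAnnotation(ann.name, labels, B, True)


@dataclass
class CGHProfile:
    """Array-CGH probes: (chrom, position, log-ratio value) records."""

    probes: pd.DataFrame  # columns chrom, position, value


def binarize_cgh(profile: CGHProfile, binning: GenomeBinning,
                 min_probes: int = 20,
                 aggregation: str = "stouffer") -> tuple[np.ndarray, np.ndarray]:
    """Binarise binned CGH log-ratios at mean + 2 sd.

    Per bin, the statistic is sum(values)/sqrt(n_probes) (Stouffer-style;
    aggregation='mean' uses the plain mean instead).  Bins with fewer than
    ``min_probes`` probes are masked out; labels are 1 where the statistic
    exceeds mu + 2 sigma over the kept bins.  Returns (labels, kept mask).
    """
    if aggregation not in ("stouffer", "mean"):
        raise ValueError("aggregation must be 'stouffer' or 'mean'")
    sums = np.zeros(binning.n_bins)
    counts = np.zeros(binning.n_bins, dtype=np.int64)
    for row in profile.probes.itertuples(index=False):
        chrom, pos, val = str(row.chrom), int(row.position), float(row.value)
        if chrom not in binning.chrom_sizes:
            continue
        i = binning.bin_of(chrom, pos)
        sums[i] += val
        counts[i] += 1
    kept = counts >= min_probes
    if not kept.any():
        raise ValueError(f"no bin has >= {min_probes} probes")
    with np.errstate(divide="ignore", invalid="ignore"):
        if aggregation == "stouffer":
            v = sums / np.sqrt(np.maximum(counts, 1))
        else:
            v = sums / np.maximum(counts, 1)
    vk = v[kept]
    mu, sd = float(vk.mean()), float(vk.std())
    labels = np.zeros(binning.n_bins, dtype=np.int64)
    if sd > 0:
        labels[kept] = (vk > mu + 2 * sd).astype(np.int64)
    return labels, kept


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def differential_hic_labels(ref: ContactMap, var: ContactMap,
                            band: int = 5, z_cut: float = 1.96,
                            pooled: bool = False) -> np.ndarray:
    """Loci whose local contact structure differs between two maps.

    Per chromosome: each intra-chromosomal sub-matrix is Z-scored over its
    own entries; entries with |i - j| > ``band`` are masked to zero; the
    per-locus statistic is the Euclidean distance between the masked
    reference and variant rows; those distances are Z-scored (per chromosome
    unless ``pooled``) and a locus is labelled 1 where |Z| > ``z_cut``.
    Zero-variance Z steps yield all-zero scores.
    """
    if len(ref.bins) != len(var.bins) or not (
            ref.bins[["chrom", "start", "end"]].reset_index(drop=True)
            .equals(var.bins[["chrom", "start", "end"]].reset_index(drop=True))):
        raise ValueError("reference and variant maps must share the binning")
    labels = np.zeros(ref.n_bins, dtype=np.int64)
    chroms = ref.bins["chrom"].to_numpy()
    dist_all, sel_all = [], []
    for c in pd.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        Mr = _zscore(ref.counts[np.ix_(sel, sel)])
        Mv = _zscore(var.counts[np.ix_(sel, sel)])
        i = np.arange(sel.size)
        mask = np.abs(i[:, None] - i[None, :]) <= band
        Mr, Mv = Mr * mask, Mv * mask
        d = np.linalg.norm(Mr - Mv, axis=1)
        if pooled:
            dist_all.append(d)
            sel_all.append(sel)
        else:
            labels[sel] = (np.abs(_zscore(d)) > z_cut).astype(np.int64)
    if pooled and dist_all:
        z = _zscore(np.concatenate(dist_all))
        labels[np.concatenate(sel_all)] = (np.abs(z) > z_cut).astype(np.int64)
    return labels
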