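"""Plain-text input/output: TSV, BED and YAML config handling.

All tabular formats are headered TSV except BED (headerless, 0-based
half-open).  Contact maps load from a dense bins-x-bins TSV or a COO triple
TSV (bin_i, bin_j, count; upper-triangle or full, symmetrised on load with a
consistency check) plus a bin table TSV (chrom, start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .embedding import ContactMap, Embedding3D
from .geometry import LabeledCloud

__all__ = [
    "DataFormatError",
    "RunConfig",
    "read_bin_table",
    "read_contact_map",
    "write_contact_map",
    "read_embedding",
    "write_embedding",
    "read_labels",
    "write_labels",
    "read_bed",
    "read_gene_term_table",
    "read_cgh",
    "write_results",
    "load_config",
    "cloud_from_files",
]

RESULT_COLUMNS = ["dataset", "annotation", "method", "chrom", "pivot_x",
                  "pivot_y", "pivot_z", "threshold_n", "b_at_threshold",
                  "score", "pvalue", "qvalue", "p_sim", "radius",
                  "pivots_evaluated", "seed"]


class DataFormatError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected on load."""

    contact_map: Optional[str] = None
    bin_table: Optional[str] = None
    embedding: Optional[str] = None
    annotations: Optional[str] = None
    output_dir: str = "."
    method: str = "grid"
    epsilon: Optional[float] = None
    budget: int = 100_000
    slack: float = 0.10
    max_depth: int = 24
    sample_max_pivots: Optional[int] = None
    smooth_z_threshold: float = 3.0
    smooth_max_iter: int = 10
    nmds_max_iter: int = 300
    n_shuffles: int = 100
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DataFormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def read_bin_table(path: str | Path) -> pd.DataFrame:
    bins = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "end"} - set(bins.columns)
    if missing:
        raise DataFormatError(f"{path}: bin table missing columns {sorted(missing)}")
    return bins


def read_contact_map(path: str | Path, bin_table: str | Path,
                     resolution: Optional[int] = None) -> ContactMap:
    """Dense (bins x bins, no header) or COO (bin_i, bin_j, count) TSV."""
    bins = read_bin_table(bin_table)
    n = len(bins)
    with open(path) as fh:
        first = fh.readline()
    ncol = len(first.rstrip("\n").split("\t"))
    if ncol == 3 and n != 3:
        counts = np.zeros((n, n))
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise DataFormatError(f"{path}:{lineno}: expected 3 columns")
                try:
                    i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as e:
                    raise DataFormatError(f"{path}:{lineno}: {e}") from None
                if not (0 <= i < n and 0 <= j < n):
                    raise DataFormatError(f"{path}:{lineno}: bin index out of range")
                if counts[i, j] and counts[i, j] != c:
                    raise DataFormatError(
                        f"{path}:{lineno}: conflicting duplicate entry ({i},{j})")
                counts[i, j] = c
                if counts[j, i] and counts[j, i] != c:
                    raise DataFormatError(
                        f"{path}:{lineno}: asymmetric duplicate entry ({i},{j})")
                counts[j, i] = c
    else:
        counts = np.loadtxt(path, delimiter="\t", ndmin=2)
        if counts.shape != (n, n):
            raise DataFormatError(
                f"{path}: dense matrix is {counts.shape}, bin table has {n} bins")
    if resolution is None and len(bins):
        resolution = int(bins.iloc[0]["end"] - bins.iloc[0]["start"])
    return ContactMap(counts, bins, resolution)


def write_contact_map(cmap: ContactMap, path: str | Path,
                      bin_table: str | Path) -> None:
    np.savetxt(path, cmap.counts, delimiter="\t", fmt="%.10g")
    cmap.bins.to_csv(bin_table, sep="\t", index=False)


def write_embedding(emb: Embedding3D, path: str | Path) -> None:
    cols = {"chrom": emb.chrom.astype(str), "bin_index": emb.bin_index}
    for k, ax in enumerate("xyz"[: emb.coords.shape[1]]):
        cols[ax] = emb.coords[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_embedding(path: str | Path) -> Embedding3D:
    df = pd.read_csv(path, sep="\t")
    axes = [a for a in ("x", "y", "z") if a in df.columns]
    need = {"chrom", "bin_index"} | set(axes[:2])
    if not {"chrom", "bin_index", "x", "y"} <= set(df.columns):
        raise DataFormatError(f"{path}: embedding needs chrom, bin_index, x, y[, z]")
    coords = df[axes].to_numpy(dtype=float)
    return Embedding3D(coords, df["chrom"].to_numpy(dtype=object),
                       df["bin_index"].to_numpy(dtype=np.int64))


def write_labels(cloud_or_df, path: str | Path) -> None:
    if isinstance(cloud_or_df, LabeledCloud):
        df = pd.DataFrame({"chrom": cloud_or_df.chrom.astype(str),
                           "bin_index": cloud_or_df.bin_index,
                           "label": cloud_or_df.labels})
    else:
        df = cloud_or_df
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "bin_index", "label"} <= set(df.columns):
        raise DataFormatError(f"{path}: labels need chrom, bin_index, label")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ (headerless, 0-based half-open); extra columns kept as name etc."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             parts[3] if len(parts) > 3 else ""))
            except ValueError as e:
                raise DataFormatError(f"{path}:{lineno}: {e}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_gene_term_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     dtype=str)
    if df.isna().any().any():
        raise DataFormatError(f"{path}: gene-term table must have 2 columns")
    return df


def read_cgh(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "position", "value"} <= set(df.columns):
        raise DataFormatError(f"{path}: CGH needs chrom, position, value")
    return df


def cloud_from_files(embedding_path: str | Path,
                     labels_path: str | Path) -> LabeledCloud:
    emb = read_embedding(embedding_path)
    lab = read_labels(labels_path)
    key = pd.DataFrame({"chrom": emb.chrom.astype(str), "bin_index": emb.bin_index})
    merged = key.merge(lab.assign(chrom=lab["chrom"].astype(str)),
                       on=["chrom", "bin_index"], how="left")
    if merged["label"].isna().any():
        raise DataFormatError("labels missing for some embedded bins")
    return LabeledCloud(emb.coords, merged["label"].to_numpy(dtype=np.int64),
                        emb.chrom, emb.bin_index)


def write_results(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)
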