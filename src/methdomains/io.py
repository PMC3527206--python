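"""Readers and writers for the plain-text genomic formats used throughout.

Coordinate conventions: all in-memory coordinates are 0-based half-open.
BED and bedGraph files are written 0-based half-open; SAM is written 1-based
by the read simulator.  Sequences are held as ``numpy.uint8`` arrays of
ASCII codes (uppercase), which makes pileup masks and FASTA round-trips
cheap.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd
import pyfaidx

A, C, G, T = (np.uint8(ord(b)) for b in "ACGT")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]
CALLS_COLUMNS = ["chrom", "pos0", "strand", "context", "n_meth", "n_total", "ratio"]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def read_fasta(path: str | Path) -> Dict[str, np.ndarray]:
    """Load a FASTA file into a dict of chromosome -> uint8 code array."""
    fa = pyfaidx.Fasta(str(path))
    return {name: seq_to_array(str(fa[name][:])) for name in fa.keys()}


def write_fasta(path: str | Path, sequences: Mapping[str, np.ndarray], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, arr in sequences.items():
            fh.write(f">{name}\n")
            s = array_to_seq(arr)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width])
                fh.write("\n")


def chrom_lengths_of(sequences: Mapping[str, np.ndarray]) -> Dict[str, int]:
    return {name: int(len(arr)) for name, arr in sequences.items()}


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3..BED6 into a frame with the full BED6 column set."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", skiprows=_track_lines(path))
    df = df.iloc[:, :4]
    df.columns = BEDGRAPH_COLUMNS
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


def _track_lines(path: str | Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(path: str | Path, df: pd.DataFrame, value_fmt: str = "%.6g") -> None:
    out = df[BEDGRAPH_COLUMNS].copy()
    out["value"] = out["value"].map(lambda v: value_fmt % v)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine call table (chrom, pos0, strand, context, n_meth, n_total, ratio)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "pos0": np.int64,
            "strand": str,
            "context": str,
            "n_meth": np.int64,
            "n_total": np.int64,
            "ratio": float,
        },
    )
    missing = set(CALLS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table {path} lacks columns: {sorted(missing)}")
    return df


def write_calls(path: str | Path, df: pd.DataFrame) -> None:
    out = df[CALLS_COLUMNS].copy()
    out["ratio"] = out["ratio"].map(lambda v: "%.6g" % v)
    out.to_csv(path, sep="\t", index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def merge_intervals(intervals: Iterable[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Merge sorted-or-not intervals, joining neighbours separated by <= gap."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
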