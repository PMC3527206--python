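"""Fixed-window methylation tracks and hypomethylated-domain calling.

A non-overlapping window of fixed width (defaults 100 kb and 20 kb) is
tiled along each chromosome; per window the mean of per-site CpG
methylation ratios over covered sites estimates the local methylation
density.  Differential tracks between two conditions flag windows whose
mean methylation drops by more than a cutoff (default 0.15); runs of
flagged windows merge into domains.  Partially methylated domains (PMDs)
are flagged windows conserved across replicate tumor-vs-normal
comparisons; Dnmt3a-protected domains (DPDs) are windows hypomethylated in
the knockout tumor relative to the wildtype tumor.  Window-level values
are correlated with external tracks (CpG density, lamina association,
H3K4me1) by Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from methdomains import io as mio

DEFAULT_WINDOW = 100_000
DEFAULT_DELTA = 0.15


def tile_windows(chrom_lengths: Mapping[str, int], w: int) -> pd.DataFrame:
    """Non-overlapping tiling; the trailing partial window is kept and flagged."""
    if w <= 0:
        raise ValueError("window size must be > 0")
    if w > max(chrom_lengths.values()):
        warnings.warn(f"window size {w} exceeds the longest chromosome; single-window tracks")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, w, dtype=np.int64)
        ends = np.minimum(starts + w, length)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "partial": ends - starts < w}
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class WindowTrack:
    """Per-window mean methylation over covered CpG sites.

    ``frame`` columns: chrom, start, end, partial, mean (NaN when the
    window holds no covered CpG), n_cpgs.
    """

    w: int
    frame: pd.DataFrame
    condition: Optional[str] = None

    def __len__(self) -> int:
        return len(self.frame)

    def same_tiling(self, other: "WindowTrack") -> bool:
        if self.w != other.w or len(self.frame) != len(other.frame):
            return False
        a, b = self.frame, other.frame
        return bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        )

    def to_bedgraph(self, path) -> None:
        df = self.frame.dropna(subset=["mean"])[["chrom", "start", "end", "mean"]]
        mio.write_bedgraph(path, df.rename(columns={"mean": "value"}))


def window_track(
    calls: pd.DataFrame,
    w: int,
    chrom_lengths: Mapping[str, int],
    condition: Optional[str] = None,
    pooled_counts: bool = False,
) -> WindowTrack:
    """Build the fixed-tiling methylation track from a call table.

    Window mean = arithmetic mean of per-site ratios of covered CG-context
    sites (both strands); with ``pooled_counts`` the window value is instead
    sum(n_meth)/sum(n_total) over those sites.
    """
    tiling = tile_windows(chrom_lengths, w)
    df = calls[(calls["context"] == "CG") & (calls["n_total"] > 0)]
    key_chrom = df["chrom"].to_numpy()
    win = df["pos0"].to_numpy() // w
    grouped = pd.DataFrame(
        {
            "chrom": key_chrom,
            "start": win * w,
            "ratio": df["ratio"].to_numpy(),
            "n_meth": df["n_meth"].to_numpy(),
            "n_total": df["n_total"].to_numpy(),
        }
    ).groupby(["chrom", "start"], sort=False)
    if pooled_counts:
        agg = grouped.agg(m=("n_meth", "sum"), t=("n_total", "sum"), n_cpgs=("ratio", "size"))
        agg["mean"] = agg["m"] / agg["t"]
        agg = agg.drop(columns=["m", "t"]).reset_index()
    else:
        agg = grouped.agg(mean=("ratio", "mean"), n_cpgs=("ratio", "size")).reset_index()
    out = tiling.merge(agg, on=["chrom", "start"], how="left")
    out["n_cpgs"] = out["n_cpgs"].fillna(0).astype(np.int64)
    return WindowTrack(w=w, frame=out, condition=condition)


@dataclass
class DifferentialTrack:
    """Window-wise methylation difference between two conditions.

    delta = mean(A) - mean(B); a window is *flagged* when methylation loss
    in A relative to baseline B exceeds ``delta_cut`` (mean(B) - mean(A) >
    delta_cut).  Windows undefined in either track (or partial trailing
    windows, by default) are incomparable and never flagged.
    """

    w: int
    delta_cut: float
    frame: pd.DataFrame  # chrom, start, end, partial, mean_a, mean_b, delta, comparable, flagged
    label: Optional[str] = None

    @property
    def n_flagged(self) -> int:
        return int(self.frame["flagged"].sum())

    @property
    def n_incomparable(self) -> int:
        return int((~self.frame["comparable"]).sum())

    def to_bedgraph(self, path) -> None:
        df = self.frame[self.frame["comparable"]][["chrom", "start", "end", "delta"]]
        mio.write_bedgraph(path, df.rename(columns={"delta": "value"}))


def differential_windows(
    track_a: WindowTrack,
    track_b: WindowTrack,
    delta: float = DEFAULT_DELTA,
    include_partial: bool = False,
    label: Optional[str] = None,
) -> Tuple[DifferentialTrack, int]:
    """Flag windows where condition A lost > ``delta`` methylation vs baseline B."""
    if not track_a.same_tiling(track_b):
        raise ValueError("differential windows require identical tilings")
    a, b = track_a.frame, track_b.frame
    out = a[["chrom", "start", "end", "partial"]].copy()
    out["mean_a"] = a["mean"].to_numpy()
    out["mean_b"] = b["mean"].to_numpy()
    out["delta"] = out["mean_a"] - out["mean_b"]
    comparable = out["mean_a"].notna() & out["mean_b"].notna()
    if not include_partial:
        comparable &= ~out["partial"]
    out["comparable"] = comparable
    out["flagged"] = comparable & ((out["mean_b"] - out["mean_a"]) > delta)
    diff = DifferentialTrack(w=track_a.w, delta_cut=delta, frame=out, label=label)
    return diff, diff.n_flagged


@dataclass
class DomainSet:
    """Merged hypomethylated domains (PMD or DPD)."""

    label: str
    frame: pd.DataFrame  # chrom, start, end, name, n_windows, mean_delta
    provenance: Tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.frame)

    def intervals(self) -> pd.DataFrame:
        return self.frame[["chrom", "start", "end"]]

    def to_bed(self, path) -> None:
        df = self.frame.copy()
        df["score"] = (df["mean_delta"] * 1000).round().astype(int).abs()
        df["strand"] = "."
        mio.write_bed(path, df)


def _merge_flagged(
    frame: pd.DataFrame,
    flags: np.ndarray,
    deltas: np.ndarray,
    label: str,
    gap_windows: int,
    min_windows: int,
) -> pd.DataFrame:
    """Merge runs of flagged windows (gap tolerance in windows) into domains."""
    rows = []
    chroms = frame["chrom"].to_numpy()
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    k = 0
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        idx = sel[flags[sel]]
        if len(idx) == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        members = [idx[0]]
        runs = []
        for i in idx[1:]:
            if i - prev <= gap_windows + 1:
                members.append(i)
            else:
                runs.append((run_start, prev, members))
                run_start = i
                members = [i]
            prev = i
        runs.append((run_start, prev, members))
        for s_i, e_i, mem in runs:
            n_win = len(mem)
            if n_win < min_windows:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[s_i]),
                    "end": int(ends[e_i]),
                    "name": f"{label}_{k:04d}",
                    "n_windows": n_win,
                    "mean_delta": float(np.nanmean(deltas[mem])),
                }
            )
            k += 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "n_windows", "mean_delta"]
    )


def call_conserved_pmds(
    diff_tracks: Sequence[DifferentialTrack],
    min_windows: int = 1,
    gap_windows: int = 0,
) -> DomainSet:
    """PMDs: windows flagged in *all* replicate comparisons, merged into runs.

    With a single comparison the call degrades to single-comparison domains
    (with a warning).
    """
    if len(diff_tracks) == 0:
        raise ValueError("at least one differential track is required")
    if len(diff_tracks) == 1:
        warnings.warn("only one comparison provided; PMDs are not replicate-conserved")
    first = diff_tracks[0]
    for other in diff_tracks[1:]:
        if other.w != first.w or len(other.frame) != len(first.frame):
            raise ValueError("all differential tracks must share one tiling")
    flags = np.logical_and.reduce([t.frame["flagged"].to_numpy() for t in diff_tracks])
    deltas = np.nanmean(
        np.vstack([t.frame["delta"].to_numpy(dtype=float) for t in diff_tracks]), axis=0
    )
    frame = _merge_flagged(first.frame, flags, deltas, "PMD", gap_windows, min_windows)
    return DomainSet(
        label="PMD",
        frame=frame,
        provenance=tuple(t.label or f"comparison{i}" for i, t in enumerate(diff_tracks)),
    )


def call_dpds(
    track_wt: WindowTrack,
    track_ko: WindowTrack,
    delta: float = DEFAULT_DELTA,
    min_windows: int = 1,
    gap_windows: int = 0,
) -> DomainSet:
    """DPDs: windows with mean(ko) < mean(wt) - delta, merged into runs."""
    diff, _ = differential_windows(track_ko, track_wt, delta=delta, label="ko_vs_wt")
    frame = _merge_flagged(
        diff.frame,
        diff.frame["flagged"].to_numpy(),
        diff.frame["delta"].to_numpy(dtype=float),
        "DPD",
        gap_windows,
        min_windows,
    )
    return DomainSet(label="DPD", frame=frame, provenance=("ko_vs_wt",))


def resample_track(
    track: pd.DataFrame, w: int, chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Coverage-weighted mean of a bedGraph onto the window tiling.

    Gaps in the bedGraph count as missing, not zero; a window with no
    overlapping record gets NaN.
    """
    tiling = tile_windows(chrom_lengths, w)
    sums = np.zeros(len(tiling))
    covs = np.zeros(len(tiling))
    index = {
        chrom: (np.flatnonzero(tiling["chrom"].to_numpy() == chrom)) for chrom in chrom_lengths
    }
    for chrom, sub in track.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in index:
            continue
        rows = index[chrom]
        base = rows[0]
        length = chrom_lengths[chrom]
        s = np.clip(sub["start"].to_numpy(), 0, length)
        e = np.clip(sub["end"].to_numpy(), 0, length)
        v = sub["value"].to_numpy(dtype=float)
        for si, ei, vi in zip(s, e, v):
            if ei <= si:
                continue
            first, last = si // w, (ei - 1) // w
            for wi in range(first, last + 1):
                lo = max(si, wi * w)
                hi = min(ei, (wi + 1) * w)
                sums[base + wi] += vi * (hi - lo)
                covs[base + wi] += hi - lo
    out = tiling.copy()
    with np.errstate(invalid="ignore"):
        out["value"] = np.where(covs > 0, sums / np.maximum(covs, 1), np.nan)
    return out


def correlate_with_track(
    window_values: pd.DataFrame,
    track: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    w: Optional[int] = None,
    min_windows: int = 10,
) -> Tuple[float, float, int]:
    """Spearman rank correlation between window values and an external track.

    ``window_values`` must carry chrom/start/end plus a ``value`` column on
    a fixed tiling; the external bedGraph is resampled onto that tiling by
    coverage-weighted mean.  Returns (rho, p_value, n_windows).
    """
    if "value" not in window_values.columns:
        raise ValueError("window_values needs a 'value' column")
    if w is None:
        w = int((window_values["end"] - window_values["start"]).max())
    resampled = resample_track(track, w, chrom_lengths)
    merged = window_values.merge(
        resampled[["chrom", "start", "value"]].rename(columns={"value": "track_value"}),
        on=["chrom", "start"],
        how="inner",
    )
    merged = merged.dropna(subset=["value", "track_value"])
    if len(merged) < min_windows:
        raise ValueError(f"only {len(merged)} comparable windows (need >= {min_windows})")
    x = merged["value"].to_numpy()
    y = merged["track_value"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), int(len(merged))


def cpg_density_track(
    sequences: Mapping[str, np.ndarray], w: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """CpG dyads per bp in each window of the tiling (value column)."""
    chrom_lengths = mio.chrom_lengths_of(sequences)
    tiling = tile_windows(chrom_lengths, w)
    values = np.zeros(len(tiling))
    row = 0
    for chrom, seq in sequences.items():
        dyads = np.flatnonzero((seq[:-1] == mio.C) & (seq[1:] == mio.G))
        n_win = int(np.ceil(len(seq) / w))
        counts = np.bincount(dyads // w, minlength=n_win)
        widths = (
            tiling.loc[row : row + n_win - 1, "end"].to_numpy()
            - tiling.loc[row : row + n_win - 1, "start"].to_numpy()
        )
        values[row : row + n_win] = counts / widths
        row += n_win
    out = tiling.copy()
    out["value"] = values
    return out


def interval_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Jaccard index of two interval sets (per-bp intersection / union)."""
    chroms = set(a["chrom"]) | set(b["chrom"])
    inter = union = 0
    for chrom in chroms:
        ia = mio.merge_intervals(
            [(int(r["start"]), int(r["end"])) for _, r in a[a["chrom"] == chrom].iterrows()]
        )
        ib = mio.merge_intervals(
            [(int(r["start"]), int(r["end"])) for _, r in b[b["chrom"] == chrom].iterrows()]
        )
        la = sum(e - s for s, e in ia)
        lb = sum(e - s for s, e in ib)
        ov = 0
        j = 0
        for s, e in ia:
            while j < len(ib) and ib[j][1] <= s:
                j += 1
            k = j
            while k < len(ib) and ib[k][0] < e:
                ov += min(e, ib[k][1]) - max(s, ib[k][0])
                k += 1
        inter += ov
        union += la + lb - ov
    return inter / union if union else float("nan")
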