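"""Bisulfite methylation calling from aligned reads.

The caller reproduces the classic strand-independent CpG pileup: for every
reference cytosine (on either strand) it counts C base calls as methylated
and T base calls as unmethylated, using only reads whose bisulfite protocol
strand is informative for that reference strand — original-top (OT) reads
inform top-strand cytosines, original-bottom (OB) reads inform bottom-strand
cytosines, where a bottom-strand C appears as a reference G and its
converted form as an A in reference orientation.  Other base calls
(mismatches, A/G on top) are ignored.  The bisulfite conversion rate is
estimated from the same pileup: C calls at all non-CpG cytosine positions
divided by all base calls at those positions, subtracted from 1.

Reads are first truncated to a maximal length (default 80 bp, applied from
the sequencing 5' end) and terminal stretches of bases below a Phred
quality threshold (default 30) are removed from both ends.

Counting is accumulated in whole-genome per-strand arrays with vectorised
slice updates per CIGAR block, which keeps multi-million-read inputs
tractable; an even faster matrix path handles the uniform-length in-memory
read sets produced by the simulator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from methdomains import io as mio
from methdomains.simulate.reads import SimulatedReadSet

logger = logging.getLogger(__name__)

CG, CH = "CG", "CH"


@dataclass
class ConversionEstimate:
    """Bisulfite conversion rate from non-CpG cytosine positions."""

    n_c_at_noncpg: int
    n_bases_at_noncpg: int

    @property
    def rate(self) -> float:
        if self.n_bases_at_noncpg <= 0:
            raise ValueError("conversion rate undefined: no non-CpG cytosine coverage")
        return 1.0 - self.n_c_at_noncpg / self.n_bases_at_noncpg


def trim_read(
    seq: np.ndarray,
    qual: np.ndarray,
    start: int,
    is_reverse: bool = False,
    max_length: Optional[int] = 80,
    min_quality: int = 30,
    trim_ends: str = "both",
) -> Optional[Tuple[np.ndarray, np.ndarray, int]]:
    """Truncate a read to ``max_length`` and strip low-quality terminal runs.

    ``seq``/``qual`` are in reference orientation (as stored in SAM); for a
    reverse-strand alignment the sequencing 5' end is the *right* end, so
    truncation keeps the rightmost ``max_length`` bases and the alignment
    start shifts accordingly.  Quality stripping removes maximal terminal
    runs with quality < ``min_quality`` from both ends (or only the
    sequencing 3' end with ``trim_ends="three_prime"``).  Returns
    ``(seq, qual, new_start)`` or ``None`` when nothing survives.
    """
    if qual is None or len(qual) != len(seq):
        warnings.warn("read discarded: missing or mismatched base qualities")
        return None
    n = len(seq)
    if max_length is not None and n > max_length:
        if is_reverse:
            start += n - max_length
            seq, qual = seq[n - max_length :], qual[n - max_length :]
        else:
            seq, qual = seq[:max_length], qual[:max_length]
        n = max_length
    ok = np.asarray(qual) >= min_quality
    if not ok.any():
        return None
    left = int(np.argmax(ok))
    right = int(n - np.argmax(ok[::-1]))
    if trim_ends == "three_prime":
        if is_reverse:
            right = n
        else:
            left = 0
    elif trim_ends != "both":
        raise ValueError(f"trim_ends must be 'both' or 'three_prime', got {trim_ends!r}")
    if right <= left:
        return None
    return seq[left:right], qual[left:right], start + left


@dataclass
class CallingResult:
    """Accumulated pileup counts plus bookkeeping, queryable per context."""

    chrom_order: Tuple[str, ...]
    meth_top: Dict[str, np.ndarray]
    unmeth_top: Dict[str, np.ndarray]
    cov_top: Dict[str, np.ndarray]
    meth_bot: Dict[str, np.ndarray]
    unmeth_bot: Dict[str, np.ndarray]
    cov_bot: Dict[str, np.ndarray]
    cg_top: Dict[str, np.ndarray]
    cg_bot: Dict[str, np.ndarray]
    ch_top: Dict[str, np.ndarray]
    ch_bot: Dict[str, np.ndarray]
    n_reads_used: int = 0
    n_reads_skipped: int = 0
    n_reads_discarded_trim: int = 0
    skip_reasons: Dict[str, int] = field(default_factory=dict)

    def conversion(self) -> ConversionEstimate:
        n_c = n_all = 0
        for chrom in self.chrom_order:
            n_c += int(self.meth_top[chrom][self.ch_top[chrom]].sum())
            n_c += int(self.meth_bot[chrom][self.ch_bot[chrom]].sum())
            n_all += int(self.cov_top[chrom][self.ch_top[chrom]].sum())
            n_all += int(self.cov_bot[chrom][self.ch_bot[chrom]].sum())
        return ConversionEstimate(n_c, n_all)

    def calls(self, context: str = CG, pool_strands: bool = False) -> pd.DataFrame:
        """Per-site call table; sites with zero C+T calls are omitted.

        ``pool_strands`` sums the two strands of each CpG dyad into one
        record at the dyad start (downstream convenience; the analyses
        themselves treat strands independently).
        """
        frames = []
        for chrom in self.chrom_order:
            for strand, meth, unmeth, cg_mask, ch_mask in (
                ("+", self.meth_top[chrom], self.unmeth_top[chrom], self.cg_top[chrom], self.ch_top[chrom]),
                ("-", self.meth_bot[chrom], self.unmeth_bot[chrom], self.cg_bot[chrom], self.ch_bot[chrom]),
            ):
                if context == CG:
                    ctx_mask = cg_mask
                elif context == CH:
                    ctx_mask = ch_mask
                elif context == "all":
                    ctx_mask = cg_mask | ch_mask
                else:
                    raise ValueError(f"context must be CG, CH or all, got {context!r}")
                pos = np.flatnonzero(ctx_mask)
                m = meth[pos]
                t = m + unmeth[pos]
                keep = t > 0
                pos, m, t = pos[keep], m[keep], t[keep]
                ctx = np.where(cg_mask[pos], CG, CH)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos0": pos.astype(np.int64),
                            "strand": strand,
                            "context": ctx,
                            "n_meth": m.astype(np.int64),
                            "n_total": t.astype(np.int64),
                        }
                    )
                )
        df = pd.concat(frames, ignore_index=True)
        if pool_strands and context == CG:
            # the - strand record of a dyad sits at dyad start + 1
            df["dyad"] = np.where(df["strand"].eq("-"), df["pos0"] - 1, df["pos0"])
            df = (
                df.groupby(["chrom", "dyad"], as_index=False, sort=True)
                .agg(n_meth=("n_meth", "sum"), n_total=("n_total", "sum"))
                .rename(columns={"dyad": "pos0"})
            )
            df["strand"] = "."
            df["context"] = CG
        df["ratio"] = df["n_meth"] / df["n_total"]
        df = df.sort_values(["chrom", "pos0", "strand"], ignore_index=True)
        return df[mio.CALLS_COLUMNS]


def _context_masks(seq: np.ndarray) -> tuple:
    """Reference context masks for one chromosome sequence (uint8 codes)."""
    is_c = seq == mio.C
    is_g = seq == mio.G
    cg_top = is_c.copy()
    cg_top[:-1] &= seq[1:] == mio.G
    cg_top[-1] = False
    cg_bot = is_g.copy()
    cg_bot[1:] &= seq[:-1] == mio.C
    cg_bot[0] = False
    ch_top = is_c & ~cg_top
    ch_bot = is_g & ~cg_bot
    return is_c, is_g, cg_top, cg_bot, ch_top, ch_bot


class MethylationCaller:
    """Streaming pileup accumulator over a loaded reference."""

    def __init__(self, reference: Mapping[str, np.ndarray]):
        self.reference = dict(reference)
        self.result = _empty_result(self.reference)
        self._is_c = {c: s == mio.C for c, s in self.reference.items()}
        self._is_g = {c: s == mio.G for c, s in self.reference.items()}

    def add_segment(self, chrom: str, ref_start: int, read_codes: np.ndarray, is_ot: bool) -> None:
        """Accumulate one gapless aligned block."""
        r = self.result
        s, e = ref_start, ref_start + len(read_codes)
        if is_ot:
            cmask = self._is_c[chrom][s:e]
            r.meth_top[chrom][s:e] += cmask & (read_codes == mio.C)
            r.unmeth_top[chrom][s:e] += cmask & (read_codes == mio.T)
            r.cov_top[chrom][s:e] += cmask
        else:
            gmask = self._is_g[chrom][s:e]
            r.meth_bot[chrom][s:e] += gmask & (read_codes == mio.G)
            r.unmeth_bot[chrom][s:e] += gmask & (read_codes == mio.A)
            r.cov_bot[chrom][s:e] += gmask

    def add_chunk(self, chrom: str, starts: np.ndarray, seqs: np.ndarray, is_ot: np.ndarray) -> None:
        """Vectorised accumulation of uniform-length gapless reads.

        Counts are binned over the genomic span the chunk actually covers,
        which keeps the per-chunk cost proportional to the chunk, not the
        chromosome.
        """
        r = self.result
        width = seqs.shape[1]
        offsets = np.arange(width, dtype=np.int32)
        for ot_value in (True, False):
            rows = np.flatnonzero(is_ot == ot_value)
            if len(rows) == 0:
                continue
            flat_idx = (starts[rows, None].astype(np.int32) + offsets[None, :]).ravel()
            flat_codes = seqs[rows].ravel()
            if ot_value:
                sitemask = self._is_c[chrom][flat_idx]
                meth_code, unmeth_code = mio.C, mio.T
                meth, unmeth, cov = r.meth_top[chrom], r.unmeth_top[chrom], r.cov_top[chrom]
            else:
                sitemask = self._is_g[chrom][flat_idx]
                meth_code, unmeth_code = mio.G, mio.A
                meth, unmeth, cov = r.meth_bot[chrom], r.unmeth_bot[chrom], r.cov_bot[chrom]
            flat_pos = flat_idx[sitemask]
            flat_codes = flat_codes[sitemask]
            if len(flat_pos) == 0:
                continue
            base = int(flat_pos.min())
            span = int(flat_pos.max()) - base + 1
            rel = flat_pos - base
            cov[base : base + span] += np.bincount(rel, minlength=span).astype(np.int32)
            meth[base : base + span] += np.bincount(
                rel[flat_codes == meth_code], minlength=span
            ).astype(np.int32)
            unmeth[base : base + span] += np.bincount(
                rel[flat_codes == unmeth_code], minlength=span
            ).astype(np.int32)
        r.n_reads_used += len(starts)


def _empty_result(reference: Mapping[str, np.ndarray]) -> CallingResult:
    meth_top, unmeth_top, cov_top = {}, {}, {}
    meth_bot, unmeth_bot, cov_bot = {}, {}, {}
    cg_top, cg_bot, ch_top, ch_bot = {}, {}, {}, {}
    for chrom, seq in reference.items():
        L = len(seq)
        for store in (meth_top, unmeth_top, cov_top, meth_bot, unmeth_bot, cov_bot):
            store[chrom] = np.zeros(L, dtype=np.int32)
        _, _, cg_t, cg_b, ch_t, ch_b = _context_masks(seq)
        cg_top[chrom], cg_bot[chrom] = cg_t, cg_b
        ch_top[chrom], ch_bot[chrom] = ch_t, ch_b
    return CallingResult(
        chrom_order=tuple(reference),
        meth_top=meth_top,
        unmeth_top=unmeth_top,
        cov_top=cov_top,
        meth_bot=meth_bot,
        unmeth_bot=unmeth_bot,
        cov_bot=cov_bot,
        cg_top=cg_top,
        cg_bot=cg_bot,
        ch_top=ch_top,
        ch_bot=ch_bot,
    )


ReadsInput = Union[str, Path, SimulatedReadSet]


def run_caller(
    reads: ReadsInput,
    reference: Mapping[str, np.ndarray],
    trim: bool = True,
    max_length: Optional[int] = 80,
    min_quality: int = 30,
    trim_ends: str = "both",
) -> CallingResult:
    """Run the full pileup over a SAM/BAM file or an in-memory read set."""
    caller = MethylationCaller(reference)
    if isinstance(reads, SimulatedReadSet):
        _accumulate_readset(caller, reads, trim, max_length, min_quality, trim_ends)
    else:
        _accumulate_sam(caller, str(reads), trim, max_length, min_quality, trim_ends)
    return caller.result


def call_methylation(
    reads: ReadsInput,
    reference: Mapping[str, np.ndarray],
    context_filter: str = CG,
    trim: bool = True,
    max_length: Optional[int] = 80,
    min_quality: int = 30,
    trim_ends: str = "both",
    pool_strands: bool = False,
) -> pd.DataFrame:
    """Per-cytosine methylation calls (chrom, pos0, strand, context, counts, ratio)."""
    result = run_caller(reads, reference, trim, max_length, min_quality, trim_ends)
    return result.calls(context=context_filter, pool_strands=pool_strands)


def estimate_conversion(
    reads: ReadsInput | CallingResult,
    reference: Mapping[str, np.ndarray] | None = None,
    **kwargs,
) -> ConversionEstimate:
    """Bisulfite conversion rate: 1 - (C calls / base calls) at non-CpG cytosines."""
    if isinstance(reads, CallingResult):
        return reads.conversion()
    if reference is None:
        raise ValueError("reference required when passing raw reads")
    return run_caller(reads, reference, **kwargs).conversion()


def aggregate_mean_ratio(calls: pd.DataFrame) -> float:
    """Arithmetic mean of per-site methylation ratios over covered sites."""
    covered = calls.loc[calls["n_total"] > 0, "ratio"]
    if len(covered) == 0:
        raise ValueError("cannot average an empty call collection")
    return float(covered.mean())


# ---------------------------------------------------------------------------
# input adapters


def _accumulate_readset(
    caller: MethylationCaller,
    readset: SimulatedReadSet,
    trim: bool,
    max_length: Optional[int],
    min_quality: int,
    trim_ends: str,
    chunk_reads: int = 200_000,
) -> None:
    """Fast path: uniform read length and a shared quality profile.

    The trim rule is resolved once on the quality profile and applied as a
    column slice per protocol-strand orientation.
    """
    qual = readset.quality_profile
    rl = readset.read_length
    if trim:
        # resolve the trim rule once on the shared quality profile; the
        # surviving reference-orientation column window is the same for
        # every read of a given alignment orientation.  OB reads here carry
        # flag 16, so their profile appears reversed in reference
        # orientation.
        fwd = trim_read(np.arange(rl), qual, 0, False, max_length, min_quality, trim_ends)
        rev = trim_read(np.arange(rl), qual[::-1], 0, True, max_length, min_quality, trim_ends)
        if fwd is None or rev is None:
            caller.result.n_reads_discarded_trim += readset.n_reads
            return
        fwd_cols = (int(fwd[0][0]), int(fwd[0][-1]) + 1)
        rev_cols = (int(rev[0][0]), int(rev[0][-1]) + 1)
    else:
        fwd_cols = rev_cols = (0, rl)

    for cr in readset.per_chrom:
        n = len(cr.starts)
        for lo in range(0, n, chunk_reads):
            hi = min(lo + chunk_reads, n)
            starts = cr.starts[lo:hi]
            seqs = cr.seqs[lo:hi]
            is_ot = cr.is_ot[lo:hi]
            for rows, cols, ot_value in (
                (np.flatnonzero(is_ot), fwd_cols, True),
                (np.flatnonzero(~is_ot), rev_cols, False),
            ):
                if len(rows) == 0:
                    continue
                caller.add_chunk(
                    cr.chrom,
                    starts[rows] + cols[0],
                    seqs[rows, cols[0] : cols[1]],
                    np.full(len(rows), ot_value, dtype=bool),
                )


def _infer_protocol_strand(read: pysam.AlignedSegment) -> Optional[bool]:
    """True for original-top, False for original-bottom, None if unknown."""
    for tag in ("ZS", "XG"):
        if read.has_tag(tag):
            v = str(read.get_tag(tag))
            if v.startswith("+") or v == "CT":
                return True
            if v.startswith("-") or v == "GA":
                return False
    return None


def _accumulate_sam(
    caller: MethylationCaller,
    path: str,
    trim: bool,
    max_length: Optional[int],
    min_quality: int,
    trim_ends: str,
) -> None:
    result = caller.result
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                result.n_reads_skipped += 1
                result.skip_reasons["flag"] = result.skip_reasons.get("flag", 0) + 1
                continue
            chrom = read.reference_name
            if chrom not in caller.reference:
                result.n_reads_skipped += 1
                result.skip_reasons["unknown_chrom"] = result.skip_reasons.get("unknown_chrom", 0) + 1
                continue
            is_ot = _infer_protocol_strand(read)
            if is_ot is None:
                # fall back on the alignment strand: a directional protocol
                # maps OT reads forward and OB reads reverse
                is_ot = not read.is_reverse
            seq = read.query_sequence
            if seq is None:
                result.n_reads_skipped += 1
                result.skip_reasons["no_seq"] = result.skip_reasons.get("no_seq", 0) + 1
                continue
            codes = mio.seq_to_array(seq)
            quals = read.query_qualities
            cigar = read.cigartuples or [(0, len(codes))]
            simple = len(cigar) == 1 and cigar[0][0] in (0, 7, 8)
            start = read.reference_start
            if trim and simple:
                q = np.asarray(quals, dtype=np.int16) if quals is not None else None
                trimmed = trim_read(
                    codes, q, start, read.is_reverse, max_length, min_quality, trim_ends
                )
                if trimmed is None:
                    result.n_reads_discarded_trim += 1
                    continue
                codes, _, start = trimmed
                caller.add_segment(chrom, start, codes, is_ot)
            else:
                # gapped alignments: accumulate per gapless block, untrimmed
                qpos = 0
                rpos = start
                for op, length in cigar:
                    if op in (0, 7, 8):  # M/=/X
                        caller.add_segment(chrom, rpos, codes[qpos : qpos + length], is_ot)
                        qpos += length
                        rpos += length
                    elif op in (1, 4):  # I / soft clip consume query
                        qpos += length
                    elif op in (2, 3):  # D / N consume reference
                        rpos += length
                    # H/P consume neither
            result.n_reads_used += 1
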