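"""Simulated aligned bisulfite reads.

Reads are sampled uniformly along each chromosome, half from the
original-top (OT) and half from the original-bottom (OB) protocol strand.
For an OT read, every reference-C base is reported as C when the underlying
molecule is methylated and as T with probability ``conversion_rate`` when
it is not (unconverted unmethylated cytosines stay C); OB reads show the
mirror image at reference-G positions (C->T on the bottom strand appears as
G->A in reference orientation).  Uniform substitution errors are applied on
top.  Reads are emitted with a ``ZS`` tag carrying the protocol strand
('+' = OT, '-' = OB), single-end, with a two-level quality profile (high
interior, low tail) so that the quality-trimming rule downstream has
something to bite on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import numpy as np

from methdomains import io as mio
from methdomains.simulate.genome import Genome
from methdomains.simulate.truth import TruthMethylome

_CODE_TO_RANK = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TO_RANK[_b] = _i
_RANK_TO_CODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadSimParams:
    """Sequencing-model parameters (study-condition defaults).

    coverage: target mean genome coverage in raw read bases / genome length.
    conversion_rate: probability a truly unmethylated C is converted (read T).
    error_rate: per-base uniform substitution error.
    low_tail: number of trailing sequencing cycles given ``quality_low``.
    """

    coverage: float = 10.0
    read_length: int = 105
    conversion_rate: float = 0.99
    error_rate: float = 0.001
    quality_high: int = 40
    quality_low: int = 20
    low_tail: int = 5
    paired: bool = False  # mate simulation adds no methylation information

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.9 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate outside [0.9, 1.0]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate outside [0, 1]")
        if self.paired:
            raise NotImplementedError("mate simulation is not implemented; single-end only")

    def quality_profile(self) -> np.ndarray:
        q = np.full(self.read_length, self.quality_high, dtype=np.uint8)
        if self.low_tail > 0:
            q[self.read_length - self.low_tail :] = self.quality_low
        return q


@dataclass
class ChromReads:
    """All simulated reads of one chromosome, column-wise."""

    chrom: str
    starts: np.ndarray  # int64, 0-based
    is_ot: np.ndarray  # bool, True = original-top protocol strand
    seqs: np.ndarray  # (n_reads, read_length) uint8 ASCII codes


@dataclass
class SimulatedReadSet:
    """Simulated aligned read set for one condition."""

    condition: str
    chrom_lengths: Dict[str, int]
    quality_profile: np.ndarray
    per_chrom: List[ChromReads] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(len(c.starts) for c in self.per_chrom)

    @property
    def total_bases(self) -> int:
        return sum(c.seqs.size for c in self.per_chrom)

    @property
    def read_length(self) -> int:
        return len(self.quality_profile)

    def iter_records(self) -> Iterator[Tuple[str, str, int, bool, np.ndarray]]:
        """Yield (name, chrom, start, is_ot, seq_codes) per read."""
        i = 0
        for cr in self.per_chrom:
            for j in range(len(cr.starts)):
                yield f"r{i:08d}", cr.chrom, int(cr.starts[j]), bool(cr.is_ot[j]), cr.seqs[j]
                i += 1

    def write_sam(self, path: str | Path) -> None:
        """Write a SAM file (1-based POS, flag 0 for OT / 16 for OB, ZS tag)."""
        rl = self.read_length
        qual = "".join(chr(q + 33) for q in self.quality_profile)
        qual_rev = qual[::-1]
        cigar = f"{rl}M"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
            fh.write("@PG\tID:methdomains\tPN:methdomains-simulate\n")
            i = 0
            for cr in self.per_chrom:
                chrom = cr.chrom
                raw = cr.seqs.tobytes()
                for j in range(len(cr.starts)):
                    seq = raw[j * rl : (j + 1) * rl].decode("ascii")
                    if cr.is_ot[j]:
                        flag, zs, q = 0, "+", qual
                    else:
                        # quality profile is in sequencing-cycle order; a
                        # reverse-strand alignment shows it reversed
                        flag, zs, q = 16, "-", qual_rev
                    fh.write(
                        f"r{i:08d}\t{flag}\t{chrom}\t{cr.starts[j] + 1}\t255\t{cigar}"
                        f"\t*\t0\t0\t{seq}\t{q}\tZS:Z:{zs}\n"
                    )
                    i += 1


def _per_position_truth(
    genome: Genome, truth: TruthMethylome, condition: str, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-dyad truth into per-bp arrays for each strand.

    p_top[i] = true methylation probability of a top-strand C at i
    p_bot[i] = same for a bottom-strand C (reference G at i).
    Non-CpG cytosines get ``truth.noncpg_level``.
    """
    seq = genome.sequences[chrom]
    L = len(seq)
    p_cpg = truth.probs[condition][chrom]
    pos = truth.cpg_positions[chrom]
    p_top = np.zeros(L, dtype=np.float32)
    p_bot = np.zeros(L, dtype=np.float32)
    if truth.noncpg_level > 0:
        p_top[seq == mio.C] = truth.noncpg_level
        p_bot[seq == mio.G] = truth.noncpg_level
    p_top[pos] = p_cpg
    p_bot[pos + 1] = p_cpg
    return p_top, p_bot


def simulate_bisulfite_reads(
    genome: Genome,
    truth: TruthMethylome,
    condition: str = "normal",
    params: ReadSimParams | None = None,
    seed: int = 0,
    chunk_reads: int = 200_000,
) -> SimulatedReadSet:
    """Simulate a single-end aligned bisulfite read set for one condition.

    Deterministic given ``seed``.  The number of reads per chromosome is
    ``round(length * coverage / read_length)``.
    """
    params = params or ReadSimParams()
    rl = params.read_length
    conv = truth.conversion_rates.get(condition, 0.99)
    min_len = min(genome.chrom_lengths.values())
    if rl > min_len:
        raise ValueError(f"read_length {rl} exceeds shortest chromosome ({min_len} bp)")

    cond_key = zlib.crc32(condition.encode()) % (2**31)
    root = np.random.SeedSequence(entropy=seed, spawn_key=(cond_key,))
    chrom_seeds = root.spawn(len(genome.sequences))
    out = SimulatedReadSet(
        condition=condition,
        chrom_lengths=genome.chrom_lengths,
        quality_profile=params.quality_profile(),
    )
    offsets = np.arange(rl, dtype=np.int32)
    for (chrom, seq), ss in zip(genome.sequences.items(), chrom_seeds):
        rng = np.random.default_rng(ss)
        L = len(seq)
        n_reads = int(round(L * params.coverage / rl))
        starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads)).astype(np.int64)
        is_ot = rng.random(n_reads) < 0.5
        p_top, p_bot = _per_position_truth(genome, truth, condition, chrom)
        seqs = np.empty((n_reads, rl), dtype=np.uint8)
        for lo in range(0, n_reads, chunk_reads):
            hi = min(lo + chunk_reads, n_reads)
            flat_idx = (starts[lo:hi, None].astype(np.int32) + offsets[None, :]).ravel()
            block = seq[flat_idx]
            ot_cells = np.repeat(is_ot[lo:hi], rl)
            # randomness is only needed at informative cytosine cells:
            # P(report T | ref C, OT read) = (1 - p) * conversion_rate,
            # and the mirror image (G -> A) on original-bottom reads
            for code, out_code, p_arr, cells in (
                (mio.C, mio.T, p_top, ot_cells),
                (mio.G, mio.A, p_bot, ~ot_cells),
            ):
                cand = np.flatnonzero((block == code) & cells)
                if len(cand):
                    pv = p_arr[flat_idx[cand]]
                    u = rng.random(len(cand))
                    block[cand[u < (1.0 - pv) * conv]] = out_code
            if params.error_rate > 0:
                # sampled error positions (with replacement: a doubly hit
                # cell is still a single substituted base)
                n_err = rng.binomial(block.size, params.error_rate)
                if n_err:
                    pos = rng.integers(0, block.size, size=n_err)
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    block[pos] = _RANK_TO_CODE[(_CODE_TO_RANK[block[pos]] + shift) % 4]
            seqs[lo:hi] = block.reshape(-1, rl)
        out.per_chrom.append(ChromReads(chrom=chrom, starts=starts, is_ot=is_ot, seqs=seqs))
    return out
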