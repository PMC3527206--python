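"""Synthetic genome construction with planted domain architecture.

The genome is a random sequence with *no* background CpG dinucleotides;
every CpG dyad is planted explicitly at a position sampled from a
per-region density, so the realised CpG landscape follows the plan exactly
(up to binomial sampling).  PMD-like intervals are CpG-poor, DPD-like
intervals CpG-dense, mirroring the contrast between inactive
lamina-associated heterochromatin and active, CpG-rich chromatin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from methdomains import io as mio

#: Condition labels: normal lung, Dnmt3a-wildtype tumor, Dnmt3a-knockout tumor.
CONDITIONS = ("normal", "wt", "ko")

SUBREGIONS = ("utr5", "exon", "intron", "utr3")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DomainInterval:
    """A planted megabase-scale domain.

    ``shift`` maps condition -> additive change of the true methylation
    probability inside the interval (clipped to [0, 1]).  ``weights``
    optionally replaces the genome-wide methylation-state mixture weights
    for CpGs inside the domain; by default PMD/DPD-like domains are almost
    fully methylated in the baseline so a planted loss is well defined.
    """

    chrom: str
    start: int
    end: int
    label: str  # "PMD" | "DPD" | "neutral"
    cpg_multiplier: float = 1.0
    shift: Mapping[str, float] = field(default_factory=dict)
    weights: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.label not in ("PMD", "DPD", "neutral"):
            raise ValueError(f"unknown domain label {self.label!r}")
        if self.cpg_multiplier <= 0:
            raise ValueError("cpg_multiplier must be > 0")
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad domain interval [{self.start}, {self.end})")


@dataclass
class RepeatPlan:
    """Dispersed (or tandem) repeat family with per-condition methylation."""

    family: str
    copy_length: int = 500
    copy_count: int = 50
    meth: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 0.85, "wt": 0.80, "ko": 0.70}
    )
    tandem: bool = False

    def __post_init__(self) -> None:
        for cond, m in self.meth.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"repeat methylation for {cond} outside [0,1]")


@dataclass
class GenePlan:
    """Gene-model plan: identical gene structures placed across the genome.

    A gene is [5'UTR][exon [intron exon]...][3'UTR]; the promoter is the
    1 kb upstream of the TSS and is not part of the gene interval.
    ``frac_in_dpd`` steers placement into DPD-like domains (active,
    gene-rich chromatin); genes are never placed inside PMD-like domains
    (gene-poor heterochromatin).
    """

    n_genes: int = 100
    n_exons: int = 3
    utr5_length: int = 200
    exon_length: int = 200
    intron_length: int = 1000
    utr3_length: int = 500
    frac_in_dpd: float = 0.5
    cgi_fraction: float = 0.5  # fraction of promoters carrying a CpG island
    cgi_length: int = 600
    cgi_multiplier: float = 8.0

    @property
    def gene_length(self) -> int:
        return (
            self.utr5_length
            + self.n_exons * self.exon_length
            + (self.n_exons - 1) * self.intron_length
            + self.utr3_length
        )


@dataclass
class GenomeSpec:
    """Complete plan for one synthetic study (genome + truth parameters).

    ``state_weights`` are the genome-wide mixture weights for the
    (unmethylated, partially methylated, fully methylated) CpG states in
    the baseline; the defaults reproduce the bimodal normal-lung profile
    (17% / 35% / 48%).  ``beta_components`` are the Beta(a, b) parameters
    of the three states; they are sharp spikes near 0, 0.5 and 1 so the
    planted state of a CpG remains recoverable from finite-coverage reads.
    """

    chrom_lengths: Mapping[str, int]
    cpg_per_kb: float = 10.0
    domains: List[DomainInterval] = field(default_factory=list)
    repeats: List[RepeatPlan] = field(default_factory=list)
    genes: GenePlan = field(default_factory=GenePlan)
    seed: int = 0
    state_weights: Tuple[float, float, float] = (0.17, 0.35, 0.48)
    beta_components: Tuple[Tuple[float, float], ...] = ((0.5, 500.0), (5.0, 5.0), (500.0, 0.5))
    domain_state_weights: Tuple[float, float, float] = (0.02, 0.08, 0.90)
    noncpg_level: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.state_weights) - 1.0) > 1e-9:
            raise ValueError("state_weights must sum to 1")
        if not 0.0 <= self.noncpg_level <= 1.0:
            raise ValueError("noncpg_level outside [0,1]")
        planted: Dict[str, List[Tuple[int, int]]] = {}
        for dom in self.domains:
            if dom.chrom not in self.chrom_lengths:
                raise ValueError(f"domain on unknown chromosome {dom.chrom!r}")
            if dom.end > self.chrom_lengths[dom.chrom]:
                raise ValueError(f"domain [{dom.start},{dom.end}) exceeds {dom.chrom} length")
            if dom.label in ("PMD", "DPD"):
                planted.setdefault(dom.chrom, []).append((dom.start, dom.end))
        for chrom, ivs in planted.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping planted domains on {chrom}: [{s1},{e1}) and [{s2},{e2})"
                    )

    def domains_on(self, chrom: str, labels: Sequence[str] = ("PMD", "DPD")) -> List[DomainInterval]:
        return [d for d in self.domains if d.chrom == chrom and d.label in labels]

    def replace(self, **kwargs) -> "GenomeSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Genome:
    """A built synthetic genome plus its annotations (all 0-based half-open)."""

    spec: GenomeSpec
    sequences: Dict[str, np.ndarray]  # chrom -> uint8 ASCII codes
    cpg_positions: Dict[str, np.ndarray]  # chrom -> sorted dyad start positions
    genes: pd.DataFrame  # BED6: name = gene id
    subregions: pd.DataFrame  # BED6: name = "<gene>:<utr5|exon|intron|utr3>"
    repeats: pd.DataFrame  # BED6: name = family
    cgi: pd.DataFrame  # BED6 CpG islands
    domains: pd.DataFrame  # BED6: name = label

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return mio.chrom_lengths_of(self.sequences)

    @property
    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))

    def write(self, outdir) -> Dict[str, str]:
        """Write genome.fa and annotation BEDs; returns name -> path."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": str(outdir / "genome.fa")}
        mio.write_fasta(paths["genome"], self.sequences)
        for name, df in (
            ("genes", self.genes),
            ("subregions", self.subregions),
            ("repeats", self.repeats),
            ("cgi", self.cgi),
            ("domains_truth", self.domains),
        ):
            paths[name] = str(outdir / f"{name}.bed")
            mio.write_bed(paths[name], df)
        return paths


def default_spec(
    chrom_lengths: Mapping[str, int] | None = None,
    seed: int = 0,
    pmd_fraction: float = 0.25,
    dpd_fraction: float = 0.15,
    domain_size: int = 500_000,
    pmd_shift: Mapping[str, float] | None = None,
    dpd_shift: Mapping[str, float] | None = None,
    n_genes: int = 100,
) -> GenomeSpec:
    """Study-condition default plan.

    Alternating PMD-like (CpG-poor, hypomethylated in both tumor
    conditions) and DPD-like (CpG-dense, hypomethylated only in the
    knockout tumor) domains are laid out on a regular grid covering
    roughly the requested genome fractions.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 10_000_000}
    pmd_shift = dict(pmd_shift or {"wt": -0.30, "ko": -0.30})
    dpd_shift = dict(dpd_shift or {"ko": -0.30})
    domains: List[DomainInterval] = []
    # deterministic layout on a domain_size grid: per period of 8 slots,
    # round(8*fraction) PMD/DPD slots spread evenly so that even short
    # chromosomes see both domain types
    period = 8
    n_pmd = int(round(period * pmd_fraction)) if pmd_fraction > 0 else 0
    n_dpd = int(round(period * dpd_fraction)) if dpd_fraction > 0 else 0
    pattern = ["neutral"] * period
    for i in range(n_pmd):
        pattern[(i * period) // max(n_pmd, 1)] = "PMD"
    for i in range(n_dpd):
        slot = ((2 * i + 1) * period) // max(2 * n_dpd, 1)
        while pattern[slot % period] != "neutral":
            slot += 1
        pattern[slot % period] = "DPD"
    for chrom, length in chrom_lengths.items():
        n_slots = length // domain_size
        for slot in range(n_slots):
            label = pattern[slot % len(pattern)]
            start = slot * domain_size
            end = start + domain_size
            if label == "PMD":
                domains.append(
                    DomainInterval(chrom, start, end, "PMD", cpg_multiplier=0.5, shift=pmd_shift)
                )
            elif label == "DPD":
                domains.append(
                    DomainInterval(chrom, start, end, "DPD", cpg_multiplier=4.0, shift=dpd_shift)
                )
    return GenomeSpec(
        chrom_lengths=dict(chrom_lengths),
        domains=domains,
        repeats=[
            RepeatPlan("Line1", copy_length=1000, copy_count=30),
            RepeatPlan("SineB1", copy_length=150, copy_count=60),
            RepeatPlan("Satellite", copy_length=300, copy_count=20, tandem=True),
        ],
        genes=GenePlan(n_genes=n_genes),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# construction


def build_genome(spec: GenomeSpec) -> Genome:
    """Build the reference sequence and annotations from a plan.

    Deterministic given ``spec.seed``.  The background sequence contains no
    CG dinucleotides; CpG dyads are planted at rate
    ``cpg_per_kb / 1000 * multiplier`` per bp, where the multiplier comes
    from the domain plan (and CpG islands).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    seq_ss, place_ss = root.spawn(2)
    rng = np.random.default_rng(seq_ss)
    place_rng = np.random.default_rng(place_ss)

    # --- annotations that alter CpG density must be placed first
    genes, subregions, cgi = _place_genes(spec, place_rng)
    repeats = _place_repeats(spec, place_rng, genes)

    sequences: Dict[str, np.ndarray] = {}
    cpg_positions: Dict[str, np.ndarray] = {}
    base_rate = spec.cpg_per_kb / 1000.0
    for chrom, length in spec.chrom_lengths.items():
        seq = _BASES[rng.integers(0, 4, size=length)]
        # erase background CG dyads so planted CpGs are the only ones
        mask = (seq[:-1] == mio.C) & (seq[1:] == mio.G)
        seq[1:][mask] = mio.A
        rate = np.full(length, base_rate, dtype=np.float32)
        for dom in spec.domains_on(chrom, labels=("PMD", "DPD", "neutral")):
            rate[dom.start : dom.end] *= dom.cpg_multiplier
        for _, row in cgi[cgi["chrom"] == chrom].iterrows():
            rate[row["start"] : row["end"]] *= spec.genes.cgi_multiplier
        np.clip(rate, 0.0, 0.5, out=rate)
        pos = np.flatnonzero(rng.random(length) < rate)
        pos = pos[pos <= length - 2]
        pos = _drop_adjacent(pos)
        seq[pos] = mio.C
        seq[pos + 1] = mio.G
        sequences[chrom] = seq
        cpg_positions[chrom] = pos.astype(np.int64)

    domains_df = pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "name": d.label,
                "score": 0,
                "strand": ".",
            }
            for d in spec.domains
        ],
        columns=mio.BED_COLUMNS,
    )
    return Genome(
        spec=spec,
        sequences=sequences,
        cpg_positions=cpg_positions,
        genes=genes,
        subregions=subregions,
        repeats=repeats,
        cgi=cgi,
        domains=domains_df,
    )


def _drop_adjacent(pos: np.ndarray, min_gap: int = 2) -> np.ndarray:
    """Greedily drop positions closer than min_gap so CG dyads never overlap."""
    while len(pos) > 1:
        close = np.flatnonzero(np.diff(pos) < min_gap)
        if len(close) == 0:
            break
        # drop the later member of each too-close pair, skipping chained runs
        drop = []
        last = -2
        for i in close:
            if i != last + 1:
                drop.append(i + 1)
            last = i
        pos = np.delete(pos, drop)
    return pos


def _interval_overlaps(start: int, end: int, intervals: Sequence[Tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in intervals)


def _place_genes(
    spec: GenomeSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    plan = spec.genes
    gene_rows, sub_rows, cgi_rows = [], [], []
    if plan.n_genes == 0:
        empty = pd.DataFrame(columns=mio.BED_COLUMNS)
        return empty, empty.copy(), empty.copy()

    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    pmd_by_chrom = {c: [(d.start, d.end) for d in spec.domains_on(c, ("PMD",))] for c in chroms}
    dpd_by_chrom = {c: [(d.start, d.end) for d in spec.domains_on(c, ("DPD",))] for c in chroms}
    dpd_all = [(c, s, e) for c in chroms for (s, e) in dpd_by_chrom[c]]
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    margin = 1000  # keep promoters clear of the neighbouring gene
    glen = plan.gene_length

    placed = 0
    attempts = 0
    while placed < plan.n_genes and attempts < plan.n_genes * 200:
        attempts += 1
        in_dpd = bool(dpd_all) and rng.random() < plan.frac_in_dpd
        if in_dpd:
            c, ds, de = dpd_all[rng.integers(len(dpd_all))]
            if de - ds < glen + 2 * margin:
                continue
            start = int(rng.integers(ds + margin, de - glen - margin + 1))
        else:
            c = chroms[rng.choice(len(chroms), p=chrom_p)]
            if spec.chrom_lengths[c] < glen + 2 * margin:
                continue
            start = int(rng.integers(margin, spec.chrom_lengths[c] - glen - margin + 1))
            if _interval_overlaps(start, start + glen, pmd_by_chrom[c]):
                continue
        if _interval_overlaps(start - margin, start + glen + margin, occupied[c]):
            continue
        occupied[c].append((start, start + glen))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{placed:04d}"
        end = start + glen
        gene_rows.append((c, start, end, name, 0, strand))
        # genomic layout of subregions, 5'->3' along the strand
        parts: List[Tuple[str, int]] = [("utr5", plan.utr5_length)]
        for i in range(plan.n_exons):
            parts.append(("exon", plan.exon_length))
            if i < plan.n_exons - 1:
                parts.append(("intron", plan.intron_length))
        parts.append(("utr3", plan.utr3_length))
        if strand == "-":
            parts = parts[::-1]
        cursor = start
        for kind, width in parts:
            sub_rows.append((c, cursor, cursor + width, f"{name}:{kind}", 0, strand))
            cursor += width
        if rng.random() < plan.cgi_fraction:
            tss = start if strand == "+" else end - 1
            half = plan.cgi_length // 2
            cs = max(0, tss - half)
            ce = min(spec.chrom_lengths[c], tss + half)
            cgi_rows.append((c, cs, ce, f"cgi_{name}", 0, "."))
        placed += 1
    if placed < plan.n_genes:
        raise ValueError(
            f"could only place {placed}/{plan.n_genes} genes; genome too small or too constrained"
        )
    genes = pd.DataFrame(gene_rows, columns=mio.BED_COLUMNS)
    subregions = pd.DataFrame(sub_rows, columns=mio.BED_COLUMNS)
    cgi = pd.DataFrame(cgi_rows, columns=mio.BED_COLUMNS)
    return genes, subregions, cgi


def _place_repeats(
    spec: GenomeSpec, rng: np.random.Generator, genes: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    blocked: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for c in chroms:
        blocked[c].extend((d.start, d.end) for d in spec.domains_on(c, ("PMD", "DPD")))
    for _, g in genes.iterrows():
        blocked[g["chrom"]].append((int(g["start"]) - 1000, int(g["end"])))

    for plan in spec.repeats:
        if plan.tandem:
            block_len = plan.copy_length * plan.copy_count
            for _ in range(500):
                c = chroms[rng.choice(len(chroms), p=chrom_p)]
                if spec.chrom_lengths[c] <= block_len:
                    continue
                start = int(rng.integers(0, spec.chrom_lengths[c] - block_len))
                if not _interval_overlaps(start, start + block_len, blocked[c]):
                    break
            else:
                raise ValueError(f"could not place tandem block for {plan.family}")
            for i in range(plan.copy_count):
                s = start + i * plan.copy_length
                rows.append((c, s, s + plan.copy_length, plan.family, 0, "."))
            blocked[c].append((start, start + block_len))
        else:
            placed = 0
            attempts = 0
            while placed < plan.copy_count and attempts < plan.copy_count * 200:
                attempts += 1
                c = chroms[rng.choice(len(chroms), p=chrom_p)]
                if spec.chrom_lengths[c] <= plan.copy_length:
                    continue
                start = int(rng.integers(0, spec.chrom_lengths[c] - plan.copy_length))
                if _interval_overlaps(start, start + plan.copy_length, blocked[c]):
                    continue
                rows.append((c, start, start + plan.copy_length, plan.family, 0, "."))
                blocked[c].append((start, start + plan.copy_length))
                placed += 1
            if placed < plan.copy_count:
                raise ValueError(f"could only place {placed} copies of {plan.family}")
    df = pd.DataFrame(rows, columns=mio.BED_COLUMNS)
    return df.sort_values(["chrom", "start"], ignore_index=True)
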