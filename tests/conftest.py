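"""Shared fixtures: a small synthetic study and hand-written SAM helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from methdomains import io as mio
from methdomains.simulate import (
    DomainInterval,
    GenePlan,
    GenomeSpec,
    ReadSimParams,
    RepeatPlan,
    assign_truth_methylome,
    build_genome,
    simulate_bisulfite_reads,
)


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    """400 kb genome with one PMD-like and one DPD-like domain."""
    return GenomeSpec(
        chrom_lengths={"chr1": 400_000},
        cpg_per_kb=10.0,
        domains=[
            DomainInterval("chr1", 50_000, 150_000, "PMD", 0.5, {"wt": -0.3, "ko": -0.3}),
            DomainInterval("chr1", 200_000, 300_000, "DPD", 4.0, {"ko": -0.3}),
        ],
        repeats=[RepeatPlan("Line1", copy_length=500, copy_count=10)],
        genes=GenePlan(n_genes=12),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return build_genome(small_spec)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_spec):
    return assign_truth_methylome(small_genome, small_spec, conversion_rates=0.99)


@pytest.fixture(scope="session")
def small_reads(small_genome, small_truth):
    return simulate_bisulfite_reads(
        small_genome, small_truth, "normal", ReadSimParams(coverage=10.0), seed=11
    )


@pytest.fixture(scope="session")
def small_calls(small_genome, small_reads):
    from methdomains import calling

    return calling.call_methylation(small_reads, small_genome.sequences)


def make_sam(
    path: Path,
    chrom_lengths: dict,
    reads: list[dict],
) -> str:
    """Write a SAM from dicts with keys name, flag, chrom, pos0, seq, qual,
    and optionally cigar (default '<len>M') and zs ('+'/'-')."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for r in reads:
        seq = r["seq"]
        qual = r.get("qual", "I" * len(seq))
        cigar = r.get("cigar", f"{len(seq)}M")
        tags = []
        if "zs" in r:
            tags.append(f"ZS:Z:{r['zs']}")
        fields = [
            r.get("name", "read"),
            str(r.get("flag", 0)),
            r["chrom"],
            str(r["pos0"] + 1),
            "255",
            cigar,
            "*",
            "0",
            "0",
            seq,
            qual,
        ] + tags
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def reference_from_strings(seqs: dict[str, str]) -> dict[str, np.ndarray]:
    return {name: mio.seq_to_array(s) for name, s in seqs.items()}
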