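"""Synthetic-methylome generator: genome, truth and read properties."""

from __future__ import annotations

import numpy as np
import pytest

from methdomains import io as mio
from methdomains.simulate import (
    DomainInterval,
    GenePlan,
    GenomeSpec,
    ReadSimParams,
    assign_truth_methylome,
    build_genome,
    simulate_bisulfite_reads,
    simulate_external_tracks,
)


def test_chromosome_lengths_match_plan(tmp_path):
    spec = GenomeSpec(
        chrom_lengths={"chrA": 50_000, "chrB": 30_000}, genes=GenePlan(n_genes=0), seed=3
    )
    genome = build_genome(spec)
    assert len(genome.sequences["chrA"]) == 50_000
    assert len(genome.sequences["chrB"]) == 30_000
    mio.write_fasta(tmp_path / "g.fa", genome.sequences)
    back = mio.read_fasta(tmp_path / "g.fa")
    assert all(np.array_equal(back[c], genome.sequences[c]) for c in back)


def test_all_cpg_dyads_are_planted(small_genome):
    """Background CG dyads are erased, so the dyad list is exhaustive."""
    for chrom, seq in small_genome.sequences.items():
        dyads = np.flatnonzero((seq[:-1] == mio.C) & (seq[1:] == mio.G))
        assert np.array_equal(dyads, small_genome.cpg_positions[chrom])


def test_cpg_density_follows_domain_multiplier():
    # gene-free plan so CpG-island promoters don't add density on top
    spec = GenomeSpec(
        chrom_lengths={"chr1": 600_000},
        cpg_per_kb=10.0,
        domains=[
            DomainInterval("chr1", 50_000, 150_000, "PMD", 0.5),
            DomainInterval("chr1", 200_000, 300_000, "DPD", 4.0),
        ],
        genes=GenePlan(n_genes=0),
        seed=11,
    )
    genome = build_genome(spec)
    pos = genome.cpg_positions["chr1"]
    base = spec.cpg_per_kb / 1000.0
    for dom in spec.domains:
        n = np.searchsorted(pos, dom.end) - np.searchsorted(pos, dom.start)
        expect = base * dom.cpg_multiplier * (dom.end - dom.start)
        # binomial 4-sigma band
        assert abs(n - expect) < 4 * np.sqrt(expect)


def test_empty_plans_leave_only_domain_annotations():
    spec = GenomeSpec(
        chrom_lengths={"chr1": 100_000},
        domains=[DomainInterval("chr1", 0, 50_000, "PMD")],
        genes=GenePlan(n_genes=0),
        seed=5,
    )
    genome = build_genome(spec)
    assert len(genome.genes) == 0
    assert len(genome.repeats) == 0
    assert len(genome.cgi) == 0
    assert len(genome.domains) == 1


def test_overlapping_planted_domains_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        GenomeSpec(
            chrom_lengths={"chr1": 1_000_000},
            domains=[
                DomainInterval("chr1", 0, 500_000, "PMD"),
                DomainInterval("chr1", 400_000, 900_000, "DPD"),
            ],
        )


def test_domain_outside_chromosome_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        GenomeSpec(
            chrom_lengths={"chr1": 100_000},
            domains=[DomainInterval("chr1", 50_000, 200_000, "PMD")],
        )


def test_genome_build_is_deterministic(small_spec, small_genome):
    again = build_genome(small_spec)
    for chrom in small_genome.sequences:
        assert np.array_equal(again.sequences[chrom], small_genome.sequences[chrom])
    assert again.genes.equals(small_genome.genes)
    assert again.repeats.equals(small_genome.repeats)


class TestTruthMethylome:
    def test_entry_conservation(self, small_genome, small_truth):
        assert small_truth.n_entries == 2 * small_genome.n_cpgs

    def test_state_weight_recovery(self):
        """Fraction of truth probabilities < 0.05 matches the unmethylated weight."""
        spec = GenomeSpec(
            chrom_lengths={"chr1": 3_000_000}, genes=GenePlan(n_genes=0), seed=7
        )
        truth = assign_truth_methylome(build_genome(spec), spec)
        p = truth.probs["normal"]["chr1"]
        assert len(p) > 20_000
        for frac, expect in (
            (float((p < 0.05).mean()), 0.17),
            (float((p > 0.95).mean()), 0.48),
        ):
            assert abs(frac - expect) < 0.01

    def test_neutral_regions_identical_across_conditions(self, small_genome, small_truth):
        # outside planted domains and outside repeats (repeat families carry
        # their own per-condition methylation), the truth is condition-free
        pos = small_truth.cpg_positions["chr1"]
        neutral = (pos >= 310_000) & (pos < 390_000)
        for _, r in small_genome.repeats.iterrows():
            neutral &= ~((pos >= r["start"]) & (pos < r["end"]))
        assert neutral.sum() > 100
        assert np.array_equal(
            small_truth.probs["normal"]["chr1"][neutral],
            small_truth.probs["wt"]["chr1"][neutral],
        )

    def test_planted_shift_recovered_in_dpd(self):
        # gene-free plan: without unmethylated CpG-island promoters inside
        # the domain (whose shift clips at 0) the mean drop equals the shift
        spec = GenomeSpec(
            chrom_lengths={"chr1": 400_000},
            domains=[DomainInterval("chr1", 100_000, 300_000, "DPD", 1.0, {"ko": -0.3})],
            genes=GenePlan(n_genes=0),
            seed=13,
        )
        truth = assign_truth_methylome(build_genome(spec), spec)
        m_wt = truth.mean_in("chr1", 100_000, 300_000, "wt")
        m_ko = truth.mean_in("chr1", 100_000, 300_000, "ko")
        assert m_ko == pytest.approx(m_wt - 0.3, abs=0.03)

    def test_planted_effect_monotonicity(self, small_truth):
        pos = small_truth.cpg_positions["chr1"]
        dpd = (pos >= 200_000) & (pos < 300_000)
        pmd = (pos >= 50_000) & (pos < 150_000)
        t = small_truth.probs
        assert (t["ko"]["chr1"][dpd] <= t["wt"]["chr1"][dpd]).all()
        assert (t["wt"]["chr1"][pmd] <= t["normal"]["chr1"][pmd]).all()

    def test_truth_frame_has_both_strands(self, small_truth):
        df = small_truth.to_frame()
        assert len(df) == small_truth.n_entries
        plus = df[df["strand"] == "+"]
        minus = df[df["strand"] == "-"]
        assert np.array_equal(plus["p_normal"].to_numpy(), minus["p_normal"].to_numpy())
        assert np.array_equal(plus["pos0"].to_numpy() + 1, minus["pos0"].to_numpy())


class TestReadSimulation:
    def test_fully_methylated_noiseless_reads_keep_all_cg(self, small_genome):
        truth = _constant_truth(small_genome, 1.0, conversion=1.0)
        reads = simulate_bisulfite_reads(
            small_genome,
            truth,
            "normal",
            ReadSimParams(coverage=2.0, error_rate=0.0, conversion_rate=1.0),
            seed=1,
        )
        seq = small_genome.sequences["chr1"]
        cg = (seq[:-1] == mio.C) & (seq[1:] == mio.G)
        for cr in reads.per_chrom:
            for j in range(0, len(cr.starts), 50):
                s = int(cr.starts[j])
                window = cg[s : s + reads.read_length - 1]
                read_c = cr.seqs[j][:-1][window]
                if cr.is_ot[j]:
                    assert (read_c == mio.C).all()

    def test_total_mapped_bases_match_coverage(self, small_genome, small_truth):
        params = ReadSimParams(coverage=10.0, read_length=80)
        reads = simulate_bisulfite_reads(small_genome, small_truth, "normal", params, seed=2)
        expect = 400_000 * 10.0
        assert abs(reads.total_bases - expect) < 0.01 * expect

    def test_unmethylated_truth_leaves_residual_c_at_conversion_failure_rate(self, small_genome):
        truth = _constant_truth(small_genome, 0.0, conversion=0.98)
        reads = simulate_bisulfite_reads(
            small_genome,
            truth,
            "normal",
            ReadSimParams(coverage=5.0, error_rate=0.0),
            seed=3,
        )
        seq = small_genome.sequences["chr1"]
        n_c = n_tot = 0
        for cr in reads.per_chrom:
            ot_rows = np.flatnonzero(cr.is_ot)
            for j in ot_rows[::5]:
                s = int(cr.starts[j])
                refc = seq[s : s + reads.read_length] == mio.C
                bases = cr.seqs[j][refc]
                n_c += int((bases == mio.C).sum())
                n_tot += int(len(bases))
        assert n_tot > 10_000
        assert n_c / n_tot == pytest.approx(0.02, abs=0.005)

    def test_read_simulation_deterministic_and_sam_stable(self, small_genome, small_truth, tmp_path):
        params = ReadSimParams(coverage=1.0)
        a = simulate_bisulfite_reads(small_genome, small_truth, "wt", params, seed=9)
        b = simulate_bisulfite_reads(small_genome, small_truth, "wt", params, seed=9)
        a.write_sam(tmp_path / "a.sam")
        b.write_sam(tmp_path / "b.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()
        c = simulate_bisulfite_reads(small_genome, small_truth, "wt", params, seed=10)
        assert not np.array_equal(a.per_chrom[0].starts, c.per_chrom[0].starts)

    def test_invalid_parameters_rejected(self, small_genome, small_truth):
        with pytest.raises(ValueError, match="coverage"):
            ReadSimParams(coverage=0)
        with pytest.raises(ValueError, match="conversion"):
            ReadSimParams(conversion_rate=0.5)
        with pytest.raises(ValueError, match="read_length"):
            simulate_bisulfite_reads(
                small_genome, small_truth, "normal", ReadSimParams(read_length=500_000), seed=1
            )


def test_external_tracks_follow_domain_plan(small_genome):
    tracks = simulate_external_tracks(small_genome, seed=4)
    lamina = tracks["lamina"]
    mid = (lamina["start"] + lamina["end"]) // 2
    in_pmd = (mid >= 50_000) & (mid < 150_000)
    assert lamina.loc[in_pmd, "value"].mean() > lamina.loc[~in_pmd, "value"].mean() + 0.5


def _constant_truth(genome, p, conversion):
    from methdomains.simulate.truth import TruthMethylome

    probs = {
        cond: {c: np.full(len(pos), p) for c, pos in genome.cpg_positions.items()}
        for cond in ("normal", "wt", "ko")
    }
    return TruthMethylome(
        cpg_positions=genome.cpg_positions,
        probs=probs,
        conversion_rates={c: conversion for c in ("normal", "wt", "ko")},
        domains=genome.domains,
    )
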