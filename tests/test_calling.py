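"""Methylation caller: trimming, counting, conversion rate, oracle parity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdomains import calling
from methdomains import io as mio
from methdomains.simulate import ReadSimParams, simulate_bisulfite_reads

from conftest import make_sam, reference_from_strings
from _bruteforce import bruteforce_conversion, bruteforce_pileup


def _codes(s: str) -> np.ndarray:
    return mio.seq_to_array(s)


class TestTrimRead:
    def test_long_high_quality_read_truncates_to_80(self):
        seq = _codes("A" * 105)
        qual = np.full(105, 40)
        out = calling.trim_read(seq, qual, start=100, is_reverse=False)
        assert out is not None
        trimmed, _, start = out
        assert len(trimmed) == 80
        assert start == 100

    def test_low_quality_tail_removed(self):
        seq = _codes("A" * 60)
        qual = np.array([40] * 55 + [20] * 5)
        trimmed, _, start = calling.trim_read(seq, qual, start=10, is_reverse=False)
        assert len(trimmed) == 55
        assert start == 10

    def test_low_quality_head_shifts_alignment_start(self):
        seq = _codes("A" * 50)
        qual = np.array([10] * 4 + [40] * 46)
        trimmed, _, start = calling.trim_read(seq, qual, start=200, is_reverse=False)
        assert len(trimmed) == 46
        assert start == 204

    def test_entirely_low_quality_read_discarded(self):
        out = calling.trim_read(_codes("A" * 40), np.full(40, 10), 0, False)
        assert out is None

    def test_reverse_read_truncates_from_left_of_reference(self):
        # the sequencing 5' end of a reverse-aligned read is its right end,
        # so the 105->80 truncation drops the leftmost 25 reference bases
        seq = _codes("A" * 105)
        qual = np.full(105, 40)
        trimmed, _, start = calling.trim_read(seq, qual, start=1000, is_reverse=True)
        assert len(trimmed) == 80
        assert start == 1025

    def test_three_prime_only_mode_keeps_low_quality_head(self):
        seq = _codes("A" * 50)
        qual = np.array([10] * 4 + [40] * 41 + [10] * 5)
        trimmed, _, start = calling.trim_read(
            seq, qual, 0, False, trim_ends="three_prime"
        )
        assert start == 0
        assert len(trimmed) == 45

    def test_missing_qualities_discards_with_warning(self):
        with pytest.warns(UserWarning, match="qualities"):
            out = calling.trim_read(_codes("ACGT"), None, 0, False)
        assert out is None


class TestCounting:
    # reference with one CpG at position 2 (+ strand C at 2, - strand C at 3)
    REF = {"chrT": "ATCGATAACATTCAGT"}

    def test_cpg_counted_per_strand(self, tmp_path):
        # 3 methylated + 1 unmethylated observation of the + strand C,
        # 1 methylated observation of the - strand (the reference G)
        reads = [
            dict(name=f"m{i}", chrom="chrT", pos0=0, seq="ATCGATAA", zs="+") for i in range(3)
        ]
        reads.append(dict(name="u0", chrom="chrT", pos0=0, seq="ATTGATAA", zs="+"))
        reads.append(dict(name="b0", chrom="chrT", pos0=0, seq="ATCGATAA", zs="-", flag=16))
        sam = make_sam(tmp_path / "t.sam", {"chrT": 16}, reads)
        calls = calling.call_methylation(
            sam, reference_from_strings(self.REF), context_filter="CG", trim=False
        )
        plus = calls[(calls["pos0"] == 2) & (calls["strand"] == "+")].iloc[0]
        assert (plus["n_meth"], plus["n_total"]) == (3, 4)
        assert plus["ratio"] == pytest.approx(0.75)
        minus = calls[(calls["pos0"] == 3) & (calls["strand"] == "-")].iloc[0]
        assert (minus["n_meth"], minus["n_total"]) == (1, 1)

    def test_strand_without_informative_reads_gets_no_call(self, tmp_path):
        reads = [dict(name="a", chrom="chrT", pos0=0, seq="ATCGATAA", zs="-", flag=16)]
        sam = make_sam(tmp_path / "t.sam", {"chrT": 16}, reads)
        calls = calling.call_methylation(
            sam, reference_from_strings(self.REF), context_filter="CG", trim=False
        )
        assert (calls["strand"] == "+").sum() == 0
        assert (calls["strand"] == "-").sum() == 1

    def test_mismatch_bases_ignored_in_counts(self, tmp_path):
        reads = [dict(name="a", chrom="chrT", pos0=0, seq="ATGGATAA", zs="+")]  # G at the C site
        sam = make_sam(tmp_path / "t.sam", {"chrT": 16}, reads)
        calls = calling.call_methylation(
            sam, reference_from_strings(self.REF), context_filter="CG", trim=False
        )
        assert len(calls[(calls["pos0"] == 2) & (calls["strand"] == "+")]) == 0

    def test_deleted_site_not_informed(self, tmp_path):
        # read with a 2-bp deletion spanning the CpG: no call at positions 2/3
        reads = [
            dict(name="d", chrom="chrT", pos0=0, seq="ATATAACA", cigar="2M2D6M", zs="+"),
        ]
        sam = make_sam(tmp_path / "t.sam", {"chrT": 16}, reads)
        calls = calling.call_methylation(
            sam, reference_from_strings(self.REF), context_filter="all", trim=False
        )
        assert 2 not in set(calls["pos0"])

    def test_pooled_strand_output_sums_dyad(self, tmp_path):
        reads = [
            dict(name="a", chrom="chrT", pos0=0, seq="ATCGATAA", zs="+"),
            dict(name="b", chrom="chrT", pos0=0, seq="ATTGATAA", zs="+"),
            dict(name="c", chrom="chrT", pos0=0, seq="ATCGATAA", zs="-", flag=16),
        ]
        sam = make_sam(tmp_path / "t.sam", {"chrT": 16}, reads)
        pooled = calling.call_methylation(
            sam, reference_from_strings(self.REF), trim=False, pool_strands=True
        )
        row = pooled[pooled["pos0"] == 2].iloc[0]
        assert (row["n_meth"], row["n_total"]) == (2, 3)


class TestConversion:
    def test_direct_formula(self):
        est = calling.ConversionEstimate(n_c_at_noncpg=2, n_bases_at_noncpg=100)
        assert est.rate == pytest.approx(0.98)
        assert calling.ConversionEstimate(0, 57).rate == 1.0
        with pytest.raises(ValueError, match="undefined"):
            _ = calling.ConversionEstimate(0, 0).rate

    def test_counts_only_noncpg_cytosines(self, tmp_path):
        # reference: CpG at 2; non-CpG C at 9; read has C at both
        ref = {"chrT": "ATCGATAACATTCAGT"}
        reads = [dict(name="a", chrom="chrT", pos0=0, seq="ATCGATAACATTCAGT", zs="+")]
        sam = make_sam(tmp_path / "t.sam", {"chrT": 16}, reads)
        est = calling.estimate_conversion(sam, reference_from_strings(ref), trim=False)
        # non-CpG top-strand Cs at 9 and 12, both read as C
        assert (est.n_c_at_noncpg, est.n_bases_at_noncpg) == (2, 2)
        assert est.rate == 0.0

    def test_simulation_recovery_within_half_percent(self, small_genome):
        from test_simulate import _constant_truth

        truth = _constant_truth(small_genome, 1.0, conversion=0.99)
        reads = simulate_bisulfite_reads(
            small_genome, truth, "normal", ReadSimParams(coverage=3.0, error_rate=0.0), seed=21
        )
        est = calling.estimate_conversion(reads, small_genome.sequences)
        assert est.n_bases_at_noncpg > 50_000
        assert est.rate == pytest.approx(0.99, abs=0.005)


def test_aggregate_mean_ratio():
    calls = pd.DataFrame({"ratio": [0.2, 0.4, 0.9], "n_total": [3, 3, 3]})
    assert calling.aggregate_mean_ratio(calls) == pytest.approx(0.5)
    ones = pd.DataFrame({"ratio": [1.0, 1.0], "n_total": [5, 1]})
    assert calling.aggregate_mean_ratio(ones) == 1.0
    with pytest.raises(ValueError, match="empty"):
        calling.aggregate_mean_ratio(pd.DataFrame({"ratio": [], "n_total": []}))


def test_count_conservation(small_genome, small_reads):
    """n_meth <= n_total everywhere, and totals add up across a partition."""
    result = calling.run_caller(small_reads, small_genome.sequences)
    calls = result.calls("CG")
    assert (calls["n_meth"] <= calls["n_total"]).all()
    mid = 200_000
    left = calls[calls["pos0"] < mid]["n_total"].sum()
    right = calls[calls["pos0"] >= mid]["n_total"].sum()
    assert left + right == calls["n_total"].sum()


def test_strand_symmetry_on_symmetric_truth(small_genome, small_calls):
    """Both strands of a dyad share one truth, so ratio distributions match."""
    plus = small_calls[small_calls["strand"] == "+"]["ratio"]
    minus = small_calls[small_calls["strand"] == "-"]["ratio"]
    stat = sps.mannwhitneyu(plus, minus)
    assert stat.pvalue > 0.01


def test_sam_and_memory_paths_agree(small_genome, small_reads, tmp_path):
    """Reading back the written SAM reproduces the in-memory calls exactly."""
    sam = tmp_path / "reads.sam"
    small_reads.write_sam(sam)
    from_mem = calling.call_methylation(small_reads, small_genome.sequences)
    from_sam = calling.call_methylation(str(sam), small_genome.sequences)
    pd.testing.assert_frame_equal(from_mem, from_sam)


def test_oracle_equivalence_small_fixture(small_genome, small_truth, tmp_path):
    """Vectorised caller matches the dict-based brute-force pileup exactly."""
    reads = simulate_bisulfite_reads(
        small_genome, small_truth, "wt", ReadSimParams(coverage=1.0), seed=33
    )
    sam = tmp_path / "wt.sam"
    reads.write_sam(sam)
    ref_str = {c: mio.array_to_seq(s) for c, s in small_genome.sequences.items()}
    oracle = bruteforce_pileup(str(sam), ref_str)
    result = calling.run_caller(str(sam), small_genome.sequences)
    calls = result.calls("all")
    ours = {
        (r.chrom, int(r.pos0), r.strand): (int(r.n_meth), int(r.n_total))
        for r in calls.itertuples()
    }
    assert ours == oracle
    n_c, n_all = bruteforce_conversion(str(sam), ref_str)
    est = result.conversion()
    assert (est.n_c_at_noncpg, est.n_bases_at_noncpg) == (n_c, n_all)
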