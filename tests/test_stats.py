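"""State classification, binned distributions and feature summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methdomains import stats
from methdomains.simulate import GenePlan, GenomeSpec, ReadSimParams, assign_truth_methylome, build_genome, simulate_bisulfite_reads
from methdomains import calling


def _calls_frame(positions, ratios, chrom="chr1", strand="+", context="CG", n_total=10):
    positions = np.asarray(positions)
    ratios = np.asarray(ratios, dtype=float)
    n_tot = np.full(len(positions), n_total)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": positions,
            "strand": strand,
            "context": context,
            "n_meth": np.round(ratios * n_tot).astype(int),
            "n_total": n_tot,
            "ratio": ratios,
        }
    )


class TestClassify:
    @pytest.mark.parametrize(
        "ratio,state",
        [
            (0.96, "fully_methylated"),
            (0.04, "unmethylated"),
            (0.05, "partial"),
            (0.95, "partial"),
            (0.5, "partial"),
            (0.0, "unmethylated"),
            (1.0, "fully_methylated"),
        ],
    )
    def test_threshold_rule(self, ratio, state):
        assert stats.classify_site(ratio) == state

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.classify_site(1.2)
        with pytest.raises(ValueError):
            stats.classify_ratios(np.array([0.5, -0.1]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_vectorised_matches_scalar(self, ratios):
        codes = stats.classify_ratios(np.array(ratios))
        assert [stats.STATES[c] for c in codes] == [stats.classify_site(r) for r in ratios]


class TestBinDistribution:
    def test_toy_fractions(self):
        calls = _calls_frame(range(5), [0, 0, 1, 1, 0.5])
        bins = stats.bin_distribution(calls)
        assert bins.fractions == {
            "unmethylated": 0.4,
            "partial": 0.2,
            "fully_methylated": 0.4,
        }

    def test_all_fully_methylated(self):
        bins = stats.bin_distribution(_calls_frame(range(4), [1.0] * 4))
        assert bins.fractions["fully_methylated"] == 1.0
        assert bins.hist_counts.sum() == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no covered sites"):
            stats.bin_distribution(_calls_frame([], []))

    def test_fractions_consistent_with_sitewise_classification(self):
        rng = np.random.default_rng(5)
        ratios = rng.random(1000)
        calls = _calls_frame(np.arange(1000) * 3, ratios)
        bins = stats.bin_distribution(calls)
        codes = stats.classify_ratios(ratios)
        for k, state in enumerate(stats.STATES):
            assert bins.counts[state] == int((codes == k).sum())

    def test_uncovered_sites_excluded(self):
        calls = _calls_frame(range(4), [1.0, 1.0, 0.0, 0.0])
        calls.loc[2:, "n_total"] = 0
        bins = stats.bin_distribution(calls)
        assert bins.n_sites == 2
        assert bins.fractions["fully_methylated"] == 1.0


class TestFeatureMethylation:
    def test_simple_feature_mean(self):
        calls = _calls_frame([100, 150, 200], [0.1, 0.1, 0.1], n_total=3)
        features = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [250], "name": ["p1"]})
        s = stats.feature_methylation(calls, features, min_cpgs=3, min_coverage=3)
        assert s.mean == pytest.approx(0.1)
        assert s.n_features == 1

    def test_min_cpg_filter_excludes_sparse_promoter(self):
        calls = _calls_frame([100, 150], [0.2, 0.4], n_total=3)
        features = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [250], "name": ["p1"]})
        s = stats.feature_methylation(calls, features, min_cpgs=3, min_coverage=3)
        assert s.n_features == 0
        assert s.n_excluded == 1
        assert np.isnan(s.mean)

    def test_min_coverage_monotonicity(self):
        rng = np.random.default_rng(9)
        calls = _calls_frame(np.arange(50) * 10, rng.random(50))
        calls["n_total"] = rng.integers(1, 12, 50)
        features = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500], "name": ["f"]})
        counts = [
            stats.feature_methylation(calls, features, 1, cov).per_feature["n_cpgs"].iloc[0]
            for cov in (1, 3, 5, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_degenerate_interval_rejected(self):
        calls = _calls_frame([1], [0.5])
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10], "name": ["x"]})
        with pytest.raises(ValueError, match="degenerate"):
            stats.feature_methylation(calls, bad)


class TestGenicPartition:
    def test_promoter_is_1kb_upstream_on_coding_strand(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 30_000],
                "end": [15_000, 35_000],
                "name": ["gp", "gm"],
                "score": [0, 0],
                "strand": ["+", "-"],
            }
        )
        proms = stats.promoter_intervals(genes, {"chr1": 100_000})
        p_plus = proms.iloc[0]
        assert (p_plus["start"], p_plus["end"]) == (9_000, 10_000)
        p_minus = proms.iloc[1]
        assert (p_minus["start"], p_minus["end"]) == (35_000, 36_000)

    def test_missing_strand_rejected(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "name": ["g"], "score": [0], "strand": ["."]}
        )
        with pytest.raises(ValueError, match="strand"):
            stats.promoter_intervals(genes, {"chr1": 100})

    def test_partition_recovers_planted_means_exactly(self):
        # sites planted region by region; priority promoter > exon > intron
        genes = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [10_000],
                "end": [16_000],
                "name": ["g"],
                "score": [0],
                "strand": ["+"],
            }
        )
        subregions = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [10_000, 10_500, 12_500, 14_500],
                "end": [10_500, 12_500, 14_500, 16_000],
                "name": ["g:utr5", "g:exon", "g:intron", "g:utr3"],
                "score": [0] * 4,
                "strand": ["+"] * 4,
            }
        )
        regions = {
            "promoter": (9_200, 9_800, 0.10),
            "utr5": (10_050, 10_450, 0.20),
            "exon": (10_600, 12_400, 0.80),
            "intron": (12_600, 14_400, 0.70),
            "utr3": (14_600, 15_900, 0.60),
            "intergenic": (50_000, 60_000, 0.55),
        }
        frames = []
        for _, (lo, hi, value) in regions.items():
            pos = np.arange(lo, hi, 100)
            frames.append(_calls_frame(pos, np.full(len(pos), value)))
        calls = pd.concat(frames, ignore_index=True)
        part = stats.partition_genic(calls, genes, subregions, {"chr1": 100_000})
        for cat in ("promoter", "utr5", "exon", "intron", "utr3", "intergenic"):
            assert part[cat].mean == pytest.approx(regions[cat][2]), cat
        body = part["gene_body"]
        sub_sites = [part[c] for c in ("utr5", "exon", "intron", "utr3")]
        pooled = sum(s.mean * s.n_sites for s in sub_sites) / sum(s.n_sites for s in sub_sites)
        assert body.mean == pytest.approx(pooled)

    def test_gene_covering_everything_leaves_no_intergenic(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "name": ["g"], "score": [0], "strand": ["+"]}
        )
        subregions = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "name": ["g:exon"], "score": [0], "strand": ["+"]}
        )
        calls = _calls_frame(np.arange(0, 1000, 50), np.full(20, 0.5))
        part = stats.partition_genic(calls, genes, subregions, {"chr1": 1000})
        assert part["intergenic"].n_sites == 0
        assert np.isnan(part["intergenic"].mean)

    def test_partition_counts_every_covered_site_once(self, small_genome, small_calls):
        part = stats.partition_genic(
            small_calls, small_genome.genes, small_genome.subregions, small_genome.chrom_lengths
        )
        n_covered = int((small_calls["n_total"] > 0).sum())
        total = (
            part["promoter"].n_sites + part["gene_body"].n_sites + part["intergenic"].n_sites
        )
        assert total == n_covered


def test_state_fraction_recovery_from_reads():
    """Planted mixture weights are recovered from simulated reads."""
    spec = GenomeSpec(
        chrom_lengths={"chr1": 1_500_000},
        state_weights=(0.17, 0.35, 0.48),
        genes=GenePlan(n_genes=0),
        seed=17,
    )
    genome = build_genome(spec)
    truth = assign_truth_methylome(genome, spec, conversion_rates=0.99)
    # reads simulated at the 80-bp analysis length with uniform qualities so
    # the stated coverage is delivered in usable (post-trim) bases
    reads = simulate_bisulfite_reads(
        genome, truth, "normal", ReadSimParams(coverage=15.0, read_length=80, low_tail=0), seed=17
    )
    calls = calling.call_methylation(reads, genome.sequences)
    bins = stats.bin_distribution(calls)
    for state, weight in zip(stats.STATES, spec.state_weights):
        assert bins.fractions[state] == pytest.approx(weight, abs=0.02), state
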