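"""Synthetic external tracks and expression tables.

The correlation analyses downstream need a lamina-association profile
(high inside PMD-like heterochromatin), an H3K4me1 profile (high inside
DPD-like active chromatin), a normal-tissue expression track, and a
knockout-vs-wildtype fold-change table in which deregulated genes sit in
DPDs.  These are generated directly from the domain plan with additive
Gaussian noise — they emulate the *correlation structure* of the real
tracks, not their assay-specific signal distributions.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from methdomains.simulate.genome import SUBREGIONS, Genome


def _bin_frame(chrom_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _domain_indicator(bins: pd.DataFrame, domains: pd.DataFrame, label: str) -> np.ndarray:
    ind = np.zeros(len(bins), dtype=bool)
    doms = domains[domains["name"] == label]
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    for _, d in doms.iterrows():
        ind |= (bins["chrom"].to_numpy() == d["chrom"]) & (mid >= d["start"]) & (mid < d["end"])
    return ind


def simulate_external_tracks(
    genome: Genome,
    bin_size: int = 20_000,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> Dict[str, pd.DataFrame]:
    """bedGraph-style frames for lamina, H3K4me1 and normal expression.

    lamina ~ 1 inside PMDs, 0 elsewhere; h3k4me1 and expression ~ 1 inside
    DPDs, lower elsewhere and lowest in PMDs; all plus N(0, noise_sd).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(71,)))
    bins = _bin_frame(genome.chrom_lengths, bin_size)
    in_pmd = _domain_indicator(bins, genome.domains, "PMD")
    in_dpd = _domain_indicator(bins, genome.domains, "DPD")
    n = len(bins)
    tracks = {}
    lamina = np.where(in_pmd, 1.0, 0.0) + rng.normal(0, noise_sd, n)
    h3k4me1 = np.where(in_dpd, 1.0, np.where(in_pmd, 0.0, 0.4)) + rng.normal(0, noise_sd, n)
    expression = np.where(in_dpd, 1.0, np.where(in_pmd, 0.1, 0.5)) + rng.normal(0, noise_sd, n)
    for name, values in (("lamina", lamina), ("h3k4me1", h3k4me1), ("expression", expression)):
        df = bins.copy()
        df["value"] = values
        tracks[name] = df
    return tracks


def simulate_expression_table(
    genome: Genome,
    seed: int = 0,
    de_prob_in_dpd: float = 0.9,
    up_down_ratio: float = 0.5,
    null_log2_sd: float = 0.2,
) -> pd.DataFrame:
    """Fold-change table (gene, fold_change), knockout vs wildtype.

    Genes inside DPD-like domains are deregulated with probability
    ``de_prob_in_dpd`` (log2 fold magnitude 1.1 + Exp(0.5), i.e. always
    beyond the 2-fold threshold, direction up with probability
    ``up_down_ratio``); all other genes get null log2 fold N(0, 0.2).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(72,)))
    genes = genome.genes
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    in_dpd = np.zeros(len(genes), dtype=bool)
    for _, d in genome.domains[genome.domains["name"] == "DPD"].iterrows():
        in_dpd |= (genes["chrom"].to_numpy() == d["chrom"]) & (mid >= d["start"]) & (mid < d["end"])
    log2fc = rng.normal(0.0, null_log2_sd, len(genes))
    de = in_dpd & (rng.random(len(genes)) < de_prob_in_dpd)
    n_de = int(de.sum())
    magnitude = 1.1 + rng.exponential(0.5, n_de)
    sign = np.where(rng.random(n_de) < up_down_ratio, 1.0, -1.0)
    log2fc[de] = sign * magnitude
    return pd.DataFrame({"gene": genes["name"], "fold_change": 2.0 ** log2fc})


def simulate_subregion_means(
    n_genes_up: int = 100,
    n_genes_down: int = 100,
    shift: Mapping[Tuple[str, str], float] | None = None,
    base_mean: float = 0.7,
    gene_sd: float = 0.1,
    seed: int = 0,
) -> Dict[str, pd.DataFrame]:
    """Per-gene subregion methylation means for wt and ko tumors.

    Monte-Carlo generator for calibrating the subregion t-test: per gene
    set ("up"/"down") and subregion, per-gene means are drawn around
    ``base_mean`` with between-gene spread ``gene_sd`` (clipped to [0,1]),
    independently per condition.  ``shift`` maps (gene_set, subregion) ->
    additive change applied to the ko condition only, e.g.
    ``{("up", "utr5"): -0.2}`` plants Dnmt3a-dependent 5'-UTR
    hypomethylation of upregulated genes.
    """
    shift = dict(shift or {})
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(73,)))
    out: Dict[str, pd.DataFrame] = {}
    for cond in ("wt", "ko"):
        rows = []
        for gene_set, n in (("up", n_genes_up), ("down", n_genes_down)):
            for sub in SUBREGIONS:
                mu = base_mean
                if cond == "ko":
                    mu += shift.get((gene_set, sub), 0.0)
                vals = np.clip(rng.normal(mu, gene_sd, n), 0.0, 1.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene": [f"{gene_set}{i:04d}" for i in range(n)],
                            "gene_set": gene_set,
                            "subregion": sub,
                            "mean_ratio": vals,
                        }
                    )
                )
        out[cond] = pd.concat(rows, ignore_index=True)
    return out
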