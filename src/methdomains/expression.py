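"""Association of deregulated genes with domain-level methylation loss.

Genes with a greater-than-2-fold expression change between
Dnmt3a-knockout and Dnmt3a-wildtype tumors are selected from a fold-change
table, mapped onto the 100-kb differential methylation track (window
containing the gene midpoint by default), and their gene-body subregions
(5'-UTR, exon, intron, 3'-UTR) are tested for differential methylation
between the two tumor genotypes with an unpaired Welch t-test at
alpha = 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SUBREGIONS = ("utr5", "exon", "intron", "utr3")
FOLD_THRESHOLD = 2.0
ALPHA = 0.01


@dataclass
class DeGeneSets:
    """Up/down/unchanged gene sets at a fold-change threshold."""

    up: pd.DataFrame
    down: pd.DataFrame
    unchanged: pd.DataFrame
    threshold: float
    n_rejected: int = 0

    @property
    def counts(self) -> Dict[str, int]:
        return {"up": len(self.up), "down": len(self.down), "unchanged": len(self.unchanged)}


def select_de_genes(table: pd.DataFrame, fold_threshold: float = FOLD_THRESHOLD) -> DeGeneSets:
    """Split a (gene, fold_change) table into up / down / unchanged sets.

    up: fold > threshold; down: fold < 1/threshold (linear scale, strict);
    rows with non-positive fold change are rejected and counted.
    """
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must be > 1")
    df = table.copy()
    bad = ~(df["fold_change"] > 0)
    if bad.any():
        logger.warning("rejected %d rows with non-positive fold change", int(bad.sum()))
    df = df[~bad]
    up = df[df["fold_change"] > fold_threshold]
    down = df[df["fold_change"] < 1.0 / fold_threshold]
    unchanged = df[
        (df["fold_change"] <= fold_threshold) & (df["fold_change"] >= 1.0 / fold_threshold)
    ]
    return DeGeneSets(
        up=up.reset_index(drop=True),
        down=down.reset_index(drop=True),
        unchanged=unchanged.reset_index(drop=True),
        threshold=fold_threshold,
        n_rejected=int(bad.sum()),
    )


def gene_window_delta(
    genes: pd.DataFrame,
    diff_track,
    assignment: str = "midpoint",
) -> Tuple[pd.DataFrame, float]:
    """Per-gene methylation delta from the differential window track.

    ``genes`` needs chrom/start/end/name.  With ``assignment="midpoint"``
    each gene takes the delta of the window containing its midpoint; with
    ``"overlap"`` it takes the span-weighted mean delta of the windows it
    overlaps.  Returns the per-gene frame (delta, flagged) and the fraction
    of genes lying in flagged (hypomethylated) windows; genes falling
    outside the track or in incomparable windows are excluded and counted.
    """
    frame = diff_track.frame
    w = diff_track.w
    rows = []
    n_outside = 0
    by_chrom = {
        str(c): sub.reset_index(drop=True) for c, sub in frame.groupby("chrom", sort=False)
    }
    for _, g in genes.iterrows():
        chrom = str(g["chrom"])
        sub = by_chrom.get(chrom)
        if sub is None:
            n_outside += 1
            continue
        if assignment == "midpoint":
            mid = (int(g["start"]) + int(g["end"])) // 2
            wi = mid // w
            if wi >= len(sub) or not sub.loc[wi, "comparable"]:
                n_outside += 1
                continue
            delta = float(sub.loc[wi, "delta"])
            flagged = bool(sub.loc[wi, "flagged"])
        elif assignment == "overlap":
            first, last = int(g["start"]) // w, (int(g["end"]) - 1) // w
            weights, deltas, flags = [], [], []
            for wi in range(first, min(last + 1, len(sub))):
                if not sub.loc[wi, "comparable"]:
                    continue
                lo = max(int(g["start"]), wi * w)
                hi = min(int(g["end"]), (wi + 1) * w)
                weights.append(hi - lo)
                deltas.append(float(sub.loc[wi, "delta"]))
                flags.append(bool(sub.loc[wi, "flagged"]))
            if not weights:
                n_outside += 1
                continue
            delta = float(np.average(deltas, weights=weights))
            flagged = any(flags)
        else:
            raise ValueError("assignment must be 'midpoint' or 'overlap'")
        rows.append({"gene": g["name"], "chrom": chrom, "delta": delta, "flagged": flagged})
    out = pd.DataFrame(rows, columns=["gene", "chrom", "delta", "flagged"])
    out.attrs["n_outside"] = n_outside
    fraction = float(out["flagged"].mean()) if len(out) else float("nan")
    return out, fraction


def gene_subregion_means(
    calls: pd.DataFrame,
    subregions: pd.DataFrame,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Per-gene, per-subregion mean methylation from a call table.

    ``subregions`` is the BED with name "<gene>:<kind>"; all records of the
    same (gene, kind) pool their covered CG sites.  Genes/kinds with no
    covered site are absent from the result.
    """
    df = calls[(calls["context"] == "CG") & (calls["n_total"] >= max(min_coverage, 1))]
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos0")
        pos = sub["pos0"].to_numpy()
        ratios = sub["ratio"].to_numpy()
        feats = subregions[subregions["chrom"] == chrom]
        for _, feat in feats.iterrows():
            lo, hi = np.searchsorted(pos, [int(feat["start"]), int(feat["end"])])
            if hi == lo:
                continue
            gene, _, kind = str(feat["name"]).rpartition(":")
            rows.append(
                {
                    "gene": gene,
                    "subregion": kind,
                    "sum": float(ratios[lo:hi].sum()),
                    "n": int(hi - lo),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["gene", "subregion", "mean_ratio", "n_cpgs"])
    agg = (
        pd.DataFrame(rows)
        .groupby(["gene", "subregion"], as_index=False)
        .agg(sum=("sum", "sum"), n=("n", "sum"))
    )
    agg["mean_ratio"] = agg["sum"] / agg["n"]
    return agg.rename(columns={"n": "n_cpgs"})[["gene", "subregion", "mean_ratio", "n_cpgs"]]


def subregion_differential_test(
    gene_sets: Mapping[str, pd.Series | list],
    means_wt: pd.DataFrame,
    means_ko: pd.DataFrame,
    alpha: float = ALPHA,
    paired: bool = False,
) -> pd.DataFrame:
    """Welch t-test of wt vs ko subregion methylation per gene set.

    ``gene_sets`` maps a set label (e.g. "up"/"down") to gene identifiers;
    ``means_wt``/``means_ko`` are frames with gene, subregion, mean_ratio
    (as from :func:`gene_subregion_means`).  Cells with fewer than two
    genes in either condition are skipped (tested = False).  Swapping the
    two conditions flips every t statistic and keeps p-values.
    """
    rows = []
    for set_label, genes in gene_sets.items():
        genes = set(map(str, list(genes)))
        for sub in SUBREGIONS:
            wt = means_wt[(means_wt["subregion"] == sub) & means_wt["gene"].isin(genes)]
            ko = means_ko[(means_ko["subregion"] == sub) & means_ko["gene"].isin(genes)]
            row = {
                "gene_set": set_label,
                "subregion": sub,
                "n_wt": len(wt),
                "n_ko": len(ko),
                "mean_wt": float(wt["mean_ratio"].mean()) if len(wt) else np.nan,
                "mean_ko": float(ko["mean_ratio"].mean()) if len(ko) else np.nan,
            }
            if len(wt) < 2 or len(ko) < 2:
                row.update(t=np.nan, p=np.nan, significant=False, tested=False)
            else:
                if paired:
                    both = wt.merge(ko, on="gene", suffixes=("_wt", "_ko"))
                    t, p = sps.ttest_rel(both["mean_ratio_wt"], both["mean_ratio_ko"])
                else:
                    t, p = sps.ttest_ind(
                        wt["mean_ratio"], ko["mean_ratio"], equal_var=False
                    )
                row.update(t=float(t), p=float(p), significant=bool(p < alpha), tested=True)
            rows.append(row)
    return pd.DataFrame(rows)
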