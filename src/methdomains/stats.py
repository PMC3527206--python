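"""Methylation-state classification and feature-level summaries.

Sites are classified by their methylation ratio into unmethylated
(< 0.05), fully methylated (> 0.95) and partially methylated (everything
in between, boundaries inclusive).  Feature-level summaries average
per-site ratios within annotated intervals (promoters, CpG-island
promoters, repeat copies, gene-body subregions) subject to minimum-CpG and
minimum-coverage filters, and the genic partition splits the genome into
promoter / gene body / intergenic space with a fixed overlap priority so
no CpG is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

T_LOW, T_HIGH = 0.05, 0.95
STATES = ("unmethylated", "partial", "fully_methylated")

# partition labels, in ascending paint order = ascending priority
_PARTITION_PAINT = ("intergenic", "intron", "utr3", "utr5", "exon", "promoter")
_SUBREGION_KINDS = ("utr5", "exon", "intron", "utr3")


def classify_site(ratio: float, t_low: float = T_LOW, t_high: float = T_HIGH) -> str:
    """Classify one methylation ratio into a three-state label."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"methylation ratio {ratio} outside [0, 1]")
    if ratio < t_low:
        return "unmethylated"
    if ratio > t_high:
        return "fully_methylated"
    return "partial"


def classify_ratios(
    ratios: np.ndarray, t_low: float = T_LOW, t_high: float = T_HIGH
) -> np.ndarray:
    """Vectorised classification; returns int codes 0/1/2 for the STATES order."""
    r = np.asarray(ratios, dtype=float)
    if ((r < 0) | (r > 1)).any():
        raise ValueError("methylation ratios outside [0, 1]")
    return np.where(r < t_low, 0, np.where(r > t_high, 2, 1)).astype(np.int8)


@dataclass
class MethylationStateBins:
    """Three-state composition plus a fine histogram of a ratio set."""

    t_low: float
    t_high: float
    counts: Dict[str, int]
    n_sites: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    @property
    def fractions(self) -> Dict[str, float]:
        return {k: v / self.n_sites for k, v in self.counts.items()}

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions)


def bin_distribution(
    calls: pd.DataFrame,
    context: Optional[str] = "CG",
    bin_width: float = 0.05,
    t_low: float = T_LOW,
    t_high: float = T_HIGH,
) -> MethylationStateBins:
    """Distribution of per-site ratios for one context (covered sites only)."""
    df = calls
    if context is not None and context != "all":
        df = df[df["context"] == context]
    df = df[df["n_total"] > 0]
    if len(df) == 0:
        raise ValueError("no covered sites for the requested context")
    ratios = df["ratio"].to_numpy()
    codes = classify_ratios(ratios, t_low, t_high)
    counts = {state: int((codes == k).sum()) for k, state in enumerate(STATES)}
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    hist, edges = np.histogram(ratios, bins=edges)
    return MethylationStateBins(
        t_low=t_low,
        t_high=t_high,
        counts=counts,
        n_sites=int(len(ratios)),
        hist_edges=edges,
        hist_counts=hist,
    )


@dataclass
class FeatureMethylationSummary:
    """Average methylation of one annotation category."""

    category: str
    mean: float  # NaN when no feature passes the filters
    n_features: int
    n_excluded: int
    min_cpgs: int
    min_coverage: int
    per_feature: Optional[pd.DataFrame] = field(default=None, repr=False)
    n_sites: Optional[int] = None


def _sites_by_chrom(calls: pd.DataFrame, min_coverage: int) -> Dict[str, tuple]:
    """Sorted (positions, ratios) per chromosome for covered CG sites."""
    df = calls[(calls["context"] == "CG") & (calls["n_total"] >= max(min_coverage, 1))]
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos0")
        out[str(chrom)] = (sub["pos0"].to_numpy(), sub["ratio"].to_numpy())
    return out


def feature_methylation(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    min_cpgs: int = 3,
    min_coverage: int = 3,
    category: str = "feature",
) -> FeatureMethylationSummary:
    """Per-feature mean methylation and the category-level average.

    A feature qualifies when it contains >= ``min_cpgs`` CG-context sites
    with >= ``min_coverage`` informative reads; its mean is the average of
    per-site ratios over those sites (both strands pooled).  The category
    average is the unweighted mean over qualifying features.
    """
    sites = _sites_by_chrom(calls, min_coverage)
    rows = []
    for _, feat in features.iterrows():
        chrom = str(feat["chrom"])
        start, end = int(feat["start"]), int(feat["end"])
        if end <= start:
            raise ValueError(f"degenerate feature interval [{start}, {end}) on {chrom}")
        if chrom not in sites:
            n, mean = 0, np.nan
        else:
            pos, ratios = sites[chrom]
            lo, hi = np.searchsorted(pos, [start, end])
            n = int(hi - lo)
            mean = float(ratios[lo:hi].mean()) if n else np.nan
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": feat.get("name", "."),
                "n_cpgs": n,
                "mean_ratio": mean,
                "included": n >= min_cpgs,
            }
        )
    per_feature = pd.DataFrame(rows)
    included = per_feature[per_feature["included"]]
    return FeatureMethylationSummary(
        category=category,
        mean=float(included["mean_ratio"].mean()) if len(included) else float("nan"),
        n_features=int(len(included)),
        n_excluded=int(len(per_feature) - len(included)),
        min_cpgs=min_cpgs,
        min_coverage=min_coverage,
        per_feature=per_feature,
    )


def promoter_intervals(genes: pd.DataFrame, chrom_lengths: Mapping[str, int], size: int = 1000) -> pd.DataFrame:
    """Promoters as the 1 kb upstream of each TSS on the coding strand.

    For a + strand gene [s, e) the promoter is [s - size, s); for a -
    strand gene it is [e, e + size), clipped to the chromosome.
    """
    rows = []
    for _, g in genes.iterrows():
        strand = g["strand"]
        if strand not in ("+", "-"):
            raise ValueError(f"gene {g.get('name')} lacks a strand")
        if strand == "+":
            start, end = int(g["start"]) - size, int(g["start"])
        else:
            start, end = int(g["end"]), int(g["end"]) + size
        start = max(start, 0)
        end = min(end, chrom_lengths[str(g["chrom"])])
        if end > start:
            rows.append(
                {
                    "chrom": g["chrom"],
                    "start": start,
                    "end": end,
                    "name": f"promoter_{g.get('name', '.')}",
                    "score": 0,
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def partition_genic(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    subregions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    promoter_size: int = 1000,
    min_coverage: int = 1,
) -> Dict[str, FeatureMethylationSummary]:
    """Genome partition averages: promoter / gene body / intergenic, plus
    gene-body subregions (5'-UTR, exon, intron, 3'-UTR).

    The partition is painted onto per-bp label arrays in ascending priority
    (promoter > exon > 5'-UTR > 3'-UTR > intron > intergenic), so the
    categories cover the genome exactly once and no CpG is double counted.
    Averages are over per-site ratios of covered CG sites.
    """
    label_of = {name: k for k, name in enumerate(_PARTITION_PAINT)}
    labels = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_lengths.items()}

    def paint(df: pd.DataFrame, kind_from_name: bool, kind: Optional[str] = None) -> None:
        for _, row in df.iterrows():
            k = row["name"].rsplit(":", 1)[-1] if kind_from_name else kind
            if k not in label_of:
                continue
            arr = labels[str(row["chrom"])]
            s, e = max(int(row["start"]), 0), min(int(row["end"]), len(arr))
            code = label_of[k]
            seg = arr[s:e]
            np.maximum(seg, code, out=seg)

    paint(subregions, kind_from_name=True)
    promoters = promoter_intervals(genes, chrom_lengths, promoter_size)
    paint(promoters, kind_from_name=False, kind="promoter")

    sites = _sites_by_chrom(calls, min_coverage)
    sums = {name: 0.0 for name in _PARTITION_PAINT}
    ns = {name: 0 for name in _PARTITION_PAINT}
    for chrom, (pos, ratios) in sites.items():
        if chrom not in labels:
            continue
        site_labels = labels[chrom][pos]
        for name, code in label_of.items():
            mask = site_labels == code
            sums[name] += float(ratios[mask].sum())
            ns[name] += int(mask.sum())

    def summary(cat: str, names: Sequence[str]) -> FeatureMethylationSummary:
        total = sum(sums[n] for n in names)
        count = sum(ns[n] for n in names)
        return FeatureMethylationSummary(
            category=cat,
            mean=total / count if count else float("nan"),
            n_features=len(names),
            n_excluded=0,
            min_cpgs=0,
            min_coverage=min_coverage,
            n_sites=count,
        )

    out = {
        "promoter": summary("promoter", ["promoter"]),
        "gene_body": summary("gene_body", list(_SUBREGION_KINDS)),
        "intergenic": summary("intergenic", ["intergenic"]),
    }
    for kind in _SUBREGION_KINDS:
        out[kind] = summary(kind, [kind])
    return out
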