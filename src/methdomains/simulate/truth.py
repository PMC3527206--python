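"""Ground-truth methylome assignment.

Every CpG dyad receives a true methylation probability per condition.  The
baseline draw is a three-component Beta mixture (spikes near 0 and 1 plus a
broad intermediate component) whose weights reproduce the bimodal
unmethylated / partial / fully-methylated composition of normal tissue.
Planted domains then apply condition-specific additive shifts: PMD-like
domains lose methylation in both tumor conditions, DPD-like domains only in
the knockout — by construction ko <= wt inside DPDs and wt <= normal inside
PMDs.  Both strands of a dyad share one probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from methdomains.simulate.genome import CONDITIONS, Genome, GenomeSpec

logger = logging.getLogger(__name__)


@dataclass
class TruthMethylome:
    """Per-condition true CpG methylation probabilities plus planted domains."""

    cpg_positions: Dict[str, np.ndarray]  # chrom -> dyad start (C on + strand)
    probs: Dict[str, Dict[str, np.ndarray]]  # condition -> chrom -> p (float64)
    conversion_rates: Mapping[str, float]
    domains: pd.DataFrame
    noncpg_level: float = 0.0
    n_clipped: Dict[str, int] = field(default_factory=dict)

    @property
    def conditions(self) -> tuple:
        return tuple(self.probs)

    @property
    def n_entries(self) -> int:
        """Number of per-strand truth entries (two per CpG dyad)."""
        return 2 * sum(len(p) for p in self.cpg_positions.values())

    def mean_in(self, chrom: str, start: int, end: int, condition: str) -> float:
        pos = self.cpg_positions[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        if hi == lo:
            return float("nan")
        return float(self.probs[condition][chrom][lo:hi].mean())

    def mean_overall(self, condition: str) -> float:
        total = sum(p.sum() for p in self.probs[condition].values())
        n = sum(len(p) for p in self.probs[condition].values())
        return float(total / n)

    def to_frame(self) -> pd.DataFrame:
        """Per-strand rows: (chrom, pos0, strand, p_<condition>...).

        The + strand row sits at the dyad start (the C), the - strand row at
        dyad start + 1 (the G, i.e. the C of the bottom strand).
        """
        frames = []
        conds = list(self.probs)
        for chrom, pos in self.cpg_positions.items():
            for strand, offset in (("+", 0), ("-", 1)):
                d = {"chrom": chrom, "pos0": pos + offset, "strand": strand}
                for cond in conds:
                    d[f"p_{cond}"] = self.probs[cond][chrom]
                frames.append(pd.DataFrame(d))
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["chrom", "pos0"], ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        for col in df.columns:
            if col.startswith("p_"):
                df[col] = df[col].map(lambda v: "%.6g" % v)
        df.to_csv(path, sep="\t", index=False)


def assign_truth_methylome(
    genome: Genome,
    spec: GenomeSpec | None = None,
    conversion_rates: Mapping[str, float] | float = 0.99,
) -> TruthMethylome:
    """Draw per-CpG truth probabilities for every condition.

    Deterministic given ``spec.seed``.  Overrides are applied in the order
    base mixture -> domain-specific mixture -> repeat families -> CpG
    islands, then per-condition domain shifts (clipped to [0, 1]; clip
    counts are logged and recorded).
    """
    spec = spec or genome.spec
    if isinstance(conversion_rates, (int, float)):
        conversion_rates = {c: float(conversion_rates) for c in CONDITIONS}
    for cond, rate in conversion_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"conversion rate for {cond} outside [0,1]")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    comps = spec.beta_components
    probs: Dict[str, Dict[str, np.ndarray]] = {c: {} for c in CONDITIONS}
    n_clipped: Dict[str, int] = {c: 0 for c in CONDITIONS}

    for chrom, pos in genome.cpg_positions.items():
        n = len(pos)
        base = _mixture_draw(rng, n, spec.state_weights, comps)

        for dom in spec.domains_on(chrom, labels=("PMD", "DPD", "neutral")):
            weights = dom.weights
            if weights is None and dom.label in ("PMD", "DPD"):
                weights = spec.domain_state_weights
            if weights is None:
                continue
            lo, hi = np.searchsorted(pos, [dom.start, dom.end])
            if hi > lo:
                base[lo:hi] = _mixture_draw(rng, hi - lo, weights, comps)

        # repeat families: per-condition Beta around the family mean, driven
        # by one shared uniform so equal parameters give identical values
        rep_latent: Dict[int, np.ndarray] = {}
        rep_rows = genome.repeats[genome.repeats["chrom"] == chrom]
        for ridx, row in rep_rows.iterrows():
            lo, hi = np.searchsorted(pos, [row["start"], row["end"]])
            if hi > lo:
                rep_latent[ridx] = rng.random(hi - lo)

        cgi_rows = genome.cgi[genome.cgi["chrom"] == chrom] if len(genome.cgi) else genome.cgi
        cgi_draws: Dict[int, np.ndarray] = {}
        for cidx, row in cgi_rows.iterrows():
            lo, hi = np.searchsorted(pos, [row["start"], row["end"]])
            if hi > lo:
                a, b = comps[0]
                cgi_draws[cidx] = rng.beta(a, b, size=hi - lo)

        rep_plans = {p.family: p for p in spec.repeats}
        conc = 50.0  # concentration of per-copy repeat methylation
        for cond in CONDITIONS:
            p = base.copy()
            for ridx, u in rep_latent.items():
                row = rep_rows.loc[ridx]
                m = rep_plans[row["name"]].meth.get(cond)
                if m is None:
                    continue
                m = min(max(m, 1e-6), 1 - 1e-6)
                lo, hi = np.searchsorted(pos, [row["start"], row["end"]])
                p[lo:hi] = stats.beta.ppf(u, conc * m, conc * (1 - m))
            for cidx, draw in cgi_draws.items():
                row = cgi_rows.loc[cidx]
                lo, hi = np.searchsorted(pos, [row["start"], row["end"]])
                p[lo:hi] = draw
            for dom in spec.domains_on(chrom, labels=("PMD", "DPD", "neutral")):
                shift = dom.shift.get(cond, 0.0)
                if shift == 0.0:
                    continue
                lo, hi = np.searchsorted(pos, [dom.start, dom.end])
                if hi == lo:
                    continue
                shifted = p[lo:hi] + shift
                clipped = int(((shifted < 0.0) | (shifted > 1.0)).sum())
                if clipped:
                    n_clipped[cond] += clipped
                p[lo:hi] = np.clip(shifted, 0.0, 1.0)
            probs[cond][chrom] = p

    for cond, k in n_clipped.items():
        if k:
            logger.info("condition %s: %d truth probabilities clipped to [0,1]", cond, k)

    return TruthMethylome(
        cpg_positions=genome.cpg_positions,
        probs=probs,
        conversion_rates=dict(conversion_rates),
        domains=genome.domains,
        noncpg_level=spec.noncpg_level,
        n_clipped=n_clipped,
    )


def _mixture_draw(rng, n, weights, comps) -> np.ndarray:
    comp = rng.choice(len(weights), size=n, p=np.asarray(weights, dtype=float))
    out = np.empty(n, dtype=np.float64)
    for k, (a, b) in enumerate(comps):
        idx = comp == k
        out[idx] = rng.beta(a, b, size=int(idx.sum()))
    return out
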