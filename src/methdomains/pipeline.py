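"""End-to-end orchestration: simulate -> call -> stats -> domains -> expression.

A single YAML-configurable run simulates the three study conditions
(normal lung, Dnmt3a-wildtype tumor, Dnmt3a-knockout tumor, plus a second
wildtype-tumor read replicate for conserved-PMD calling), calls
methylation per condition, summarises methylome composition, segments
hypomethylated domains for the three comparisons (tumor vs normal, ko vs
normal, ko vs wt), correlates window tracks with the external tracks, and
associates deregulated genes with Dnmt3a-dependent methylation loss.
Every output file is recorded in a manifest with its SHA-256 checksum;
rerunning with an identical config and seed reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from methdomains import io as mio
from methdomains import calling, domains, expression, stats
from methdomains.simulate import (
    ReadSimParams,
    assign_truth_methylome,
    build_genome,
    default_spec,
    simulate_bisulfite_reads,
    simulate_expression_table,
    simulate_external_tracks,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "stats", "domains", "correlate", "expression")
COMPARISONS = (("wt", "normal"), ("ko", "normal"), ("ko", "wt"))


def _package_version() -> str:
    import methdomains

    return methdomains.__version__


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters; YAML-serialisable."""

    outdir: str = "methdomains_run"
    seed: int = 0
    # genome plan
    chrom_lengths: Dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    n_genes: int = 100
    pmd_fraction: float = 0.25
    dpd_fraction: float = 0.125
    domain_size: int = 500_000
    # sequencing model
    coverage: float = 10.0
    read_length: int = 105
    error_rate: float = 0.001
    conversion_rates: Dict[str, float] = field(
        default_factory=lambda: {"normal": 0.991, "wt": 0.990, "ko": 0.989}
    )
    # calling
    max_read_length: int = 80
    min_quality: int = 30
    # windows / domains
    window_size: int = 100_000
    delta: float = 0.15
    # feature filters
    promoter_min_cpgs: int = 3
    promoter_min_coverage: int = 3
    cgi_promoter_min_cpgs: int = 6  # "more than 5 CpGs"
    # expression
    fold_threshold: float = 2.0
    alpha: float = 0.01
    # stage toggles
    stages: Dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        for cond, rate in self.conversion_rates.items():
            if not 0.9 <= rate <= 1.0:
                raise ValueError(f"conversion rate for {cond} outside [0.9, 1.0]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        stages = {s: True for s in STAGES}
        stages.update(data.pop("stages", {}))
        return cls(stages=stages, **data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest dict.

    On stage failure the partial manifest is written next to a FAILED
    marker file and a :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _package_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "comparisons": [f"{a}_vs_{b}" for a, b in COMPARISONS],
        "stages": {},
        "files": {},
        "summary": {},
    }
    state = _RunState(config=config, outdir=outdir, manifest=manifest)
    t0 = time.time()
    for stage in STAGES:
        if not config.stages.get(stage, True):
            manifest["stages"][stage] = {"status": "skipped"}
            logger.info("stage %s skipped", stage)
            continue
        logger.info("stage %s started", stage)
        t = time.time()
        try:
            _STAGE_FUNCS[stage](state)
        except Exception as exc:  # pragma: no cover - exercised via tests
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(outdir, manifest)
            (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
            raise PipelineError(stage, exc) from exc
        # timings are logged, never written: outputs must be byte-identical
        # across reruns with the same seed
        manifest["stages"][stage] = {"status": "ok"}
        logger.info("stage %s done in %.1fs", stage, time.time() - t)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    _write_manifest(outdir, manifest)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return manifest


@dataclass
class _RunState:
    config: RunConfig
    outdir: Path
    manifest: dict
    genome: Optional[object] = None
    truth: Optional[object] = None
    tracks: Optional[Dict[str, pd.DataFrame]] = None
    expr_table: Optional[pd.DataFrame] = None
    calls: Dict[str, pd.DataFrame] = field(default_factory=dict)
    window_tracks: Dict[str, object] = field(default_factory=dict)
    diff_tracks: Dict[str, object] = field(default_factory=dict)
    pmds: Optional[object] = None
    dpds: Optional[object] = None

    #: read sets: the three conditions plus a second wildtype-tumor
    #: replicate (independent reads from the same wildtype truth)
    @property
    def read_roles(self) -> List[tuple]:
        return [
            ("normal", "normal", self.config.seed),
            ("wt", "wt", self.config.seed),
            ("wt_small", "wt", self.config.seed + 7919),
            ("ko", "ko", self.config.seed),
        ]

    def register(self, name: str, path: Path) -> None:
        self.manifest["files"][str(path.relative_to(self.outdir))] = mio.sha256_file(path)

    def chrom_lengths(self) -> Dict[str, int]:
        return dict(self.config.chrom_lengths)


def _stage_simulate(state: _RunState) -> None:
    cfg = state.config
    spec = default_spec(
        chrom_lengths=cfg.chrom_lengths,
        seed=cfg.seed,
        pmd_fraction=cfg.pmd_fraction,
        dpd_fraction=cfg.dpd_fraction,
        domain_size=cfg.domain_size,
        n_genes=cfg.n_genes,
    )
    state.genome = build_genome(spec)
    state.truth = assign_truth_methylome(state.genome, spec, cfg.conversion_rates)
    paths = state.genome.write(state.outdir)
    for name, p in paths.items():
        state.register(name, Path(p))
    truth_path = state.outdir / "truth.tsv"
    state.truth.write_tsv(truth_path)
    state.register("truth", truth_path)
    state.tracks = simulate_external_tracks(state.genome, seed=cfg.seed)
    for name, df in state.tracks.items():
        p = state.outdir / f"track_{name}.bedGraph"
        mio.write_bedgraph(p, df)
        state.register(f"track_{name}", p)
    state.expr_table = simulate_expression_table(state.genome, seed=cfg.seed)
    p = state.outdir / "expression.tsv"
    state.expr_table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    state.register("expression", p)
    state.manifest["summary"]["n_cpgs"] = state.genome.n_cpgs


def _stage_call(state: _RunState) -> None:
    cfg = state.config
    if state.genome is None:
        _load_simulated(state)
    params = ReadSimParams(
        coverage=cfg.coverage,
        read_length=cfg.read_length,
        error_rate=cfg.error_rate,
    )
    conv_summary, mean_summary = {}, {}
    for role, cond, seed in state.read_roles:
        readset = simulate_bisulfite_reads(state.genome, state.truth, cond, params, seed=seed)
        sam_path = state.outdir / f"reads_{role}.sam"
        readset.write_sam(sam_path)
        state.register(f"reads_{role}", sam_path)
        result = calling.run_caller(
            readset,
            state.genome.sequences,
            max_length=cfg.max_read_length,
            min_quality=cfg.min_quality,
        )
        calls = result.calls(context="CG")
        state.calls[role] = calls
        calls_path = state.outdir / f"calls_{role}.tsv"
        mio.write_calls(calls_path, calls)
        state.register(f"calls_{role}", calls_path)
        conv_summary[role] = round(result.conversion().rate, 5)
        mean_summary[role] = round(calling.aggregate_mean_ratio(calls), 4)
        del readset
    state.manifest["summary"]["conversion_rate"] = conv_summary
    state.manifest["summary"]["mean_cpg_methylation"] = mean_summary


def _stage_stats(state: _RunState) -> None:
    cfg = state.config
    if not state.calls:
        _load_calls(state)
    genome = state.genome
    chrom_lengths = state.chrom_lengths()
    promoters = stats.promoter_intervals(genome.genes, chrom_lengths)
    cgi_promoters = _cgi_promoters(promoters, genome.cgi)
    hist_rows, feat_rows, fraction_summary = [], [], {}
    for role, calls in state.calls.items():
        bins = stats.bin_distribution(calls, context="CG")
        fraction_summary[role] = {k: round(v, 4) for k, v in bins.fractions.items()}
        for lo, hi, count in zip(bins.hist_edges[:-1], bins.hist_edges[1:], bins.hist_counts):
            hist_rows.append(
                {"condition": role, "bin_low": lo, "bin_high": hi, "count": int(count)}
            )
        summaries = [
            stats.feature_methylation(
                calls, promoters, cfg.promoter_min_cpgs, cfg.promoter_min_coverage, "promoter"
            ),
            stats.feature_methylation(
                calls,
                cgi_promoters,
                cfg.cgi_promoter_min_cpgs,
                cfg.promoter_min_coverage,
                "cgi_promoter",
            ),
        ]
        for family, feats in genome.repeats.groupby("name"):
            summaries.append(
                stats.feature_methylation(calls, feats, 1, 1, f"repeat_{family}")
            )
        partition = stats.partition_genic(
            calls, genome.genes, genome.subregions, chrom_lengths
        )
        for s in summaries:
            feat_rows.append(
                {
                    "condition": role,
                    "category": s.category,
                    "mean": s.mean,
                    "n_features": s.n_features,
                    "n_excluded": s.n_excluded,
                }
            )
        for cat, s in partition.items():
            feat_rows.append(
                {
                    "condition": role,
                    "category": cat,
                    "mean": s.mean,
                    "n_features": s.n_sites,
                    "n_excluded": 0,
                }
            )
    hist_path = state.outdir / "histograms.tsv"
    pd.DataFrame(hist_rows).to_csv(hist_path, sep="\t", index=False, float_format="%.6g")
    state.register("histograms", hist_path)
    feat_path = state.outdir / "feature_summary.tsv"
    pd.DataFrame(feat_rows).to_csv(feat_path, sep="\t", index=False, float_format="%.6g")
    state.register("feature_summary", feat_path)
    state.manifest["summary"]["state_fractions"] = fraction_summary


def _stage_domains(state: _RunState) -> None:
    cfg = state.config
    if not state.calls:
        _load_calls(state)
    chrom_lengths = state.chrom_lengths()
    w = cfg.window_size
    for role, calls in state.calls.items():
        track = domains.window_track(calls, w, chrom_lengths, condition=role)
        state.window_tracks[role] = track
        p = state.outdir / f"windows_{w}_{role}.bedGraph"
        track.to_bedgraph(p)
        state.register(f"windows_{role}", p)
    counts = {}
    for a, b in COMPARISONS:
        diff, n = domains.differential_windows(
            state.window_tracks[a], state.window_tracks[b], cfg.delta, label=f"{a}_vs_{b}"
        )
        state.diff_tracks[f"{a}_vs_{b}"] = diff
        counts[f"{a}_vs_{b}"] = n
        p = state.outdir / f"diff_{a}_vs_{b}.bedGraph"
        diff.to_bedgraph(p)
        state.register(f"diff_{a}_vs_{b}", p)
    # replicate comparison for conserved PMDs
    diff_rep, n_rep = domains.differential_windows(
        state.window_tracks["wt_small"],
        state.window_tracks["normal"],
        cfg.delta,
        label="wt_small_vs_normal",
    )
    state.diff_tracks["wt_small_vs_normal"] = diff_rep
    counts["wt_small_vs_normal"] = n_rep
    p = state.outdir / "diff_wt_small_vs_normal.bedGraph"
    diff_rep.to_bedgraph(p)
    state.register("diff_wt_small_vs_normal", p)

    state.pmds = domains.call_conserved_pmds(
        [state.diff_tracks["wt_vs_normal"], diff_rep]
    )
    state.dpds = domains.call_dpds(
        state.window_tracks["wt"], state.window_tracks["ko"], cfg.delta
    )
    for name, dset in (("pmds", state.pmds), ("dpds", state.dpds)):
        p = state.outdir / f"{name}.bed"
        dset.to_bed(p)
        state.register(name, p)
    state.manifest["summary"]["hypomethylated_windows"] = counts
    state.manifest["summary"]["n_pmds"] = len(state.pmds)
    state.manifest["summary"]["n_dpds"] = len(state.dpds)


def _stage_correlate(state: _RunState) -> None:
    cfg = state.config
    if state.tracks is None or state.genome is None:
        _load_simulated(state)
    chrom_lengths = state.chrom_lengths()
    rows = []
    # methylation loss in wildtype tumors (PMD signal) vs lamina / CpG density / H3K4me1
    pmd_diff = state.diff_tracks["wt_vs_normal"].frame
    loss = pmd_diff[["chrom", "start", "end"]].copy()
    loss["value"] = pmd_diff["mean_b"] - pmd_diff["mean_a"]
    dpd_diff = state.diff_tracks["ko_vs_wt"].frame
    dpd_loss = dpd_diff[["chrom", "start", "end"]].copy()
    dpd_loss["value"] = dpd_diff["mean_b"] - dpd_diff["mean_a"]
    cpg_density = domains.cpg_density_track(state.genome.sequences, cfg.window_size)
    pairs = [
        ("pmd_loss", "lamina", loss, state.tracks["lamina"]),
        ("pmd_loss", "cpg_density", loss, cpg_density[mio.BEDGRAPH_COLUMNS]),
        ("pmd_loss", "h3k4me1", loss, state.tracks["h3k4me1"]),
        ("dpd_loss", "cpg_density", dpd_loss, cpg_density[mio.BEDGRAPH_COLUMNS]),
        ("dpd_loss", "h3k4me1", dpd_loss, state.tracks["h3k4me1"]),
    ]
    summary = {}
    for signal, track_name, values, track in pairs:
        rho, p, n = domains.correlate_with_track(values, track, chrom_lengths, cfg.window_size)
        rows.append(
            {"signal": signal, "track": track_name, "rho": rho, "p": p, "n_windows": n}
        )
        summary[f"{signal}_vs_{track_name}"] = round(rho, 3)
    path = state.outdir / "correlations.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    state.register("correlations", path)
    state.manifest["summary"]["spearman"] = summary


def _stage_expression(state: _RunState) -> None:
    cfg = state.config
    if state.expr_table is None:
        _load_simulated(state)
    sets = expression.select_de_genes(state.expr_table, cfg.fold_threshold)
    genes = state.genome.genes
    diff = state.diff_tracks["ko_vs_wt"]
    de_genes = genes[genes["name"].isin(set(sets.up["gene"]) | set(sets.down["gene"]))]
    deltas, fraction = expression.gene_window_delta(de_genes, diff)
    p = state.outdir / "de_gene_deltas.tsv"
    deltas.to_csv(p, sep="\t", index=False, float_format="%.6g")
    state.register("de_gene_deltas", p)

    means_wt = expression.gene_subregion_means(state.calls["wt"], state.genome.subregions)
    means_ko = expression.gene_subregion_means(state.calls["ko"], state.genome.subregions)
    tests = expression.subregion_differential_test(
        {"up": sets.up["gene"], "down": sets.down["gene"]}, means_wt, means_ko, cfg.alpha
    )
    p = state.outdir / "subregion_tests.tsv"
    tests.to_csv(p, sep="\t", index=False, float_format="%.6g")
    state.register("subregion_tests", p)
    state.manifest["summary"]["de_genes"] = sets.counts
    state.manifest["summary"]["fraction_de_in_hypomethylated_windows"] = (
        round(fraction, 4) if np.isfinite(fraction) else None
    )
    state.manifest["summary"]["significant_subregions"] = [
        f"{r.gene_set}:{r.subregion}" for r in tests.itertuples() if r.significant
    ]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "stats": _stage_stats,
    "domains": _stage_domains,
    "correlate": _stage_correlate,
    "expression": _stage_expression,
}


def _cgi_promoters(promoters: pd.DataFrame, cgi: pd.DataFrame) -> pd.DataFrame:
    """Promoters overlapping an annotated CpG island."""
    if len(cgi) == 0 or len(promoters) == 0:
        return promoters.iloc[0:0]
    keep = []
    for _, p in promoters.iterrows():
        sub = cgi[cgi["chrom"] == p["chrom"]]
        if ((sub["start"] < p["end"]) & (p["start"] < sub["end"])).any():
            keep.append(True)
        else:
            keep.append(False)
    return promoters[np.asarray(keep, dtype=bool)]


def _load_simulated(state: _RunState) -> None:
    """Recover simulate-stage outputs from disk when that stage was skipped."""
    cfg = state.config
    outdir = state.outdir
    spec = default_spec(
        chrom_lengths=cfg.chrom_lengths,
        seed=cfg.seed,
        pmd_fraction=cfg.pmd_fraction,
        dpd_fraction=cfg.dpd_fraction,
        domain_size=cfg.domain_size,
        n_genes=cfg.n_genes,
    )
    state.genome = build_genome(spec)
    state.truth = assign_truth_methylome(state.genome, spec, cfg.conversion_rates)
    tracks = {}
    for name in ("lamina", "h3k4me1", "expression"):
        p = outdir / f"track_{name}.bedGraph"
        if p.exists():
            tracks[name] = mio.read_bedgraph(p)
    if not tracks:
        tracks = simulate_external_tracks(state.genome, seed=cfg.seed)
    state.tracks = tracks
    p = outdir / "expression.tsv"
    state.expr_table = (
        pd.read_csv(p, sep="\t") if p.exists() else simulate_expression_table(state.genome, seed=cfg.seed)
    )


def _load_calls(state: _RunState) -> None:
    if state.genome is None:
        _load_simulated(state)
    for role, _, _ in state.read_roles:
        p = state.outdir / f"calls_{role}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"call stage disabled but {p} is missing")
        state.calls[role] = mio.read_calls(p)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
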