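"""Shared study configuration for the numbered analysis scripts.

The scripts run the stages of one synthetic 10-Mb lung-tumor methylome
study (normal, Dnmt3a-wildtype tumor + replicate, Dnmt3a-knockout tumor)
in order, sharing state through ``scratch/study`` and writing the tables a
reader would look at into ``results/``.
"""

from __future__ import annotations

from pathlib import Path

from methdomains.pipeline import RunConfig, STAGES

REPO_ROOT = Path(__file__).resolve().parent.parent
STUDY_DIR = REPO_ROOT / "scratch" / "study"
RESULTS_DIR = REPO_ROOT / "results"
SEED = 7


def study_config(*enabled_stages: str) -> RunConfig:
    stages = {s: s in enabled_stages for s in STAGES}
    return RunConfig(
        outdir=str(STUDY_DIR),
        seed=SEED,
        chrom_lengths={"chr1": 10_000_000},
        n_genes=100,
        coverage=10.0,
        stages=stages,
    )
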