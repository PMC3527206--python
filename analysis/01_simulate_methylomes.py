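"""Build the synthetic study: genome, truth methylomes, tracks, expression.

Plants PMD-like (CpG-poor, hypomethylated in both tumor genotypes) and
DPD-like (CpG-dense, hypomethylated only without Dnmt3a) domains on a
10 Mb chromosome, assigns per-CpG truth probabilities for the three
conditions, and emits the annotations and external tracks downstream
stages consume.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS_DIR, STUDY_DIR, study_config

from methdomains.pipeline import run_pipeline


def main() -> None:
    manifest = run_pipeline(study_config("simulate"))
    print(f"simulated genome written to {STUDY_DIR}")
    print(f"  CpG dyads: {manifest['summary']['n_cpgs']}")
    n_files = len(manifest["files"])
    print(f"  {n_files} files (genome.fa, annotations, truth.tsv, tracks)")
    RESULTS_DIR.mkdir(exist_ok=True)


if __name__ == "__main__":
    main()
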