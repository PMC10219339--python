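#!/usr/bin/env python
"""Reconstruct the regulon from the benchmark dataset.

Runs merge -> classify -> integrate -> motif -> stats end-to-end on
scratch/dataset (see 01_simulate.py) and copies the compact summaries
into results/. The full per-peak and per-TU tables stay in scratch/run.
"""

import json
import shutil
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from fur_regulon.pipeline import run_on_dataset

DATASET = REPO / "scratch" / "dataset"
RUN = REPO / "scratch" / "run"
RESULTS = REPO / "results"


def main() -> None:
    if not DATASET.exists():
        sys.exit("dataset missing - run analysis/01_simulate.py first")
    report = run_on_dataset(DATASET, RUN, seed=0)
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(RUN / "regulon_summary.json", RESULTS / "02_regulon_summary.json")
    summary = report.results["regulon_summary"]
    counts = report.results["assignment_counts"]
    print(
        f"peaks: {report.results['n_peaks_merged']} merged "
        f"({counts['n_promoter']} promoter of which {counts['n_divergent']} "
        f"divergent, {counts['n_cds']} CDS) -> "
        f"{counts['n_tu_candidates']} candidate TUs"
    )
    print(
        f"direct regulon: {summary['n_direct']} TUs "
        f"({summary['n_repressed']} repressed / {summary['n_activated']} activated); "
        f"{summary['n_direct_plusfe']} with iron, {summary['n_direct_minusfe']} "
        f"without, {summary['n_both_conditions']} in both"
    )
    print(
        f"DEG coverage: {summary['n_direct_degs']} of {summary['n_total_degs']} "
        f"DEGs in direct TUs ({summary['direct_fraction_pct']:.1f}%)"
    )


if __name__ == "__main__":
    main()
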