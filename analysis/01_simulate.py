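#!/usr/bin/env python
"""Generate the benchmark dataset: a toy genome with a planted iron regulon.

Writes the full dataset (GFF3, FASTA, peak tables, DEG tables, truth
manifest) under scratch/dataset and a compact summary under results/.
"""

import json
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from fur_regulon.simulate import SimulationConfig, simulate_dataset

OUT = REPO / "scratch" / "dataset"
RESULTS = REPO / "results"


def main() -> None:
    config = SimulationConfig(seed=0)
    sim = simulate_dataset(config, OUT)
    truth = sim.truth
    n_bound = sum(rec["bound"] for rec in truth.tus.values())
    modes = [rec["mode"] for rec in truth.tus.values() if rec["direct"]]
    summary = {
        "dataset_dir": str(OUT),
        "run_id": truth.run_id,
        "n_genes": len(sim.annotation.genes),
        "n_tus": len(sim.annotation.tus),
        "n_bound_tus": n_bound,
        "n_direct_tus": len(truth.direct_tu_ids()),
        "n_repressed": modes.count("REPRESSED"),
        "n_activated": modes.count("ACTIVATED"),
        "n_peaks_plusFe": len(sim.peak_tables[0]),
        "n_peaks_minusFe": len(sim.peak_tables[1]),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "01_dataset_summary.json").write_text(json.dumps(summary, indent=1))
    print(
        f"planted regulon: {summary['n_direct_tus']} direct of "
        f"{summary['n_bound_tus']} bound TUs "
        f"({summary['n_repressed']} repressed / {summary['n_activated']} activated) "
        f"across {summary['n_tus']} TUs, {summary['n_genes']} genes"
    )
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    main()
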