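#!/usr/bin/env python
"""Score the reconstructed regulon against the planted truth.

Reads the calls from scratch/run and the manifest from scratch/dataset;
writes precision / recall / mode accuracy to results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from fur_regulon.regulon import DIRECT, RegulonCall
from fur_regulon.simulate import load_truth, score_against_truth

DATASET = REPO / "scratch" / "dataset"
RUN = REPO / "scratch" / "run"
RESULTS = REPO / "results"


def main() -> None:
    calls_path = RUN / "regulon_calls.tsv"
    if not calls_path.exists():
        sys.exit("pipeline output missing - run analysis/02_reconstruct_regulon.py")
    df = pd.read_csv(calls_path, sep="\t")
    calls = [
        RegulonCall(
            tu_id=r.tu_id, status=r.status, mode=r.mode,
            evidence_conditions=(
                frozenset(str(r.evidence_conditions).split(","))
                if r.status == DIRECT else frozenset()
            ),
            first_gene_id=r.first_gene_id, peak_id=r.peak_id,
        )
        for r in df.itertuples()
    ]
    truth = load_truth(DATASET / "truth_manifest.json")
    scores = score_against_truth(calls, truth)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "03_recovery.json").write_text(json.dumps(scores, indent=1))
    print(
        f"recovery: precision {scores['precision']:.3f}, "
        f"recall {scores['recall']:.3f}, "
        f"mode accuracy {scores['mode_accuracy']:.3f} "
        f"({scores['tp']} TP / {scores['fp']} FP / {scores['fn']} FN)"
    )


if __name__ == "__main__":
    main()
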