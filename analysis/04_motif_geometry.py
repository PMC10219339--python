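#!/usr/bin/env python
"""Summarise binding-site motifs and their geometry by regulatory mode.

Pulls the discovered PWM statistics and scanned site positions from the
pipeline report: consensus, information content, palindromicity, and the
median site position relative to the TSS for repressed vs activated units.
"""

import json
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
RUN = REPO / "scratch" / "run"
RESULTS = REPO / "results"


def main() -> None:
    report_path = RUN / "report.json"
    if not report_path.exists():
        sys.exit("pipeline output missing - run analysis/02_reconstruct_regulon.py")
    results = json.loads(report_path.read_text())["results"]
    out = {
        "motifs": {
            mode: {
                "consensus": info["iupac_string"],
                "total_bits": round(info["total_bits"], 2),
                "palindromicity": round(info["palindromicity"], 3),
                "n_promoters": info["n_sequences"],
            }
            for mode, info in results["motifs"].items()
        },
        "site_positions": results["site_positions"],
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "04_motif_geometry.json").write_text(json.dumps(out, indent=1))
    for mode, info in out["motifs"].items():
        pos = out["site_positions"][mode]
        print(
            f"{mode}: consensus {info['consensus']} "
            f"({info['total_bits']} bits, palindromicity {info['palindromicity']}), "
            f"site median {pos['median']:+.0f} bp vs TSS (n={pos['n']})"
        )


if __name__ == "__main__":
    main()
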