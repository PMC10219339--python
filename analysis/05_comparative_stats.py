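#!/usr/bin/env python
"""Comparative statistics distinguishing repressed from activated targets.

Collects from the pipeline report: binding-strength contrasts (promoter vs
CDS; repressed vs activated), the iron-sensitivity asymmetry of paired
fold changes, the fold-change vs binding-strength regression, and the
functional-category tally of direct units.
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
    keys = (
        "class_enrichment", "mode_enrichment", "abs_fold_change",
        "iron_sensitivity", "fc_binding_regression", "category_tally",
    )
    out = {k: results[k] for k in keys if k in results}
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "05_comparative_stats.json").write_text(json.dumps(out, indent=1))

    ce = out["class_enrichment"]
    print(
        f"binding strength promoter vs CDS: "
        f"{ce['mean'][0]:.2f} vs {ce['mean'][1]:.2f} (p={ce['p']:.2e})"
    )
    me = out["mode_enrichment"]
    print(
        f"binding strength repressed vs activated: "
        f"{me['mean'][0]:.2f} vs {me['mean'][1]:.2f} (p={me['p']:.2e})"
    )
    for mode, s in out["iron_sensitivity"].items():
        print(
            f"iron sensitivity {mode}: {s['frac_larger_with_fe']:.2f} of {s['n']} "
            f"genes respond more strongly with iron (sign test p={s['sign_test_p']:.3g})"
        )
    fit = out["fc_binding_regression"]
    print(
        f"|fold change| vs binding strength: r={fit['r']:.2f} "
        f"(p={fit['p']:.3g}, n={fit['n']})"
    )
    tally = out["category_tally"]
    print(
        f"top functional category: {tally['top_category']} "
        f"({tally['top_share_pct']:.0f}% of direct TUs)"
    )


if __name__ == "__main__":
    main()
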