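"""Readers and writers for the tabular interchange formats.

Peak tables come in as narrowPeak (10 columns, fold enrichment in
``signalValue``) or a 6-column BED dialect with the fold enrichment in the
score column. DEG tables are TSV ``gene_id / log2fc / qvalue`` with an
optional leading comment line naming the comparison and the fold-change
direction; internally everything is log2(knockout / wild-type).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import GenomicInterval
from .peaks import Peak, PeakAssignment
from .regulon import COMPARISONS, DegRecord, DegTable, RegulonCall, RegulonError

NARROWPEAK_NAMES = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


class FormatError(ValueError):
    pass


def read_narrowpeak(
    path: str | Path, condition: str, fmt: str = "auto"
) -> list[Peak]:
    """Load a peak table as :class:`Peak` objects tagged with their condition.

    ``fmt``: ``narrowPeak`` (10 columns; summit offset in the last column,
    -1 for unknown), ``bed6fe`` (6 columns; fold enrichment in the score
    column), or ``auto`` to decide by column count.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if fmt == "auto":
        fmt = "narrowPeak" if df.shape[1] >= 10 else "bed6fe"
    peaks: list[Peak] = []
    for i, row in df.iterrows():
        if fmt == "narrowPeak":
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            name = str(row[3]) if not pd.isna(row[3]) else f"peak{i}"
            fe = float(row[6])
            summit_off = int(row[9])
            summit = start + summit_off if summit_off >= 0 else None
        elif fmt == "bed6fe":
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            name = str(row[3]) if df.shape[1] > 3 and not pd.isna(row[3]) else f"peak{i}"
            fe = float(row[4])
            summit = None
        else:
            raise FormatError(f"unknown peak format {fmt!r}")
        peaks.append(
            Peak(
                id=name, contig=chrom,
                interval=GenomicInterval(chrom, start, end),
                fold_enrichment=fe, conditions=frozenset({condition}),
                summit=summit,
            )
        )
    return peaks


def read_deg_table(
    path: str | Path,
    comparison_id: str | None = None,
    fc_direction: str | None = None,
) -> DegTable:
    """Load a DEG table, normalising fold changes to log2(KO/WT).

    A first line of the form ``# comparison_id=...\tfc_direction=...`` is
    honoured; explicit arguments override it. ``fc_direction`` is
    ``ko_vs_wt`` (stored as-is) or ``wt_vs_ko`` (sign flipped on load).
    """
    path = Path(path)
    header_meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].strip().split("\t"):
            if "=" in tok:
                k, v = tok.split("=", 1)
                header_meta[k.strip()] = v.strip()
    comparison_id = comparison_id or header_meta.get("comparison_id")
    fc_direction = fc_direction or header_meta.get("fc_direction", "ko_vs_wt")
    if comparison_id not in COMPARISONS:
        raise RegulonError(
            f"{path.name}: comparison_id {comparison_id!r} is not one of {COMPARISONS}"
        )
    if fc_direction not in ("ko_vs_wt", "wt_vs_ko"):
        raise RegulonError(f"unknown fc_direction {fc_direction!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "log2fc", "qvalue"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path.name}: missing columns {sorted(required - set(df.columns))}"
        )
    flip = -1.0 if fc_direction == "wt_vs_ko" else 1.0
    records = {
        str(r.gene_id): DegRecord(
            gene_id=str(r.gene_id), log2fc=flip * float(r.log2fc),
            qvalue=float(r.qvalue),
        )
        for r in df.itertuples()
    }
    return DegTable(comparison_id=comparison_id, records=records)


def read_tu_table(path: str | Path) -> list[tuple[str, str]]:
    """TSV of (unit_id, gene_id, rank) -> ordered (unit_id, gene_id) pairs."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "rank" in df.columns:
        df = df.sort_values(["unit_id", "rank"], kind="stable")
    return [(str(r.unit_id), str(r.gene_id)) for r in df.itertuples()]


def read_tss_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.gene_id): int(r.tss_1based) for r in df.itertuples()}


def read_gene_list(path: str | Path) -> set[str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    col = df.columns[0]
    return {str(g) for g in df[col]}


def read_category_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.gene_id): str(r.category) for r in df.itertuples()}


def write_assignments(
    assignments: Sequence[PeakAssignment],
    peaks: Sequence[Peak],
    path: str | Path,
) -> None:
    """Peak assignment table: one row per (peak, target) pair."""
    fe = {p.id: p for p in peaks}
    rows = []
    for a in assignments:
        peak = fe[a.peak_id]
        targets = list(zip(a.target_tu_ids, a.target_gene_ids, a.distances_to_anchor)) or [
            (None, None, None)
        ]
        for tu_id, gene_id, dist in targets:
            rows.append({
                "peak_id": a.peak_id,
                "class": a.peak_class,
                "tu_id": tu_id,
                "gene_id": gene_id,
                "distance_to_anchor": dist,
                "fold_enrichment": peak.fold_enrichment,
                "conditions": ",".join(sorted(peak.conditions)),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_regulon_calls(calls: Sequence[RegulonCall], path: str | Path) -> None:
    rows = [
        {
            "tu_id": c.tu_id,
            "status": c.status,
            "mode": c.mode,
            "evidence_conditions": ",".join(sorted(c.evidence_conditions)),
            "first_gene_id": c.first_gene_id,
            "peak_id": c.peak_id,
            "log2fc_plusFe": c.log2fc_plusfe,
            "log2fc_minusFe": c.log2fc_minusfe,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(x):
    try:
        return x.as_dict()
    except AttributeError:
        pass
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
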