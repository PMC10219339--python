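"""Direct-regulon calling: combine bound transcriptional units with DEG tables.

The decision rule: a transcriptional unit whose promoter is bound is called
a DIRECT target when its *first gene* is differentially expressed
(q < 0.01) in the wild-type versus knockout comparison in at least one of
the two iron conditions. Fold-change direction is stored internally as
log2(knockout / wild-type), so a positive value means the gene is
de-repressed in the knockout, i.e. normally REPRESSED by the regulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome import GenomeAnnotation, first_gene

logger = logging.getLogger(__name__)

# the four transcriptome comparisons
WT_FE_VS_NOFE = "WT_Fe_vs_noFe"
KO_FE_VS_NOFE = "KO_Fe_vs_noFe"
WT_VS_KO_PLUSFE = "WTvsKO_plusFe"
WT_VS_KO_MINUSFE = "WTvsKO_minusFe"
COMPARISONS = (WT_FE_VS_NOFE, KO_FE_VS_NOFE, WT_VS_KO_PLUSFE, WT_VS_KO_MINUSFE)

DIRECT = "DIRECT"
BOUND_ONLY = "BOUND_ONLY"
REPRESSED = "REPRESSED"
ACTIVATED = "ACTIVATED"
NA = "NA"

PLUS_FE = "plusFe"
MINUS_FE = "minusFe"


class RegulonError(ValueError):
    pass


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise RegulonError(f"{self.gene_id}: q-value outside [0, 1]")


@dataclass
class DegTable:
    """Per-gene log2 fold change and q-value for one comparison."""

    comparison_id: str
    records: dict[str, DegRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.comparison_id not in COMPARISONS:
            raise RegulonError(f"unknown comparison {self.comparison_id!r}")

    def log2fc(self, gene_id: str) -> float | None:
        rec = self.records.get(gene_id)
        return rec.log2fc if rec else None


@dataclass(frozen=True)
class RegulonCall:
    tu_id: str
    status: str  # DIRECT | BOUND_ONLY
    mode: str  # REPRESSED | ACTIVATED | NA
    evidence_conditions: frozenset[str]
    first_gene_id: str
    peak_id: str | None = None
    log2fc_plusfe: float | None = None
    log2fc_minusfe: float | None = None

    def __post_init__(self) -> None:
        if self.status == DIRECT and (not self.evidence_conditions or self.mode == NA):
            raise RegulonError(f"{self.tu_id}: DIRECT call lacks evidence or mode")


@dataclass
class RegulonSummary:
    n_direct: int
    n_repressed: int
    n_activated: int
    n_bound_only: int
    n_direct_plusfe: int
    n_direct_minusfe: int
    n_both_conditions: int
    n_direct_degs: int | None = None
    n_total_degs: int | None = None
    direct_fraction_pct: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_degs(table: DegTable, q_threshold: float = 0.01) -> dict[str, str]:
    """Genes passing the DEG filter, tagged ``"up"``/``"down"`` by log2fc sign.

    The threshold is applied strictly (q == threshold is excluded). A record
    with a significant q but a log2fc of exactly zero has no direction and
    is dropped with a warning.
    """
    if not (0.0 < q_threshold < 1.0):
        raise RegulonError("q_threshold must be in (0, 1)")
    out: dict[str, str] = {}
    for gid, rec in table.records.items():
        if rec.qvalue < q_threshold:
            if rec.log2fc == 0:
                logger.warning(
                    "%s: significant q but zero fold change; excluded", gid
                )
                continue
            out[gid] = "up" if rec.log2fc > 0 else "down"
    return out


def classify_mode(
    evidence_conditions: Iterable[str],
    log2fc_plusfe: float | None,
    log2fc_minusfe: float | None,
    tu_id: str = "?",
) -> str:
    """Regulatory mode from the first gene's log2(KO/WT) fold change.

    Positive (expression up in the knockout) means the regulator normally
    represses; negative means it activates. When both iron conditions carry
    evidence with conflicting signs, the iron-replete value wins (the
    regulator is fully iron-loaded there) and the conflict is logged.
    """
    conds = set(evidence_conditions)
    fc = log2fc_plusfe if PLUS_FE in conds else log2fc_minusfe
    if fc is None:
        return NA
    if (
        PLUS_FE in conds
        and MINUS_FE in conds
        and log2fc_minusfe is not None
        and log2fc_plusfe is not None
        and (log2fc_plusfe > 0) != (log2fc_minusfe > 0)
    ):
        logger.warning(
            "%s: conflicting fold-change signs between iron conditions; "
            "using the iron-replete value", tu_id,
        )
    return REPRESSED if fc > 0 else ACTIVATED


def call_direct_targets(
    bound_tus: Mapping[str, str | None],
    deg_sets: Mapping[str, Mapping[str, str]],
    annotation: GenomeAnnotation,
    deg_tables: Mapping[str, DegTable] | None = None,
) -> list[RegulonCall]:
    """Apply the first-gene DEG criterion to promoter-bound TUs.

    ``bound_tus`` maps TU id to the supporting peak id (or None);
    ``deg_sets`` holds the filtered DEG sets of the WT-vs-KO comparisons
    keyed ``plusFe``/``minusFe``; ``deg_tables`` (same keys) supply the
    fold-change values for mode classification. A first gene missing from
    a DEG table simply counts as non-DEG there.
    """
    tables = deg_tables or {}
    calls: list[RegulonCall] = []
    for tu_id, peak_id in bound_tus.items():
        tu = annotation.tus.get(tu_id)
        if tu is None:
            raise RegulonError(f"unknown transcriptional unit {tu_id}")
        fg = first_gene(tu, annotation)
        evidence = frozenset(
            cond for cond in (PLUS_FE, MINUS_FE) if fg.id in deg_sets.get(cond, {})
        )
        fc_plus = tables[PLUS_FE].log2fc(fg.id) if PLUS_FE in tables else None
        fc_minus = tables[MINUS_FE].log2fc(fg.id) if MINUS_FE in tables else None
        if evidence:
            mode = classify_mode(evidence, fc_plus, fc_minus, tu_id)
            status = DIRECT if mode != NA else BOUND_ONLY
        else:
            mode, status = NA, BOUND_ONLY
        calls.append(
            RegulonCall(
                tu_id=tu_id, status=status, mode=mode,
                evidence_conditions=evidence if status == DIRECT else frozenset(),
                first_gene_id=fg.id, peak_id=peak_id,
                log2fc_plusfe=fc_plus, log2fc_minusfe=fc_minus,
            )
        )
    return calls


def union_regulon(calls: Sequence[RegulonCall]) -> RegulonSummary:
    """Per-condition direct counts, their intersection, and the union regulon."""
    direct = [c for c in calls if c.status == DIRECT]
    set_plus = {c.tu_id for c in direct if PLUS_FE in c.evidence_conditions}
    set_minus = {c.tu_id for c in direct if MINUS_FE in c.evidence_conditions}
    n_union = len(set_plus | set_minus)
    assert n_union == len(set_plus) + len(set_minus) - len(set_plus & set_minus)
    return RegulonSummary(
        n_direct=n_union,
        n_repressed=sum(1 for c in direct if c.mode == REPRESSED),
        n_activated=sum(1 for c in direct if c.mode == ACTIVATED),
        n_bound_only=sum(1 for c in calls if c.status == BOUND_ONLY),
        n_direct_plusfe=len(set_plus),
        n_direct_minusfe=len(set_minus),
        n_both_conditions=len(set_plus & set_minus),
    )


def direct_deg_fraction(
    direct_calls: Sequence[RegulonCall],
    all_deg_union: Iterable[str],
    annotation: GenomeAnnotation,
) -> dict:
    """Share of all DEGs that belong to directly controlled units.

    Membership counts every gene of a DIRECT unit, not only the first —
    a direct unit can contribute several DEGs.
    """
    degs = set(all_deg_union)
    if not degs:
        raise RegulonError("empty DEG union")
    member_genes: set[str] = set()
    for call in direct_calls:
        if call.status != DIRECT:
            continue
        member_genes.update(annotation.tus[call.tu_id].gene_ids)
    n_direct_degs = len(degs & member_genes)
    pct = 100.0 * n_direct_degs / len(degs)
    return {
        "n_direct_degs": n_direct_degs,
        "n_total_degs": len(degs),
        "pct": pct,
        "pct_rounded": round(pct),
        "direct_deg_genes": sorted(degs & member_genes),
    }


def external_regulon_overlap(
    all_deg_union: Iterable[str],
    external_gene_set: Iterable[str],
    direct_deg_set: Iterable[str],
) -> dict:
    """Set arithmetic against an external regulon (e.g. RyhB targets).

    ``n_overlap`` DEGs are in the external regulon; ``n_dual`` of those are
    also direct targets; the remainder are controlled exclusively via the
    external pathway.
    """
    degs = set(all_deg_union)
    external = set(external_gene_set)
    direct = set(direct_deg_set)
    overlap = degs & external
    dual = overlap & direct
    exclusive = overlap - direct
    return {
        "n_overlap": len(overlap),
        "n_dual": len(dual),
        "n_exclusive": len(exclusive),
        "exclusive_pct_of_degs": 100.0 * len(exclusive) / len(degs) if degs else 0.0,
    }


def rpkm(read_count: float, gene_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0 or total_mapped_reads <= 0:
        raise RegulonError("gene length and depth must be positive")
    return 1e9 * read_count / (gene_length_bp * total_mapped_reads)
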