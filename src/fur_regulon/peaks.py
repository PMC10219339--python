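"""Peak merging across conditions and promoter/CDS assignment.

ChIP peaks called separately in iron-replete (``plusFe``) and iron-depleted
(``minusFe``) cultures are combined into one table: peaks overlapping across
conditions become a single peak whose fold enrichment is the arithmetic mean
of the two condition-level values. Each combined peak is then anchored
(summit if present, else interval midpoint) and classified as PROMOTER
(anchor inside a gene's upstream window), CDS (inside a gene body), or
INTERGENIC. An anchor covered by the upstream windows of two divergently
transcribed genes yields one PROMOTER assignment with two target units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome import Gene, GenomeAnnotation, GenomicInterval, promoter_window, tss_position
from . import stats as _stats

PLUS_FE = "plusFe"
MINUS_FE = "minusFe"

PROMOTER = "PROMOTER"
CDS = "CDS"
INTERGENIC = "INTERGENIC"


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """A binding interval with fold enrichment and condition provenance."""

    id: str
    contig: str
    interval: GenomicInterval
    fold_enrichment: float
    conditions: frozenset[str]
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise PeakError(f"peak {self.id}: fold enrichment must be positive")
        if not self.conditions:
            raise PeakError(f"peak {self.id}: no condition provenance")
        if self.summit is not None and not self.interval.contains(self.summit):
            raise PeakError(f"peak {self.id}: summit outside interval")

    @property
    def anchor(self) -> int:
        """Summit when available, else the interval midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class PeakAssignment:
    """Class and target transcriptional unit(s) of one peak.

    ``distances_to_anchor`` are signed bp from the target gene's TSS (or
    start codon when no TSS is known) to the peak anchor, negative upstream.
    """

    peak_id: str
    peak_class: str  # PROMOTER | CDS | INTERGENIC
    target_tu_ids: tuple[str, ...] = ()
    target_gene_ids: tuple[str, ...] = ()
    distances_to_anchor: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.peak_class == CDS and len(self.target_tu_ids) != 1:
            raise PeakError("CDS assignment must have exactly one target")
        if self.peak_class == PROMOTER and len(self.target_tu_ids) not in (1, 2):
            raise PeakError("PROMOTER assignment must have 1 or 2 targets")

    @property
    def divergent(self) -> bool:
        return self.peak_class == PROMOTER and len(self.target_tu_ids) == 2


def merge_condition_peaks(
    peaks_plusfe: Sequence[Peak],
    peaks_minusfe: Sequence[Peak],
    min_overlap_bp: int = 1,
) -> list[Peak]:
    """Combine the two condition-specific peak sets into one.

    Cross-condition pairs overlapping by at least ``min_overlap_bp`` are
    merged into a peak spanning the union interval with the mean fold
    enrichment; each input peak joins at most one merged peak (best
    overlap wins). Unmatched peaks pass through unchanged.
    """
    for p in itertools.chain(peaks_plusfe, peaks_minusfe):
        if p.fold_enrichment <= 0:  # dataclass already guards; belt and braces
            raise PeakError(f"peak {p.id}: fold enrichment must be positive")

    unmatched_minus = list(peaks_minusfe)
    merged: list[Peak] = []
    for p in sorted(peaks_plusfe, key=lambda x: (x.contig, x.interval.start)):
        best, best_ov = None, 0
        for m in unmatched_minus:
            ov = p.interval.overlap(m.interval)
            if ov >= min_overlap_bp and ov > best_ov:
                best, best_ov = m, ov
        if best is None:
            merged.append(p)
            continue
        unmatched_minus.remove(best)
        union = GenomicInterval(
            p.contig,
            min(p.interval.start, best.interval.start),
            max(p.interval.end, best.interval.end),
        )
        stronger = p if p.fold_enrichment >= best.fold_enrichment else best
        merged.append(
            Peak(
                id=f"{p.id}|{best.id}",
                contig=p.contig,
                interval=union,
                fold_enrichment=(p.fold_enrichment + best.fold_enrichment) / 2.0,
                conditions=frozenset({PLUS_FE, MINUS_FE}),
                summit=stronger.summit,
            )
        )
    merged.extend(unmatched_minus)
    merged.sort(key=lambda x: (x.contig, x.interval.start, x.id))
    return merged


class AnnotationIndex:
    """Interval indexes over promoter windows and gene bodies for fast lookup."""

    def __init__(self, annotation: GenomeAnnotation, promoter_width_bp: int = 300):
        if not annotation.tus:
            raise PeakError("annotation has no transcriptional units built")
        self.annotation = annotation
        self.promoter_width_bp = promoter_width_bp
        self.tu_of_gene = annotation.tu_of_gene
        self.windows: dict[str, IntervalTree] = {}
        self.bodies: dict[str, IntervalTree] = {}
        for gene in annotation.genes.values():
            win = promoter_window(gene, promoter_width_bp, annotation)
            if win is not None:
                self.windows.setdefault(gene.contig, IntervalTree()).addi(
                    win.start, win.end, gene.id
                )
            body = gene.body_interval()
            self.bodies.setdefault(gene.contig, IntervalTree()).addi(
                body.start, body.end, gene.id
            )

    def genes_with_window_at(self, contig: str, pos: int) -> list[Gene]:
        tree = self.windows.get(contig)
        if tree is None:
            return []
        hits = [self.annotation.genes[iv.data] for iv in tree.at(pos)]
        return sorted(hits, key=lambda g: (g.start, g.id))

    def genes_with_body_at(self, contig: str, pos: int) -> list[Gene]:
        tree = self.bodies.get(contig)
        if tree is None:
            return []
        hits = [self.annotation.genes[iv.data] for iv in tree.at(pos)]
        return sorted(hits, key=lambda g: (g.start, g.id))


def _signed_distance(gene: Gene, anchor: int, annotation: GenomeAnnotation) -> int:
    t0 = tss_position(gene, annotation)
    return anchor - t0 if gene.strand == "+" else t0 - anchor


def classify_peak(
    peak: Peak,
    annotation: GenomeAnnotation,
    promoter_width_bp: int = 300,
    index: AnnotationIndex | None = None,
) -> PeakAssignment:
    """Assign one peak to PROMOTER / CDS / INTERGENIC with its target TU(s).

    Promoter takes precedence over CDS. Two divergently transcribed genes
    (minus-strand gene left, plus-strand gene right, both upstream windows
    covering the anchor) share the peak; same-strand multi-window overlaps
    go to the gene with the nearer start codon.
    """
    if index is None:
        index = AnnotationIndex(annotation, promoter_width_bp)
    anchor = peak.anchor
    candidates = index.genes_with_window_at(peak.contig, anchor)
    if candidates:
        if len(candidates) >= 2:
            minus = [g for g in candidates if g.strand == "-"]
            plus = [g for g in candidates if g.strand == "+"]
            div = [
                (gm, gp)
                for gm in minus
                for gp in plus
                if gm.end < gp.start and gm.end <= anchor < gp.start - 1
            ]
            if div:
                gm, gp = min(
                    div, key=lambda pair: abs(_signed_distance(pair[0], anchor, annotation))
                )
                return PeakAssignment(
                    peak_id=peak.id,
                    peak_class=PROMOTER,
                    target_tu_ids=(index.tu_of_gene[gm.id], index.tu_of_gene[gp.id]),
                    target_gene_ids=(gm.id, gp.id),
                    distances_to_anchor=(
                        _signed_distance(gm, anchor, annotation),
                        _signed_distance(gp, anchor, annotation),
                    ),
                )
        target = min(
            candidates, key=lambda g: (abs(_signed_distance(g, anchor, annotation)), g.id)
        )
        return PeakAssignment(
            peak_id=peak.id,
            peak_class=PROMOTER,
            target_tu_ids=(index.tu_of_gene[target.id],),
            target_gene_ids=(target.id,),
            distances_to_anchor=(_signed_distance(target, anchor, annotation),),
        )
    bodies = index.genes_with_body_at(peak.contig, anchor)
    if bodies:
        target = min(
            bodies, key=lambda g: (abs(_signed_distance(g, anchor, annotation)), g.id)
        )
        return PeakAssignment(
            peak_id=peak.id,
            peak_class=CDS,
            target_tu_ids=(index.tu_of_gene[target.id],),
            target_gene_ids=(target.id,),
            distances_to_anchor=(_signed_distance(target, anchor, annotation),),
        )
    return PeakAssignment(peak_id=peak.id, peak_class=INTERGENIC)


def classify_peaks(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    promoter_width_bp: int = 300,
) -> list[PeakAssignment]:
    index = AnnotationIndex(annotation, promoter_width_bp)
    return [classify_peak(p, annotation, promoter_width_bp, index) for p in peaks]


def count_assignments(assignments: Iterable[PeakAssignment]) -> dict[str, int]:
    """Tally peak classes and distinct candidate transcriptional units.

    ``n_tu_candidates`` counts distinct TUs targeted by promoter-class
    assignments; each divergent peak contributes two, so with all targets
    distinct it equals ``n_promoter + n_divergent``.
    """
    n_promoter = n_cds = n_divergent = n_intergenic = 0
    tu_ids: set[str] = set()
    for a in assignments:
        if a.peak_class == PROMOTER:
            n_promoter += 1
            if a.divergent:
                n_divergent += 1
            tu_ids.update(a.target_tu_ids)
        elif a.peak_class == CDS:
            n_cds += 1
        else:
            n_intergenic += 1
    return {
        "n_promoter": n_promoter,
        "n_cds": n_cds,
        "n_divergent": n_divergent,
        "n_intergenic": n_intergenic,
        "n_tu_candidates": len(tu_ids),
    }


def compare_class_enrichment(
    peaks: Sequence[Peak],
    assignments: Sequence[PeakAssignment],
    kind: str = "student",
) -> "_stats.GroupComparison":
    """Two-sample t comparison of fold enrichment: promoter vs CDS peaks."""
    fe = {p.id: p.fold_enrichment for p in peaks}
    promoter = [fe[a.peak_id] for a in assignments if a.peak_class == PROMOTER]
    cds = [fe[a.peak_id] for a in assignments if a.peak_class == CDS]
    if not promoter or not cds:
        raise PeakError("both promoter and CDS classes must be non-empty")
    return _stats.two_sample_t(promoter, cds, kind=kind, names=(PROMOTER, CDS))
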