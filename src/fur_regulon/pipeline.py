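"""End-to-end orchestration: merge -> classify -> integrate -> motif -> stats.

Each stage is a thin composition of library calls; any stage failure aborts
the run but the report written so far is preserved with per-stage status
flags, so partial analyses remain inspectable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as fio
from . import motif as fmotif
from . import peaks as fpeaks
from . import regulon as fregulon
from . import stats as fstats
from .genome import (
    GenomeAnnotation,
    build_transcriptional_units,
    first_gene,
    promoter_window,
    read_annotation,
    read_fasta,
    extract_sequences,
    tss_position,
)

logger = logging.getLogger(__name__)

STAGES = ("load", "merge", "classify", "integrate", "motif", "stats")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run."""

    gff: str
    fasta: str
    peaks_plusfe: str
    peaks_minusfe: str
    deg_tables: dict[str, str]  # comparison_id -> path
    outdir: str = "regulon_out"
    tu_table: str | None = None
    tss_table: str | None = None
    ryhb_genes: str | None = None
    category_map: str | None = None
    promoter_width_bp: int = 300
    max_gap_bp: int = 50
    q_threshold: float = 0.01
    fc_direction: str = "ko_vs_wt"
    motif_width_repressed: int = 19
    motif_width_activated: int = 10
    motif_n_starts: int = 5
    motif_max_iter: int = 200
    test_kind: str = "student"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: dict
    stages: dict[str, str] = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"config": self.config, "stages": self.stages, "results": self.results}


def _promoter_sequences(
    annotation: GenomeAnnotation,
    contigs: dict[str, str],
    tu_ids: list[str],
    width: int,
) -> tuple[dict[str, str], dict[str, float]]:
    """Promoter window sequences of the first genes, with per-TU anchor index.

    Sequences are oriented 5'->3' on the coding strand; the anchor index is
    the 0-based position of the TSS (or start codon) within each sequence,
    so hit centres can be reported relative to it.
    """
    seqs: dict[str, str] = {}
    anchors: dict[str, float] = {}
    for tu_id in tu_ids:
        tu = annotation.tus[tu_id]
        fg = first_gene(tu, annotation)
        win = promoter_window(fg, width, annotation)
        if win is None:
            continue
        seq = extract_sequences(contigs, [win])[0]
        t0 = tss_position(fg, annotation)
        anchor = t0 - win.start if fg.strand == "+" else (win.end - 1) - t0
        seqs[tu_id] = seq
        anchors[tu_id] = float(anchor)
    return seqs, anchors


def run_all(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.as_dict())
    state: dict = {}

    def run_stage(name, fn):
        try:
            fn()
            report.stages[name] = "ok"
        except Exception as exc:
            report.stages[name] = f"failed: {exc}"
            fio.write_json(report.as_dict(), outdir / "report.json")
            raise PipelineError(name, exc) from exc

    def stage_load():
        contigs = read_fasta(config.fasta)
        lengths = {k: len(v) for k, v in contigs.items()}
        annotation = read_annotation(config.gff, contig_lengths=lengths)
        tu_table = fio.read_tu_table(config.tu_table) if config.tu_table else None
        build_transcriptional_units(annotation, tu_table, config.max_gap_bp)
        if config.tss_table:
            annotation.tss = fio.read_tss_table(config.tss_table)
        state["annotation"] = annotation
        state["contigs"] = contigs
        report.results["n_genes"] = len(annotation.genes)
        report.results["n_tus"] = len(annotation.tus)

    def stage_merge():
        plus = fio.read_narrowpeak(config.peaks_plusfe, fpeaks.PLUS_FE)
        minus = fio.read_narrowpeak(config.peaks_minusfe, fpeaks.MINUS_FE)
        merged = fpeaks.merge_condition_peaks(plus, minus)
        state["merged"] = merged
        report.results["n_peaks_plusFe"] = len(plus)
        report.results["n_peaks_minusFe"] = len(minus)
        report.results["n_peaks_merged"] = len(merged)

    def stage_classify():
        annotation = state["annotation"]
        merged = state["merged"]
        assignments = fpeaks.classify_peaks(merged, annotation, config.promoter_width_bp)
        counts = fpeaks.count_assignments(assignments)
        # conservation: every peak lands in exactly one class
        assert counts["n_promoter"] + counts["n_cds"] + counts["n_intergenic"] == len(merged)
        state["assignments"] = assignments
        report.results["assignment_counts"] = counts
        report.results["class_enrichment"] = fpeaks.compare_class_enrichment(
            merged, assignments, kind=config.test_kind
        ).as_dict()
        fio.write_assignments(assignments, merged, outdir / "peak_assignments.tsv")

    def stage_integrate():
        annotation = state["annotation"]
        merged = {p.id: p for p in state["merged"]}
        tables = {
            comp: fio.read_deg_table(path, comp, config.fc_direction)
            for comp, path in config.deg_tables.items()
        }
        missing = {fregulon.WT_VS_KO_PLUSFE, fregulon.WT_VS_KO_MINUSFE} - set(tables)
        if missing:
            raise fregulon.RegulonError(f"missing DEG tables: {sorted(missing)}")
        deg_sets = {
            fregulon.PLUS_FE: fregulon.filter_degs(
                tables[fregulon.WT_VS_KO_PLUSFE], config.q_threshold
            ),
            fregulon.MINUS_FE: fregulon.filter_degs(
                tables[fregulon.WT_VS_KO_MINUSFE], config.q_threshold
            ),
        }
        # bound TUs: best promoter-class peak per targeted unit
        bound: dict[str, str] = {}
        for a in state["assignments"]:
            if a.peak_class != fpeaks.PROMOTER:
                continue
            for tu_id in a.target_tu_ids:
                if (
                    tu_id not in bound
                    or merged[a.peak_id].fold_enrichment
                    > merged[bound[tu_id]].fold_enrichment
                ):
                    bound[tu_id] = a.peak_id
        calls = fregulon.call_direct_targets(
            bound, deg_sets,
            annotation,
            deg_tables={
                fregulon.PLUS_FE: tables[fregulon.WT_VS_KO_PLUSFE],
                fregulon.MINUS_FE: tables[fregulon.WT_VS_KO_MINUSFE],
            },
        )
        summary = fregulon.union_regulon(calls)
        deg_union = set(deg_sets[fregulon.PLUS_FE]) | set(deg_sets[fregulon.MINUS_FE])
        frac = fregulon.direct_deg_fraction(calls, deg_union, annotation)
        summary.n_direct_degs = frac["n_direct_degs"]
        summary.n_total_degs = frac["n_total_degs"]
        summary.direct_fraction_pct = frac["pct"]
        if config.ryhb_genes:
            report.results["external_overlap"] = fregulon.external_regulon_overlap(
                deg_union, fio.read_gene_list(config.ryhb_genes),
                frac["direct_deg_genes"],
            )
        state.update(calls=calls, deg_sets=deg_sets, tables=tables, bound=bound)
        report.results["regulon_summary"] = summary.as_dict()
        fio.write_regulon_calls(calls, outdir / "regulon_calls.tsv")
        fio.write_json(summary.as_dict(), outdir / "regulon_summary.json")

    def stage_motif():
        annotation = state["annotation"]
        calls = state["calls"]
        by_mode = {
            fregulon.REPRESSED: [
                c.tu_id for c in calls
                if c.status == fregulon.DIRECT and c.mode == fregulon.REPRESSED
            ],
            fregulon.ACTIVATED: [
                c.tu_id for c in calls
                if c.status == fregulon.DIRECT and c.mode == fregulon.ACTIVATED
            ],
        }
        widths = {
            fregulon.REPRESSED: config.motif_width_repressed,
            fregulon.ACTIVATED: config.motif_width_activated,
        }
        motifs: dict[str, dict] = {}
        positions: dict[str, list[float]] = {}
        pwms: dict[str, fmotif.Pwm] = {}
        hit_rows = []
        for mode, tu_ids in by_mode.items():
            seqs, anchors = _promoter_sequences(
                annotation, state["contigs"], tu_ids, config.promoter_width_bp
            )
            if len(seqs) < 5:
                logger.warning("motif group %s has %d promoters; skipped", mode, len(seqs))
                continue
            result = fmotif.discover_motif(
                seqs, width=widths[mode], n_starts=config.motif_n_starts,
                seed=config.seed, max_iter=config.motif_max_iter,
            )
            pwms[mode] = result.pwm
            group_positions = []
            for tu_id, seq in seqs.items():
                hit = fmotif.scan_best_site(
                    result.pwm, seq, sequence_id=tu_id,
                    anchor_index=anchors[tu_id],
                )
                group_positions.append(hit.position_vs_anchor)
                hit_rows.append({
                    "tu_id": tu_id, "mode": mode, "offset": hit.offset,
                    "strand": hit.strand, "score": hit.score,
                    "position_vs_anchor": hit.position_vs_anchor,
                })
            positions[mode] = group_positions
            motifs[mode] = {
                "n_sequences": len(seqs),
                "log_likelihood": result.log_likelihood,
                "site_prior": result.site_prior,
                "palindromicity": fmotif.palindromicity(result.pwm),
                **fmotif.consensus_and_ic(result.pwm),
            }
        state["positions"] = positions
        report.results["motifs"] = motifs
        report.results["site_positions"] = fmotif.site_position_summary(positions)
        if pwms:
            with open(outdir / "motifs.meme", "w") as fh:
                fmotif.write_meme_motif(pwms, fh)
        if hit_rows:
            import pandas as pd

            pd.DataFrame(hit_rows).to_csv(outdir / "site_hits.tsv", sep="\t", index=False)

    def stage_stats():
        annotation = state["annotation"]
        calls = state["calls"]
        merged = {p.id: p for p in state["merged"]}
        tables = state["tables"]
        direct = [c for c in calls if c.status == fregulon.DIRECT]
        fe_by_mode = {
            mode: [
                merged[c.peak_id].fold_enrichment
                for c in direct if c.mode == mode and c.peak_id
            ]
            for mode in (fregulon.REPRESSED, fregulon.ACTIVATED)
        }
        if all(len(v) >= 2 for v in fe_by_mode.values()):
            report.results["mode_enrichment"] = fstats.two_sample_t(
                fe_by_mode[fregulon.REPRESSED], fe_by_mode[fregulon.ACTIVATED],
                kind=config.test_kind,
                names=(fregulon.REPRESSED, fregulon.ACTIVATED),
            ).as_dict()
        abs_fc = {}
        for mode in (fregulon.REPRESSED, fregulon.ACTIVATED):
            fcs = [
                c.log2fc_plusfe for c in direct
                if c.mode == mode and c.log2fc_plusfe is not None
            ]
            if len(fcs) >= 2:
                abs_fc[mode] = fstats.mean_abs_fc(fcs)
        report.results["abs_fold_change"] = abs_fc

        deg_sets = state["deg_sets"]
        pairs_by_mode: dict[str, list[tuple[float, float]]] = {}
        for c in direct:
            gid = c.first_gene_id
            if gid in deg_sets[fregulon.PLUS_FE] and gid in deg_sets[fregulon.MINUS_FE]:
                pairs_by_mode.setdefault(c.mode, []).append(
                    (c.log2fc_minusfe, c.log2fc_plusfe)
                )
        report.results["iron_sensitivity"] = {
            mode: fstats.fc_sensitivity_summary(pairs)
            for mode, pairs in pairs_by_mode.items()
        }

        xy = [
            (2.0 ** abs(c.log2fc_plusfe), merged[c.peak_id].fold_enrichment)
            for c in direct
            if c.log2fc_plusfe is not None and c.peak_id
        ]
        if len(xy) >= 3:
            report.results["fc_binding_regression"] = fstats.fc_binding_regression(
                [p[0] for p in xy], [p[1] for p in xy]
            ).as_dict()

        if config.category_map:
            cats = fio.read_category_map(config.category_map)
            report.results["category_tally"] = fstats.functional_tally(
                [c.first_gene_id for c in direct], cats
            ).as_dict()

    for name, fn in zip(
        STAGES,
        (stage_load, stage_merge, stage_classify, stage_integrate, stage_motif, stage_stats),
    ):
        run_stage(name, fn)

    fio.write_json(report.as_dict(), outdir / "report.json")
    return report


def run_on_dataset(dataset_dir: str | Path, outdir: str | Path, seed: int = 0,
                   **overrides) -> RunReport:
    """Convenience: run the full pipeline on a generated dataset directory."""
    d = Path(dataset_dir)
    config = RunConfig(
        gff=str(d / "genome.gff"),
        fasta=str(d / "genome.fasta"),
        peaks_plusfe=str(d / "peaks_plusFe.narrowPeak"),
        peaks_minusfe=str(d / "peaks_minusFe.narrowPeak"),
        deg_tables={
            comp: str(d / f"deg_{comp}.tsv") for comp in fregulon.COMPARISONS
        },
        tu_table=str(d / "tus.tsv"),
        tss_table=str(d / "tss.tsv"),
        ryhb_genes=str(d / "ryhb_targets.tsv"),
        category_map=str(d / "categories.tsv"),
        outdir=str(outdir),
        seed=seed,
        **overrides,
    )
    return run_all(config)
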