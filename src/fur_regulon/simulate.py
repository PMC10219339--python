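"""Forward simulation of a toy bacterial genome with a planted iron regulon.

The generator emits exactly the files the pipeline consumes — GFF3 genes,
FASTA sequence, a transcriptional-unit table, a TSS table, two
condition-specific narrowPeak tables, four differential-expression tables,
an external (small-RNA) regulon gene list and a functional-category map —
together with a truth manifest recording what was planted, so recovery can
be scored exactly.

The planted structure mirrors the qualitative contrasts of a
repressor-dominated iron regulon:

* promoter peaks are stronger than CDS decoy peaks, and peaks on repressed
  units stronger than on activated units (lognormal fold enrichments);
* repressed units carry a near-palindromic 19-bp site centred ~-20 bp from
  the TSS, activated units a shorter asymmetric site centred ~-74 bp;
* repressed targets respond more strongly to the knockout with iron than
  without, activated targets respond similarly in both conditions;
* the knockout strain shows no iron response at all (its +/- iron
  comparison is pure null).

The planted motif strings are synthetic fixtures chosen for their shape
(length, AT richness, dyad symmetry), not measured consensus sequences.
Every output is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptionalUnit,
    build_transcriptional_units,
    first_gene,
    promoter_window,
)
from .motif import revcomp
from .regulon import (
    KO_FE_VS_NOFE,
    WT_FE_VS_NOFE,
    WT_VS_KO_MINUSFE,
    WT_VS_KO_PLUSFE,
    RegulonCall,
    DIRECT,
)

CATEGORIES = (
    "Iron homeostasis", "Carbon metabolism", "Respiration", "Motility",
    "SOS response", "Transporter", "Biosynthesis", "TF", "Translation",
    "Phage", "Function unknown",
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the planted-regulon simulation (defaults define the benchmark)."""

    seed: int = 0
    # genome layout
    n_tus: int = 200
    genes_per_tu_probs: tuple[float, ...] = (0.6, 0.2, 0.12, 0.08)  # P(1..4 genes)
    gene_length_range: tuple[int, int] = (600, 1800)
    intra_tu_gap_range: tuple[int, int] = (5, 50)
    intergenic_gap_range: tuple[int, int] = (400, 800)
    divergent_gap_range: tuple[int, int] = (150, 250)
    utr_length_range: tuple[int, int] = (20, 40)  # TSS upstream of start codon
    contig_name: str = "chr"
    contig_length_bp: int = 1_200_000
    # regulon structure
    fraction_bound: float = 0.45
    fraction_direct_of_bound: float = 0.65
    repressed_to_activated: float = 3.0
    n_divergent_pairs: int = 10
    # binding strength (lognormal: exp(N(log_mean, log_sd)))
    fe_promoter_log_mean: float = 1.4
    fe_promoter_log_sd: float = 0.4
    fe_cds_log_mean: float = 0.7
    fe_cds_log_sd: float = 0.4
    fe_repressed_multiplier: float = 2.0
    fe_condition_jitter_sd: float = 0.15
    cds_decoy_count: int = 55
    both_condition_fraction: float = 0.8
    peak_half_width: int = 75
    summit_jitter_sd: float = 3.0
    # site geometry (bp relative to TSS, negative upstream)
    site_centre_repressed: float = -20.0
    site_sd_repressed: float = 10.0
    site_centre_activated: float = -74.0
    site_sd_activated: float = 15.0
    motif_repressed: str = "GATAATGATTATCATTATC"  # synthetic 19-bp near-palindrome
    motif_activated: str = "TTGAATAATA"  # synthetic 10-bp asymmetric
    motif_mutation_rate: float = 0.05
    # expression effects, log2(knockout / wild-type)
    effect_repressed_mean: float = 3.0
    effect_repressed_sd: float = 0.8
    effect_repressed_min: float = 1.5
    effect_activated_mean: float = 1.6
    effect_activated_sd: float = 0.4
    effect_activated_min: float = 0.8
    minusfe_attenuation_range: tuple[float, float] = (0.3, 0.6)
    activated_condition_jitter_sd: float = 0.1
    minusfe_evidence_fraction: float = 0.3
    wt_iron_response_fraction: float = 0.5
    member_effect_jitter_sd: float = 0.1
    # indirect regulation and q-value model
    indirect_fraction: float = 0.5
    ryhb_indirect_fraction: float = 0.25
    ryhb_dual_fraction: float = 0.2
    noise_sd: float = 0.2
    deg_q_range: tuple[float, float] = (1e-6, 0.005)
    null_q_range: tuple[float, float] = (0.02, 1.0)
    ko_null_q_range: tuple[float, float] = (0.5, 1.0)
    # category structure
    iron_homeostasis_share: float = 0.30

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def run_id(self) -> str:
        digest = hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
        return f"sim-{self.seed}-{digest}"


@dataclass
class TruthManifest:
    """What was planted, per transcriptional unit and per gene."""

    run_id: str
    config: dict
    tus: dict[str, dict] = field(default_factory=dict)
    genes: dict[str, dict] = field(default_factory=dict)

    def direct_tu_ids(self) -> set[str]:
        return {t for t, rec in self.tus.items() if rec["direct"]}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def load_truth(path: str | Path) -> TruthManifest:
    data = json.loads(Path(path).read_text())
    return TruthManifest(**data)


@dataclass
class GenomeSim:
    """In-memory simulation state shared by the generator stages."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    truth: TruthManifest
    tss_rows: list[tuple[str, int, str]]
    decoy_genes: list[str] = field(default_factory=list)
    tu_rows: list[tuple[str, str]] = field(default_factory=list)
    divergent_partners: list[tuple[str, str]] = field(default_factory=list)
    peak_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None
    deg_tables: dict[str, pd.DataFrame] | None = None


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = []
    for c in motif:
        if rng.random() < rate:
            out.append(bases[rng.integers(4)])
        else:
            out.append(c)
    return "".join(out)


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, minimum: float
) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= minimum:
            return float(x)
    return float(minimum)


def generate_genome(
    config: SimulationConfig, with_sequence: bool = True
) -> GenomeSim:
    """Lay out the genome, assign the planted regulon, plant motif instances.

    ``with_sequence=False`` skips FASTA-scale sequence generation for
    cheap repeated truth-level sampling.
    """
    rng = _rng(config, 0)
    n_pairs = min(config.n_divergent_pairs, config.n_tus // 2)

    # --- block layout: divergent pairs plus single TUs, shuffled ---
    n_singles = config.n_tus - 2 * n_pairs
    blocks = ["pair"] * n_pairs + ["single"] * n_singles
    rng.shuffle(blocks)

    genes: dict[str, Gene] = {}
    tu_rows: list[tuple[str, str]] = []  # (unit_id, gene_id) ordered 5'->3'
    tss_rows: list[tuple[str, int, str]] = []
    tu_meta: dict[str, dict] = {}
    divergent_partners: list[tuple[str, str]] = []
    contig = config.contig_name
    gene_counter = 0
    cursor = int(rng.integers(*config.intergenic_gap_range))

    def new_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:04d}"

    def lay_tu(strand: str, left: int) -> tuple[str, int]:
        """Place one TU with its leftmost base at ``left``; returns (id, right end)."""
        n_genes = 1 + rng.choice(
            len(config.genes_per_tu_probs), p=config.genes_per_tu_probs
        )
        pos = left
        members: list[Gene] = []
        for k in range(n_genes):
            length = int(rng.integers(*config.gene_length_range))
            g = Gene(
                id=new_gene_id(), contig=contig, start=pos + 1,
                end=pos + length, strand=strand,
            )
            members.append(g)
            pos += length
            if k < n_genes - 1:
                pos += int(rng.integers(*config.intra_tu_gap_range))
        ordered = members if strand == "+" else members[::-1]
        tu_id = f"tu_{ordered[0].id}"
        for g in members:
            genes[g.id] = g
        for g in ordered:
            tu_rows.append((tu_id, g.id))
        fg = ordered[0]
        utr = int(rng.integers(*config.utr_length_range))
        tss = fg.start - utr if strand == "+" else fg.end + utr
        tss_rows.append((fg.id, tss, strand))
        tu_meta[tu_id] = {"first_gene_id": fg.id, "strand": strand, "tss": tss}
        return tu_id, pos

    for block in blocks:
        if block == "single":
            strand = "+" if rng.random() < 0.5 else "-"
            _, cursor = lay_tu(strand, cursor)
        else:
            left_id, cursor = lay_tu("-", cursor)
            cursor += int(rng.integers(*config.divergent_gap_range))
            right_id, cursor = lay_tu("+", cursor)
            divergent_partners.append((left_id, right_id))
        cursor += int(rng.integers(*config.intergenic_gap_range))

    required = cursor + max(config.intergenic_gap_range)
    if required > config.contig_length_bp:
        raise SimulationError(
            f"contig_length_bp too short: need at least {required} bp"
        )

    annotation = GenomeAnnotation(
        contigs={contig: config.contig_length_bp}, genes=genes
    )
    build_transcriptional_units(annotation, tu_table=tu_rows or [])
    annotation.tss = {g: t for g, t, _ in tss_rows}

    # --- planted regulon assignment ---
    truth = TruthManifest(run_id=config.run_id(), config=config.as_dict())
    divergent_ids = {t for pair in divergent_partners for t in pair}
    single_ids = [t for t in annotation.tus if t not in divergent_ids]
    rng.shuffle(single_ids)

    n_bound = round(config.fraction_bound * config.n_tus)
    n_bound_singles = max(0, n_bound - len(divergent_ids))
    bound_singles = single_ids[:n_bound_singles]
    n_direct = round(config.fraction_direct_of_bound * n_bound)
    n_direct = min(n_direct, len(bound_singles))
    direct_ids = bound_singles[:n_direct]
    r = config.repressed_to_activated
    n_repressed = round(n_direct * r / (r + 1.0))
    modes = {t: ("REPRESSED" if i < n_repressed else "ACTIVATED")
             for i, t in enumerate(direct_ids)}

    partner_of = {}
    for a, b in divergent_partners:
        partner_of[a], partner_of[b] = b, a

    for tu_id, tu in annotation.tus.items():
        meta = tu_meta[tu_id]
        bound = tu_id in divergent_ids or tu_id in bound_singles
        direct = tu_id in modes
        mode = modes.get(tu_id, "NA")
        site_offset = None
        if bound and tu_id not in divergent_ids:
            if mode == "REPRESSED":
                centre, sd = config.site_centre_repressed, config.site_sd_repressed
            elif mode == "ACTIVATED":
                centre, sd = config.site_centre_activated, config.site_sd_activated
            else:  # bound but silent promoters still carry a (repressor-like) site
                centre, sd = -35.0, 20.0
            w = len(
                config.motif_repressed if mode != "ACTIVATED" else config.motif_activated
            )
            utr = abs(meta["tss"] - (
                annotation.genes[meta["first_gene_id"]].start
                if meta["strand"] == "+"
                else annotation.genes[meta["first_gene_id"]].end
            ))
            # keep the whole site inside the promoter window
            lo = -(280 - utr) + w
            hi = -(w // 2 + 2)
            site_offset = float(np.clip(round(rng.normal(centre, sd)), lo, hi))
        truth.tus[tu_id] = {
            "first_gene_id": meta["first_gene_id"],
            "strand": meta["strand"],
            "tss": meta["tss"],
            "bound": bool(bound),
            "direct": bool(direct),
            "mode": mode,
            "divergent_partner": partner_of.get(tu_id),
            "site_offset_vs_tss": site_offset,
            "site_genomic_centre": None,
            "fe_plusfe": None,
            "fe_minusfe": None,
            "peak_conditions": None,
        }

    # --- sequence with planted motif instances ---
    sequences: dict[str, str] = {}
    if with_sequence:
        rng_seq = _rng(config, 1)
        arr = rng_seq.integers(0, 4, size=config.contig_length_bp, dtype=np.int8)
        for tu_id, rec in truth.tus.items():
            centre = _site_genomic_centre(rec)
            if centre is None:
                continue
            rec["site_genomic_centre"] = centre
            motif = (
                config.motif_activated
                if rec["mode"] == "ACTIVATED"
                else config.motif_repressed
            )
            inst = _mutate(motif, config.motif_mutation_rate, rng_seq)
            if rec["strand"] == "-":
                inst = revcomp(inst)
            start = centre - len(inst) // 2
            enc = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in inst],
                           dtype=np.int8)
            arr[start : start + len(inst)] = enc
        # divergent shared sites sit mid-gap, planted once per pair
        rng_div = _rng(config, 4)
        for left_id, right_id in divergent_partners:
            centre = _divergent_centre(truth, annotation, left_id, right_id)
            inst = _mutate(config.motif_repressed, config.motif_mutation_rate, rng_div)
            start = centre - len(inst) // 2
            enc = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in inst],
                           dtype=np.int8)
            arr[start : start + len(inst)] = enc
            truth.tus[left_id]["site_genomic_centre"] = centre
            truth.tus[right_id]["site_genomic_centre"] = centre
        sequences[contig] = "".join("ACGT"[b] for b in arr)
    else:
        for tu_id, rec in truth.tus.items():
            rec["site_genomic_centre"] = _site_genomic_centre(rec)
        for left_id, right_id in divergent_partners:
            centre = _divergent_centre(truth, annotation, left_id, right_id)
            truth.tus[left_id]["site_genomic_centre"] = centre
            truth.tus[right_id]["site_genomic_centre"] = centre

    return GenomeSim(
        config=config, annotation=annotation, sequences=sequences,
        truth=truth, tss_rows=tss_rows, tu_rows=tu_rows,
        divergent_partners=divergent_partners,
    )


def _site_genomic_centre(rec: dict) -> int | None:
    off = rec["site_offset_vs_tss"]
    if off is None:
        return None
    tss0 = rec["tss"] - 1
    return int(tss0 + off) if rec["strand"] == "+" else int(tss0 - off)


def _divergent_centre(
    truth: TruthManifest, annotation: GenomeAnnotation, left_id: str, right_id: str
) -> int:
    left_first = annotation.genes[truth.tus[left_id]["first_gene_id"]]
    right_first = annotation.genes[truth.tus[right_id]["first_gene_id"]]
    return (left_first.end + (right_first.start - 1)) // 2


NARROWPEAK_COLUMNS = (
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
)


def generate_peaks(
    sim: GenomeSim, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two condition-specific narrowPeak tables for the planted binding sites.

    Bound TUs get promoter peaks centred on their planted sites (one shared
    peak per divergent pair); decoy peaks are dropped into gene bodies. Fold
    enrichments are lognormal per class, with the repressed multiplier on
    repressed targets; a configurable fraction of peaks appears in both
    conditions, the rest in only one.
    """
    config = config or sim.config
    rng = _rng(config, 2)
    ann = sim.annotation
    contig = config.contig_name
    rows: list[dict] = []
    counter = 0

    def add_peak(summit: int, base_log_mean: float, log_sd: float, kind: str,
                 window: GenomicInterval | None = None) -> dict:
        nonlocal counter
        counter += 1
        if window is not None:
            summit = int(np.clip(summit, window.start + 1, window.end - 2))
        start = max(0, summit - config.peak_half_width)
        end = min(config.contig_length_bp, summit + config.peak_half_width)
        both = rng.random() < config.both_condition_fraction
        conds = ("plusFe", "minusFe") if both else (
            ("plusFe",) if rng.random() < 0.5 else ("minusFe",)
        )
        fes = {}
        for cond in conds:
            fes[cond] = float(np.exp(
                rng.normal(base_log_mean, log_sd)
                + rng.normal(0.0, config.fe_condition_jitter_sd)
            ))
        for cond in conds:
            rows.append({
                "chrom": contig, "chromStart": start, "chromEnd": end,
                "name": f"{kind}_{counter:04d}_{cond}", "score": 0, "strand": ".",
                "signalValue": round(fes[cond], 4), "pValue": -1, "qValue": -1,
                "peak": summit - start, "condition": cond,
            })
        return {"conditions": conds, "fes": fes}

    seen_pairs: set[str] = set()
    for tu_id, rec in sim.truth.tus.items():
        if not rec["bound"]:
            continue
        if rec["divergent_partner"] is not None:
            if tu_id in seen_pairs:
                continue
            seen_pairs.update({tu_id, rec["divergent_partner"]})
            centre = rec["site_genomic_centre"]
            summit = int(round(centre + rng.normal(0, config.summit_jitter_sd)))
            fg = ann.genes[rec["first_gene_id"]]
            partner_fg = ann.genes[
                sim.truth.tus[rec["divergent_partner"]]["first_gene_id"]
            ]
            left, right = sorted([fg, partner_fg], key=lambda g: g.start)
            window = GenomicInterval(contig, left.end, right.start - 1)
            info = add_peak(
                summit, config.fe_promoter_log_mean, config.fe_promoter_log_sd,
                "div", window,
            )
            for t in (tu_id, rec["divergent_partner"]):
                sim.truth.tus[t]["peak_conditions"] = list(info["conditions"])
                sim.truth.tus[t]["fe_plusfe"] = info["fes"].get("plusFe")
                sim.truth.tus[t]["fe_minusfe"] = info["fes"].get("minusFe")
            continue
        fg = ann.genes[rec["first_gene_id"]]
        window = promoter_window(fg, 300, ann)
        centre = rec["site_genomic_centre"]
        summit = int(round(centre + rng.normal(0, config.summit_jitter_sd)))
        log_mean = config.fe_promoter_log_mean
        if rec["mode"] == "REPRESSED":
            log_mean += float(np.log(config.fe_repressed_multiplier))
        info = add_peak(summit, log_mean, config.fe_promoter_log_sd, "prom", window)
        rec["peak_conditions"] = list(info["conditions"])
        rec["fe_plusfe"] = info["fes"].get("plusFe")
        rec["fe_minusfe"] = info["fes"].get("minusFe")

    # CDS decoys: planted in the rightmost gene of a TU, deep enough into the
    # body that no neighbouring promoter window can reach them
    tu_ids = sorted(ann.tus)
    n_decoys = min(config.cds_decoy_count, len(tu_ids))
    decoy_tus = rng.choice(tu_ids, size=n_decoys, replace=False) if n_decoys else []
    for tu_id in decoy_tus:
        tu = ann.tus[tu_id]
        host = max((ann.genes[g] for g in tu.gene_ids), key=lambda g: g.end)
        frac = rng.uniform(0.55, 0.8)
        summit = int(host.start - 1 + frac * host.length)
        add_peak(summit, config.fe_cds_log_mean, config.fe_cds_log_sd, "cds")
        sim.decoy_genes.append(host.id)

    df = pd.DataFrame(rows, columns=list(NARROWPEAK_COLUMNS) + ["condition"])
    plus = df[df.condition == "plusFe"][list(NARROWPEAK_COLUMNS)].reset_index(drop=True)
    minus = df[df.condition == "minusFe"][list(NARROWPEAK_COLUMNS)].reset_index(drop=True)
    return plus, minus


def generate_deg_tables(
    sim: GenomeSim, config: SimulationConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Four DEG tables keyed by comparison id, filling per-gene truth.

    Fold changes in the WT-vs-KO tables are log2(knockout / wild-type):
    positive for repressed targets, negative for activated ones. The
    knockout's own iron comparison is pure null by construction.
    """
    config = config or sim.config
    rng = _rng(config, 3)
    ann = sim.annotation

    def null_record() -> tuple[float, float]:
        return float(rng.normal(0, config.noise_sd)), float(rng.uniform(*config.null_q_range))

    def deg_q() -> float:
        return float(rng.uniform(*config.deg_q_range))

    # per-TU effect draws
    tu_effects: dict[str, dict] = {}
    for tu_id, rec in sim.truth.tus.items():
        if not rec["direct"]:
            continue
        if rec["mode"] == "REPRESSED":
            mag = _truncnorm(rng, config.effect_repressed_mean,
                             config.effect_repressed_sd, config.effect_repressed_min)
            mag_minus = mag * rng.uniform(*config.minusfe_attenuation_range)
            sign = 1.0
        else:
            mag = _truncnorm(rng, config.effect_activated_mean,
                             config.effect_activated_sd, config.effect_activated_min)
            mag_minus = abs(mag + rng.normal(0, config.activated_condition_jitter_sd))
            sign = -1.0
        tu_effects[tu_id] = {
            "plus": sign * mag,
            "minus": sign * mag_minus,
            "deg_minus": bool(rng.random() < config.minusfe_evidence_fraction),
            "wt_iron": bool(
                rec["mode"] == "REPRESSED"
                and rng.random() < config.wt_iron_response_fraction
            ),
        }
        rec["effect_log2fc_plusfe"] = tu_effects[tu_id]["plus"]
        rec["effect_log2fc_minusfe"] = tu_effects[tu_id]["minus"]
        rec["deg_minusfe"] = tu_effects[tu_id]["deg_minus"]

    # indirect targets: unbound TUs whose genes respond without binding
    unbound = sorted(
        t for t, rec in sim.truth.tus.items() if not rec["bound"]
    )
    rng.shuffle(unbound)
    n_indirect = round(config.indirect_fraction * len(unbound))
    indirect = set(unbound[:n_indirect])
    indirect_effects = {
        t: float(rng.choice([-1, 1]) * _truncnorm(rng, 1.5, 0.5, 0.8))
        for t in indirect
    }

    records: dict[str, dict[str, tuple[float, float]]] = {
        c: {} for c in (WT_FE_VS_NOFE, KO_FE_VS_NOFE, WT_VS_KO_PLUSFE, WT_VS_KO_MINUSFE)
    }
    for tu_id, tu in ann.tus.items():
        rec = sim.truth.tus[tu_id]
        eff = tu_effects.get(tu_id)
        ind = indirect_effects.get(tu_id)
        for gid in tu.gene_ids:
            jitter = rng.normal(0, config.member_effect_jitter_sd)
            if eff is not None:
                fc_plus = eff["plus"] + jitter
                fc_minus = eff["minus"] + jitter
                records[WT_VS_KO_PLUSFE][gid] = (fc_plus, deg_q())
                records[WT_VS_KO_MINUSFE][gid] = (
                    fc_minus,
                    deg_q() if eff["deg_minus"] else float(rng.uniform(*config.null_q_range)),
                )
                if eff["wt_iron"]:
                    # iron represses these genes in the wild type
                    records[WT_FE_VS_NOFE][gid] = (-abs(fc_plus), deg_q())
                else:
                    records[WT_FE_VS_NOFE][gid] = null_record()
            elif ind is not None:
                records[WT_VS_KO_PLUSFE][gid] = (ind + jitter, deg_q())
                records[WT_VS_KO_MINUSFE][gid] = (
                    (ind + jitter) * 0.8,
                    deg_q() if rng.random() < config.minusfe_evidence_fraction
                    else float(rng.uniform(*config.null_q_range)),
                )
                records[WT_FE_VS_NOFE][gid] = null_record()
            else:
                records[WT_VS_KO_PLUSFE][gid] = null_record()
                records[WT_VS_KO_MINUSFE][gid] = null_record()
                records[WT_FE_VS_NOFE][gid] = null_record()
            records[KO_FE_VS_NOFE][gid] = (
                float(rng.normal(0, config.noise_sd)),
                float(rng.uniform(*config.ko_null_q_range)),
            )

    # per-gene truth: DEG status per comparison
    for gid in ann.genes:
        gene_truth = {"ryhb": False, "category": None}
        for comp, table in records.items():
            fc, q = table[gid]
            gene_truth[f"deg_{comp}"] = bool(q < 0.01 and fc != 0)
            gene_truth[f"log2fc_{comp}"] = fc
        sim.truth.genes[gid] = gene_truth

    # external small-RNA regulon: some indirect DEGs, some dual-control genes
    for tu_id in indirect:
        for gid in ann.tus[tu_id].gene_ids:
            if rng.random() < config.ryhb_indirect_fraction:
                sim.truth.genes[gid]["ryhb"] = True
    for tu_id in tu_effects:
        for gid in ann.tus[tu_id].gene_ids:
            if rng.random() < config.ryhb_dual_fraction:
                sim.truth.genes[gid]["ryhb"] = True

    # functional categories keyed by first gene
    rng_cat = _rng(config, 5)
    others = [c for c in CATEGORIES if c != "Iron homeostasis"]
    for tu_id, tu in ann.tus.items():
        fg = first_gene(tu, ann)
        if sim.truth.tus[tu_id]["direct"] and rng_cat.random() < config.iron_homeostasis_share:
            cat = "Iron homeostasis"
        else:
            cat = str(rng_cat.choice(others))
        for gid in tu.gene_ids:
            sim.truth.genes[gid]["category"] = (
                cat if gid == fg.id else str(rng_cat.choice(CATEGORIES))
            )

    out = {}
    for comp, table in records.items():
        out[comp] = pd.DataFrame(
            [(g, fc, q) for g, (fc, q) in sorted(table.items())],
            columns=["gene_id", "log2fc", "qvalue"],
        )
    return out


def write_dataset(
    sim: GenomeSim,
    peak_tables: tuple[pd.DataFrame, pd.DataFrame],
    deg_tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
) -> Path:
    """Write every pipeline input plus the truth manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig = sim.config.contig_name

    with open(outdir / "genome.fasta", "w") as fh:
        for name, seq in sim.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(outdir / "genome.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {sim.config.contig_length_bp}\n")
        for gene in sim.annotation.genes_on(contig):
            fh.write(
                f"{contig}\tsim\tgene\t{gene.start}\t{gene.end}\t.\t{gene.strand}"
                f"\t.\tID={gene.id}\n"
            )

    tu_rows = sim.tu_rows
    with open(outdir / "tus.tsv", "w") as fh:
        fh.write("unit_id\tgene_id\trank\n")
        rank: dict[str, int] = {}
        for unit_id, gene_id in tu_rows:
            rank[unit_id] = rank.get(unit_id, 0) + 1
            fh.write(f"{unit_id}\t{gene_id}\t{rank[unit_id]}\n")

    with open(outdir / "tss.tsv", "w") as fh:
        fh.write("gene_id\ttss_1based\tstrand\n")
        for gid, tss, strand in sim.tss_rows:
            fh.write(f"{gid}\t{tss}\t{strand}\n")

    plus, minus = peak_tables
    plus.to_csv(outdir / "peaks_plusFe.narrowPeak", sep="\t", header=False, index=False)
    minus.to_csv(outdir / "peaks_minusFe.narrowPeak", sep="\t", header=False, index=False)

    for comp, df in deg_tables.items():
        path = outdir / f"deg_{comp}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# comparison_id={comp}\tfc_direction=ko_vs_wt\n")
            df.to_csv(fh, sep="\t", index=False)

    ryhb = sorted(g for g, rec in sim.truth.genes.items() if rec["ryhb"])
    with open(outdir / "ryhb_targets.tsv", "w") as fh:
        fh.write("gene_id\n")
        fh.writelines(g + "\n" for g in ryhb)

    with open(outdir / "categories.tsv", "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gid in sorted(sim.truth.genes):
            fh.write(f"{gid}\t{sim.truth.genes[gid]['category']}\n")

    sim.truth.to_json(outdir / "truth_manifest.json")
    (outdir / "config.json").write_text(json.dumps(sim.config.as_dict(), indent=1))
    return outdir


def simulate_dataset(
    config: SimulationConfig | None = None, outdir: str | Path | None = None
) -> GenomeSim:
    """Run all generator stages; optionally write the dataset to disk."""
    config = config or SimulationConfig()
    sim = generate_genome(config, with_sequence=True)
    peaks = generate_peaks(sim)
    degs = generate_deg_tables(sim)
    if outdir is not None:
        write_dataset(sim, peaks, degs, outdir)
    sim.peak_tables = peaks
    sim.deg_tables = degs
    return sim


def score_against_truth(
    calls: Sequence[RegulonCall],
    truth: TruthManifest,
    run_id: str | None = None,
) -> dict:
    """Confusion summary of DIRECT calls and modes against the manifest.

    Precision with zero calls is reported as 1.0 with an ``n_called`` flag
    (no false claims were made).
    """
    if run_id is not None and run_id != truth.run_id:
        raise SimulationError(
            f"manifest run id {truth.run_id!r} does not match {run_id!r}"
        )
    called = {c.tu_id: c for c in calls if c.status == DIRECT}
    true_direct = truth.direct_tu_ids()
    tp = set(called) & true_direct
    fp = set(called) - true_direct
    fn = true_direct - set(called)
    mode_correct = sum(
        1 for t in tp if called[t].mode == truth.tus[t]["mode"]
    )
    return {
        "n_called": len(called),
        "n_true": len(true_direct),
        "tp": len(tp),
        "fp": len(fp),
        "fn": len(fn),
        "precision": len(tp) / len(called) if called else 1.0,
        "recall": len(tp) / len(true_direct) if true_direct else 1.0,
        "mode_accuracy": mode_correct / len(tp) if tp else 1.0,
    }
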