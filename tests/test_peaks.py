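"""Peak merging, promoter/CDS classification, and class-level statistics."""

import numpy as np
import pytest

from fur_regulon.genome import Gene, GenomicInterval
from fur_regulon.peaks import (
    CDS,
    INTERGENIC,
    MINUS_FE,
    PLUS_FE,
    PROMOTER,
    Peak,
    PeakAssignment,
    PeakError,
    classify_peak,
    classify_peaks,
    compare_class_enrichment,
    count_assignments,
    merge_condition_peaks,
)
from .conftest import make_annotation


def mk_peak(pid, start, end, fe, cond=PLUS_FE, summit=None, contig="chr"):
    return Peak(
        id=pid, contig=contig, interval=GenomicInterval(contig, start, end),
        fold_enrichment=fe, conditions=frozenset({cond}), summit=summit,
    )


class TestMergeConditionPeaks:
    def test_overlapping_pair_merges_to_union_and_mean(self):
        plus = [mk_peak("p1", 100, 200, 4.0, PLUS_FE)]
        minus = [mk_peak("m1", 150, 250, 6.0, MINUS_FE)]
        (merged,) = merge_condition_peaks(plus, minus)
        assert (merged.interval.start, merged.interval.end) == (100, 250)
        assert merged.fold_enrichment == pytest.approx(5.0)
        assert merged.conditions == frozenset({PLUS_FE, MINUS_FE})

    def test_single_condition_peak_passes_through(self):
        (out,) = merge_condition_peaks([mk_peak("p1", 10, 20, 3.0)], [])
        assert out.id == "p1"
        assert out.conditions == frozenset({PLUS_FE})

    def test_disjoint_peaks_all_pass_through(self):
        plus = [mk_peak(f"p{i}", 100 * i, 100 * i + 50, 2.0) for i in range(1, 4)]
        minus = [
            mk_peak(f"m{i}", 1000 + 100 * i, 1000 + 100 * i + 50, 2.0, MINUS_FE)
            for i in range(2)
        ]
        out = merge_condition_peaks(plus, minus)
        # oracle: brute-force all-pairs overlap check finds none
        assert not any(
            p.interval.overlap(m.interval) > 0 for p in plus for m in minus
        )
        assert len(out) == 5

    def test_nonpositive_fold_enrichment_rejected(self):
        with pytest.raises(PeakError, match="positive"):
            mk_peak("bad", 0, 10, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_conserves_evidence(self, seed):
        # peaks placed in disjoint slots; a planted subset of slots carries
        # one peak from each condition, guaranteeing one-to-one matches
        rng = np.random.default_rng(seed)
        plus, minus, n_pairs = [], [], 0
        for slot in range(20):
            base = slot * 500
            kind = rng.integers(4)
            if kind == 0:
                plus.append(mk_peak(f"p{slot}", base, base + 100, 2.0))
            elif kind == 1:
                minus.append(mk_peak(f"m{slot}", base, base + 100, 3.0, MINUS_FE))
            elif kind == 2:
                plus.append(mk_peak(f"p{slot}", base, base + 100, 2.0))
                minus.append(mk_peak(f"m{slot}", base + 50, base + 150, 3.0, MINUS_FE))
                n_pairs += 1
        out = merge_condition_peaks(plus, minus)
        assert len(out) == len(plus) + len(minus) - n_pairs

    def test_merged_fe_between_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            fe_a, fe_b = rng.uniform(0.5, 20, size=2)
            (m,) = merge_condition_peaks(
                [mk_peak("a", 0, 100, fe_a)], [mk_peak("b", 50, 150, fe_b, MINUS_FE)]
            )
            assert min(fe_a, fe_b) <= m.fold_enrichment <= max(fe_a, fe_b)


@pytest.fixture
def classify_annotation():
    genes = [
        Gene("up", "chr", 1001, 1600, "+"),     # window [700, 1000)
        Gene("body", "chr", 3001, 4200, "+"),   # window [2700, 3000)
        Gene("left", "chr", 4900, 5400, "-"),   # window [5400, 5700)
        Gene("right", "chr", 5601, 6200, "+"),  # window [5300, 5600)
    ]
    return make_annotation(genes, contig_len=10_000, max_gap_bp=0)


class TestClassifyPeak:
    def test_summit_in_promoter_window(self, classify_annotation):
        a = classify_peak(mk_peak("p", 800, 900, 2.0, summit=850), classify_annotation)
        assert a.peak_class == PROMOTER
        assert a.target_gene_ids == ("up",)
        assert a.distances_to_anchor == (-150,)

    def test_summit_in_gene_body_is_cds(self, classify_annotation):
        a = classify_peak(mk_peak("p", 3500, 3700, 2.0, summit=3600), classify_annotation)
        assert a.peak_class == CDS
        assert a.target_gene_ids == ("body",)

    def test_divergent_intergenic_summit_targets_both(self, classify_annotation):
        a = classify_peak(mk_peak("p", 5440, 5560, 2.0, summit=5500), classify_annotation)
        assert a.peak_class == PROMOTER
        assert a.divergent
        assert set(a.target_gene_ids) == {"left", "right"}

    def test_promoter_takes_precedence_over_cds(self):
        # peak inside geneA's body but also inside downstream geneB's window
        genes = [Gene("A", "chr", 1001, 2000, "+"), Gene("B", "chr", 2101, 2900, "+")]
        ann = make_annotation(genes, max_gap_bp=0)
        a = classify_peak(mk_peak("p", 1900, 1960, 2.0, summit=1930), ann)
        assert a.peak_class == PROMOTER
        assert a.target_gene_ids == ("B",)

    def test_orphan_summit_is_intergenic(self, classify_annotation):
        a = classify_peak(mk_peak("p", 8000, 8100, 2.0, summit=8050), classify_annotation)
        assert a.peak_class == INTERGENIC
        assert a.target_tu_ids == ()

    def test_midpoint_used_without_summit(self, classify_annotation):
        a = classify_peak(mk_peak("p", 800, 900, 2.0), classify_annotation)
        assert a.peak_class == PROMOTER


class TestCountAssignments:
    def test_paper_style_tally(self):
        # 353 single-target promoter peaks + 24 divergent (2 targets each)
        # + 219 CDS peaks, all targets distinct
        assignments = (
            [
                PeakAssignment(f"pp{i}", PROMOTER, (f"tu{i}",), (f"g{i}",), (-50,))
                for i in range(353)
            ]
            + [
                PeakAssignment(
                    f"dv{i}", PROMOTER,
                    (f"dtuL{i}", f"dtuR{i}"), (f"dgL{i}", f"dgR{i}"), (-40, -60),
                )
                for i in range(24)
            ]
            + [
                PeakAssignment(f"cc{i}", CDS, (f"ctu{i}",), (f"cg{i}",), (200,))
                for i in range(219)
            ]
        )
        counts = count_assignments(assignments)
        assert counts["n_promoter"] == 377
        assert counts["n_cds"] == 219
        assert counts["n_divergent"] == 24
        assert counts["n_tu_candidates"] == 401
        assert counts["n_promoter"] + counts["n_cds"] == 596

    def test_empty_assignments(self):
        counts = count_assignments([])
        assert all(v == 0 for v in counts.values())

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        assignments = []
        for i in range(200):
            kind = rng.integers(4)
            if kind == 0:
                assignments.append(PeakAssignment(f"p{i}", INTERGENIC))
            elif kind == 1:
                assignments.append(
                    PeakAssignment(f"p{i}", CDS, (f"tu{rng.integers(40)}",), ("g",), (1,))
                )
            elif kind == 2:
                assignments.append(
                    PeakAssignment(
                        f"p{i}", PROMOTER, (f"tu{rng.integers(40)}",), ("g",), (-1,)
                    )
                )
            else:
                t = rng.integers(40, size=2)
                assignments.append(
                    PeakAssignment(
                        f"p{i}", PROMOTER,
                        (f"tu{t[0]}", f"tu{t[1]}x"), ("g", "h"), (-1, -2),
                    )
                )
        counts = count_assignments(assignments)
        promoter = [a for a in assignments if a.peak_class == PROMOTER]
        assert counts["n_promoter"] == len(promoter)
        assert counts["n_divergent"] == sum(len(a.target_tu_ids) == 2 for a in promoter)
        assert counts["n_cds"] == sum(a.peak_class == CDS for a in assignments)
        assert counts["n_tu_candidates"] == len(
            {t for a in promoter for t in a.target_tu_ids}
        )


class TestCompareClassEnrichment:
    def _assignments(self, n_prom, n_cds):
        return (
            [PeakAssignment(f"p{i}", PROMOTER, ("t",), ("g",), (-1,)) for i in range(n_prom)]
            + [PeakAssignment(f"c{i}", CDS, ("t",), ("g",), (1,)) for i in range(n_cds)]
        )

    def test_identical_groups_give_null_result(self):
        peaks = [mk_peak(f"p{i}", i * 10, i * 10 + 5, 5.0) for i in range(3)] + [
            mk_peak(f"c{i}", 1000 + i * 10, 1000 + i * 10 + 5, 5.0) for i in range(3)
        ]
        cmp = compare_class_enrichment(peaks, self._assignments(3, 3))
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_planted_twofold_difference_is_significant(self):
        rng = np.random.default_rng(42)
        peaks = [
            mk_peak(f"p{i}", i * 10, i * 10 + 5, float(np.exp(rng.normal(np.log(5), 0.4))))
            for i in range(100)
        ] + [
            mk_peak(f"c{i}", 5000 + i * 10, 5000 + i * 10 + 5,
                    float(np.exp(rng.normal(np.log(2.5), 0.4))))
            for i in range(100)
        ]
        cmp = compare_class_enrichment(peaks, self._assignments(100, 100))
        assert cmp.p_value <= 0.01
        assert cmp.means[0] > cmp.means[1]

    def test_mean_and_sem_match_bruteforce(self):
        rng = np.random.default_rng(7)
        fes = rng.uniform(1, 10, size=12)
        peaks = [mk_peak(f"p{i}", i * 10, i * 10 + 5, fe) for i, fe in enumerate(fes[:6])]
        peaks += [mk_peak(f"c{i}", 900 + i * 10, 900 + i * 10 + 5, fe)
                  for i, fe in enumerate(fes[6:])]
        cmp = compare_class_enrichment(peaks, self._assignments(6, 6))
        for mean, sem, xs in zip(cmp.means, cmp.sems, (fes[:6], fes[6:])):
            assert mean == pytest.approx(sum(xs) / len(xs), rel=1e-12)
            sd = (sum((x - sum(xs) / len(xs)) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5
            assert sem == pytest.approx(sd / len(xs) ** 0.5, rel=1e-12)

    def test_empty_class_rejected(self):
        peaks = [mk_peak("p0", 0, 5, 2.0)]
        with pytest.raises(PeakError, match="non-empty"):
            compare_class_enrichment(peaks, self._assignments(1, 0))


def test_classification_recovers_planted_labels(default_dataset):
    """On synthetic data every planted promoter/CDS peak lands in its class."""
    import fur_regulon.io as fio

    dataset_dir, sim = default_dataset
    merged = merge_condition_peaks(
        fio.read_narrowpeak(dataset_dir / "peaks_plusFe.narrowPeak", PLUS_FE),
        fio.read_narrowpeak(dataset_dir / "peaks_minusFe.narrowPeak", MINUS_FE),
    )
    assignments = classify_peaks(merged, sim.annotation, 300)
    by_id = dict(zip([p.id for p in merged], assignments))
    for pid, a in by_id.items():
        planted = pid.split("_")[0]
        if planted in ("prom", "div"):
            assert a.peak_class == PROMOTER
            assert a.divergent == (planted == "div")
        else:
            assert a.peak_class == CDS
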