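"""Direct-target calling, regulon set arithmetic, and the RPKM formula."""

import numpy as np
import pytest

from fur_regulon.genome import Gene
from fur_regulon.regulon import (
    ACTIVATED,
    BOUND_ONLY,
    DIRECT,
    MINUS_FE,
    PLUS_FE,
    REPRESSED,
    WT_VS_KO_MINUSFE,
    WT_VS_KO_PLUSFE,
    DegRecord,
    DegTable,
    RegulonCall,
    RegulonError,
    call_direct_targets,
    classify_mode,
    direct_deg_fraction,
    external_regulon_overlap,
    filter_degs,
    rpkm,
    union_regulon,
)
from .conftest import make_annotation


def deg_table(comparison, entries):
    return DegTable(
        comparison_id=comparison,
        records={g: DegRecord(g, fc, q) for g, (fc, q) in entries.items()},
    )


class TestFilterDegs:
    def test_threshold_is_strict_and_signed(self):
        table = deg_table(WT_VS_KO_PLUSFE, {
            "g1": (2.0, 0.005), "g2": (-1.0, 0.02), "g3": (-3.0, 0.01),
        })
        assert filter_degs(table, 0.01) == {"g1": "up"}

    def test_empty_table(self):
        assert filter_degs(deg_table(WT_VS_KO_PLUSFE, {})) == {}

    def test_zero_fold_change_excluded_with_warning(self, caplog):
        table = deg_table(WT_VS_KO_PLUSFE, {"g1": (0.0, 0.001)})
        with caplog.at_level("WARNING"):
            assert filter_degs(table) == {}
        assert "zero fold change" in caplog.text

    def test_matches_bruteforce_comprehension(self):
        rng = np.random.default_rng(3)
        entries = {
            f"g{i}": (float(rng.normal(0, 2)), float(rng.uniform(0, 0.05)))
            for i in range(1000)
        }
        table = deg_table(WT_VS_KO_PLUSFE, entries)
        expected = {
            g: ("up" if fc > 0 else "down")
            for g, (fc, q) in entries.items()
            if q < 0.01 and fc != 0
        }
        assert filter_degs(table, 0.01) == expected


@pytest.fixture
def two_gene_tu_annotation():
    genes = [Gene("f1", "chr", 1001, 1600, "+"), Gene("f2", "chr", 1651, 2300, "+")]
    return make_annotation(genes, tu_table=[("tu1", "f1"), ("tu1", "f2")])


class TestCallDirectTargets:
    def test_first_gene_deg_in_one_condition(self, two_gene_tu_annotation):
        tables = {
            PLUS_FE: deg_table(WT_VS_KO_PLUSFE, {"f1": (3.1, 0.001)}),
            MINUS_FE: deg_table(WT_VS_KO_MINUSFE, {"f1": (0.1, 0.9)}),
        }
        deg_sets = {PLUS_FE: {"f1": "up"}, MINUS_FE: {}}
        (call,) = call_direct_targets(
            {"tu1": "peak1"}, deg_sets, two_gene_tu_annotation, tables
        )
        assert call.status == DIRECT
        assert call.evidence_conditions == frozenset({PLUS_FE})
        assert call.mode == REPRESSED

    def test_second_gene_deg_does_not_qualify(self, two_gene_tu_annotation):
        deg_sets = {PLUS_FE: {"f2": "up"}, MINUS_FE: {"f2": "up"}}
        (call,) = call_direct_targets(
            {"tu1": "peak1"}, deg_sets, two_gene_tu_annotation
        )
        assert call.status == BOUND_ONLY
        assert call.mode == "NA"

    def test_first_gene_missing_from_tables_counts_as_non_deg(
        self, two_gene_tu_annotation
    ):
        (call,) = call_direct_targets(
            {"tu1": None}, {PLUS_FE: {}, MINUS_FE: {}}, two_gene_tu_annotation
        )
        assert call.status == BOUND_ONLY

    def test_planted_truth_recovered_exactly(self):
        # 100 bound single-gene units, 40 with a planted DEG first gene
        genes = [
            Gene(f"g{i}", "chr", 1001 + 2000 * i, 1600 + 2000 * i, "+")
            for i in range(100)
        ]
        ann = make_annotation(genes, contig_len=300_000, max_gap_bp=0)
        bound = {tu_id: None for tu_id in ann.tus}
        planted = {f"g{i}" for i in range(40)}
        tables = {
            PLUS_FE: deg_table(
                WT_VS_KO_PLUSFE,
                {f"g{i}": ((2.0, 0.001) if f"g{i}" in planted else (0.05, 0.8))
                 for i in range(100)},
            ),
            MINUS_FE: deg_table(WT_VS_KO_MINUSFE, {}),
        }
        deg_sets = {PLUS_FE: filter_degs(tables[PLUS_FE]), MINUS_FE: {}}
        calls = call_direct_targets(bound, deg_sets, ann, tables)
        direct = {c.first_gene_id for c in calls if c.status == DIRECT}
        assert direct == planted


class TestClassifyMode:
    def test_positive_ko_over_wt_means_repressed(self):
        assert classify_mode({PLUS_FE}, 3.1, None) == REPRESSED

    def test_negative_ko_over_wt_means_activated(self):
        assert classify_mode({PLUS_FE}, -1.2, None) == ACTIVATED

    def test_conflicting_signs_resolved_by_iron_replete(self, caplog):
        with caplog.at_level("WARNING"):
            mode = classify_mode({PLUS_FE, MINUS_FE}, 2.0, -1.5, "tuX")
        assert mode == REPRESSED
        assert "conflicting" in caplog.text

    def test_planted_mode_ratio_recovered(self, default_dataset):
        _, sim = default_dataset
        truth_modes = {
            t: rec["mode"] for t, rec in sim.truth.tus.items() if rec["direct"]
        }
        recovered = {
            t: classify_mode(
                {PLUS_FE},
                sim.truth.tus[t]["effect_log2fc_plusfe"],
                sim.truth.tus[t]["effect_log2fc_minusfe"],
            )
            for t in truth_modes
        }
        assert recovered == truth_modes


def _direct_call(tu_id, conds, mode=REPRESSED):
    return RegulonCall(
        tu_id=tu_id, status=DIRECT, mode=mode,
        evidence_conditions=frozenset(conds), first_gene_id=f"fg_{tu_id}",
    )


class TestUnionRegulon:
    def test_inclusion_exclusion_on_reported_counts(self):
        # 84 iron-replete calls, 28 iron-depleted calls, 23 shared
        calls = (
            [_direct_call(f"t{i}", {PLUS_FE, MINUS_FE}) for i in range(23)]
            + [_direct_call(f"t{i}", {PLUS_FE}) for i in range(23, 84)]
            + [_direct_call(f"u{i}", {MINUS_FE}) for i in range(5)]
        )
        summary = union_regulon(calls)
        assert summary.n_direct_plusfe == 84
        assert summary.n_direct_minusfe == 28
        assert summary.n_both_conditions == 23
        assert summary.n_direct == 89

    def test_identical_sets_are_idempotent(self):
        calls = [_direct_call(f"t{i}", {PLUS_FE, MINUS_FE}) for i in range(10)]
        summary = union_regulon(calls)
        assert summary.n_direct == summary.n_both_conditions == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_set_union(self, seed):
        rng = np.random.default_rng(seed)
        calls, a_set, b_set = [], set(), set()
        for i in range(30):
            conds = set()
            if rng.random() < 0.6:
                conds.add(PLUS_FE)
                a_set.add(f"t{i}")
            if rng.random() < 0.4:
                conds.add(MINUS_FE)
                b_set.add(f"t{i}")
            if conds:
                calls.append(_direct_call(f"t{i}", conds))
        summary = union_regulon(calls)
        assert summary.n_direct == len(a_set | b_set)
        assert summary.n_both_conditions == len(a_set & b_set)


class TestDirectDegFraction:
    def _annotation_with_direct_members(self, n_members):
        genes = [
            Gene(f"d{i}", "chr", 1001 + 700 * i, 1500 + 700 * i, "+")
            for i in range(n_members)
        ]
        ann = make_annotation(
            genes, contig_len=1_000_000,
            tu_table=[("big", f"d{i}") for i in range(n_members)],
        )
        return ann

    def test_reported_ratio_rounds_to_22pct(self):
        ann = self._annotation_with_direct_members(123)
        call = RegulonCall(
            tu_id="big", status=DIRECT, mode=REPRESSED,
            evidence_conditions=frozenset({PLUS_FE}), first_gene_id="d0",
        )
        degs = {f"d{i}" for i in range(123)} | {f"x{i}" for i in range(437)}
        out = direct_deg_fraction([call], degs, ann)
        assert out["n_direct_degs"] == 123
        assert out["n_total_degs"] == 560
        assert out["pct"] == pytest.approx(100 * 123 / 560)
        assert out["pct_rounded"] == 22

    def test_all_degs_direct_gives_100pct(self):
        ann = self._annotation_with_direct_members(5)
        call = RegulonCall(
            tu_id="big", status=DIRECT, mode=REPRESSED,
            evidence_conditions=frozenset({PLUS_FE}), first_gene_id="d0",
        )
        out = direct_deg_fraction([call], {f"d{i}" for i in range(5)}, ann)
        assert out["pct"] == 100.0

    def test_empty_deg_union_rejected(self):
        ann = self._annotation_with_direct_members(2)
        with pytest.raises(RegulonError, match="empty"):
            direct_deg_fraction([], set(), ann)


class TestExternalRegulonOverlap:
    def test_reported_ryhb_arithmetic(self):
        degs = {f"g{i}" for i in range(560)}
        external = {f"g{i}" for i in range(71)} | {"outside1", "outside2"}
        direct = {f"g{i}" for i in range(26)}
        out = external_regulon_overlap(degs, external, direct)
        assert out["n_overlap"] == 71
        assert out["n_dual"] == 26
        assert out["n_exclusive"] == 45
        assert out["exclusive_pct_of_degs"] == pytest.approx(100 * 45 / 560)
        assert out["exclusive_pct_of_degs"] < 10.0

    def test_disjoint_external_set(self):
        out = external_regulon_overlap({"a", "b"}, {"c"}, {"a"})
        assert (out["n_overlap"], out["n_dual"], out["n_exclusive"]) == (0, 0, 0)
        assert out["exclusive_pct_of_degs"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(100)]
        degs = {g for g in universe if rng.random() < 0.5}
        external = {g for g in universe if rng.random() < 0.3}
        direct = {g for g in degs if rng.random() < 0.4}
        out = external_regulon_overlap(degs, external, direct)
        assert out["n_overlap"] == len(degs & external)
        assert out["n_dual"] == len(degs & external & direct)
        assert out["n_exclusive"] == len((degs & external) - direct)


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(100, 1000, 1_000_000) == pytest.approx(100.0)

    def test_linearity(self):
        base = rpkm(50, 800, 2_000_000)
        assert rpkm(100, 800, 2_000_000) == pytest.approx(2 * base)
        assert rpkm(50, 800, 4_000_000) == pytest.approx(base / 2)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            c = float(rng.uniform(1, 1e5))
            l = float(rng.uniform(100, 1e4))
            d = float(rng.uniform(1e5, 1e8))
            assert rpkm(c, l, d) == pytest.approx(1e9 * c / (l * d), rel=1e-12)

    def test_zero_inputs_rejected(self):
        with pytest.raises(RegulonError):
            rpkm(10, 0, 1e6)
        with pytest.raises(RegulonError):
            rpkm(10, 100, 0)
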