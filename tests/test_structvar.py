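"""Variant genotyping, stage classification, replication logic and
uniquely shared consensus features."""

import numpy as np
import pytest

from malrkit.simulate import (
    make_succession_consensuses,
    mutate_seq,
    plant_structural_variants,
    succession_region,
    synthetic_internal_consensus,
    synthetic_ltr_consensus,
)
from malrkit.structvar import (
    LTRModel,
    SoloLTRError,
    StructuralVariantDef,
    THE1A_VARIANTS,
    apply_variants,
    call_element,
    call_variants,
    classify_stage,
    count_supported_pairs,
    find_ltrs,
    load_ltr_model,
    load_variant_defs,
    predict_progeny_ltr,
    scan_for_stage,
    shared_features,
    succession_support,
)


@pytest.fixture(scope="module")
def cons():
    return synthetic_ltr_consensus()


@pytest.fixture(scope="module")
def defs():
    return {n: d for n, d in load_variant_defs().items()
            if n in THE1A_VARIANTS}


@pytest.fixture(scope="module")
def ltr_model():
    return load_ltr_model()


class TestVariantDefs:
    def test_packaged_defs_cover_the_named_variants(self):
        defs = load_variant_defs()
        assert set(THE1A_VARIANTS) <= set(defs)
        assert defs["204del"].kind == "deletion"
        assert defs["303_312delinsTT"].replacement == "TT"
        d = defs["227_242del"]
        assert d.end - d.start + 1 == 16  # the 16 bp family-diagnostic loss

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            StructuralVariantDef(name="x", kind="inversion", start=1, end=5)

    def test_overlapping_variant_application_rejected(self, cons):
        defs = {
            "a": StructuralVariantDef(name="a", kind="deletion",
                                      start=100, end=120),
            "b": StructuralVariantDef(name="b", kind="deletion",
                                      start=110, end=130),
        }
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(cons, defs, ["a", "b"])


class TestCallVariants:
    def test_exact_consensus_shows_nothing(self, cons, defs):
        call = call_variants(cons, cons, defs)
        assert all(s == "absent" for s in call.status.values())

    def test_single_base_deletion_called_per_ltr(self, cons, defs):
        del204 = apply_variants(cons, defs, ["204del"])
        call = call_variants(del204, cons, defs)
        assert call.status["204del"] == "present"
        assert call.delta["204del"] == -1
        assert call.status["226_235del"] == "absent"

    def test_delins_called_by_length_signature_with_content_recorded(
            self, cons, defs):
        var = apply_variants(cons, defs, ["303_312delinsTT"])
        call = call_variants(var, cons, defs)
        assert call.status["303_312delinsTT"] == "present"
        assert "TT" in call.segment_content["303_312delinsTT"]

    def test_all_four_at_once(self, cons, defs):
        var = apply_variants(cons, defs, list(THE1A_VARIANTS))
        call = call_variants(var, cons, defs)
        assert call.present == frozenset(THE1A_VARIANTS)

    def test_calls_survive_heavy_substitution_divergence(self, cons, defs):
        rng = np.random.default_rng(0)
        var = apply_variants(cons, defs, ["204del", "186ins"])
        hits = 0
        for _ in range(30):
            call = call_variants(mutate_seq(rng, var, 0.05), cons, defs)
            hits += (call.status["204del"] == "present"
                     and call.status["186ins"] == "present"
                     and call.status["226_235del"] == "absent")
        assert hits == 30

    def test_truncated_ltr_is_uncallable_at_missing_loci(self, cons, defs):
        call = call_variants(cons[:150], cons, defs)
        assert call.status["303_312delinsTT"] == "uncallable"


class TestFindLtrs:
    def test_full_length_element_yields_both_copies(self, cons):
        elem = cons + synthetic_internal_consensus() + cons
        ltr5, ltr3 = find_ltrs(elem, cons)
        assert ltr5 == cons
        assert ltr3 == cons

    def test_solo_ltr_raises(self, cons):
        with pytest.raises(SoloLTRError):
            find_ltrs(cons, cons)


class TestStageClassification:
    def patterns_to_calls(self, cons, defs, set5, set3):
        ltr5 = apply_variants(cons, defs, set5)
        ltr3 = apply_variants(cons, defs, set3)
        return (call_variants(ltr5, cons, defs, "e", "5p"),
                call_variants(ltr3, cons, defs, "e", "3p"))

    THREE = ("186ins", "226_235del", "303_312delinsTT")

    @pytest.mark.parametrize("set5,set3,stage", [
        (THREE, THREE, "precursor"),
        (THREE + ("204del",), THREE, "intermediate"),
        (THE1A_VARIANTS, THE1A_VARIANTS, "canonical"),
        ((), (), "other"),                       # ancestral pattern
        (THREE, THREE + ("204del",), "other"),   # 204del on the wrong side
    ])
    def test_per_ltr_patterns(self, cons, defs, set5, set3, stage):
        c5, c3 = self.patterns_to_calls(cons, defs, set5, set3)
        assert classify_stage(c5, c3).stage == stage

    def test_uncallable_locus_goes_to_other_with_reason(self, cons, defs):
        c5, c3 = self.patterns_to_calls(cons, defs, self.THREE, self.THREE)
        c3.status["204del"] = "uncallable"
        sc = classify_stage(c5, c3)
        assert sc.stage == "other"
        assert "uncallable" in sc.reason


class TestPredictProgenyLtr:
    def test_intermediate_progeny_is_canonical(self, defs, ltr_model):
        three = frozenset({"186ins", "226_235del", "303_312delinsTT"})
        progeny = predict_progeny_ltr(three | {"204del"}, three, defs,
                                      ltr_model)
        assert progeny == frozenset(THE1A_VARIANTS)

    def test_identical_ltrs_are_a_fixed_point(self, defs, ltr_model):
        pattern = frozenset({"204del", "226_235del"})
        assert predict_progeny_ltr(pattern, pattern, defs,
                                   ltr_model) == pattern

    def test_u3_variant_on_three_prime_spreads_to_both(self, defs, ltr_model):
        assert ltr_model.segment_of(defs["186ins"]) == "U3"
        progeny = predict_progeny_ltr(frozenset(), {"186ins"}, defs,
                                      ltr_model)
        assert progeny == frozenset({"186ins"})

    def test_applied_twice_converges_in_one_round(self, defs, ltr_model):
        three = frozenset({"186ins", "226_235del", "303_312delinsTT"})
        once = predict_progeny_ltr(three | {"204del"}, three, defs, ltr_model)
        twice = predict_progeny_ltr(once, once, defs, ltr_model)
        assert once == twice

    def test_boundary_spanning_variant_demands_assignment(self, ltr_model):
        spanning = StructuralVariantDef(name="bad", kind="deletion",
                                        start=185, end=200)
        with pytest.raises(ValueError, match="boundary"):
            ltr_model.segment_of(spanning)


class TestScanForStage:
    def test_empty_input_empty_table(self, cons, defs):
        assert scan_for_stage({}, cons, defs).empty

    def test_element_order_invariance(self, cons, defs):
        internal = synthetic_internal_consensus()
        elems, _ = plant_structural_variants(
            cons, internal, defs, ["canonical", "precursor", "intermediate"],
            seed=8, subst_rate=0.03)
        t1 = scan_for_stage(elems, cons, defs)
        t2 = scan_for_stage(dict(reversed(list(elems.items()))), cons, defs)
        assert t1.equals(t2)

    def test_stage_counts_sum_to_callable_elements(self, cons, defs):
        internal = synthetic_internal_consensus()
        elems, _ = plant_structural_variants(
            cons, internal, defs, {"canonical": 10, "precursor": 2},
            seed=9, subst_rate=0.05)
        elems["solo"] = cons  # a lone LTR must be set aside, not staged
        table = scan_for_stage(elems, cons, defs)
        staged = table[table.stage != "solo_or_partial"]
        assert len(staged) == 12
        assert (table.stage == "solo_or_partial").sum() == 1


class TestSharedFeatures:
    def test_identical_pair_vs_distinct_backgrounds_is_one_block(self):
        rng = np.random.default_rng(1)
        from malrkit.simulate import random_seq

        a = random_seq(rng, 120)
        shift = str.maketrans("ACGT", "CGTA")
        bg = {"z": a.translate(shift)}
        blocks = shared_features(a, a, bg, min_len=10)
        # one block spanning (nearly all of) the alignment; free end gaps
        # can let the background slide at the termini
        assert len(blocks) == 1
        assert blocks[0].start <= 3
        assert blocks[0].length >= 110

    def test_pair_identical_to_background_has_no_blocks(self):
        rng = np.random.default_rng(2)
        from malrkit.simulate import random_seq

        a = random_seq(rng, 120)
        assert shared_features(a, a, {"z": a}, min_len=10) == []

    def test_planted_block_recovered_at_its_coordinates(self):
        cons = make_succession_consensuses(6)
        names = list(cons)
        bg = {n: cons[n] for n in names if n not in names[1:3]}
        blocks = shared_features(cons[names[1]], cons[names[2]], bg,
                                 min_len=10)
        lo, hi = succession_region(2, 6)
        assert len(blocks) == 1
        assert abs(blocks[0].start - lo) <= 2
        assert abs(blocks[0].end - hi) <= 2

    def test_no_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            shared_features("ACGT", "ACGT", {})


class TestSuccessionSupport:
    def test_every_true_adjacent_pair_supported(self):
        cons = make_succession_consensuses(6)
        table = succession_support(list(cons), cons)
        assert table.supported.all()

    def test_two_member_chain_single_pair(self):
        cons = make_succession_consensuses(3)
        names = list(cons)
        table = succession_support(names[:2], {n: cons[n] for n in cons})
        assert len(table) == 1

    def test_missing_consensus_rejected(self):
        cons = make_succession_consensuses(3)
        with pytest.raises(ValueError, match="no consensus"):
            succession_support(["ghost"] + list(cons), cons)

    def test_true_order_beats_shuffles(self):
        cons = make_succession_consensuses(6)
        order = list(cons)
        true_score = count_supported_pairs(order, cons)
        rng = np.random.default_rng(0)
        for _ in range(10):
            shuffled = order[:]
            while True:
                rng.shuffle(shuffled)
                if shuffled not in (order, order[::-1]):
                    break
            assert count_supported_pairs(shuffled, cons) < true_score
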