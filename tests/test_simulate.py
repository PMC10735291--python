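"""Simulator invariants: determinism, truth correspondence, branch
assignment, nesting one-sidedness, chain validity and degradation."""

import numpy as np
import pytest

from malrkit.formats import group_entities, lifted_aligned_bases, read_chain
from malrkit.simulate import (
    FamilyActivity,
    SpeciesTree,
    default_scenario,
    degrade_chain,
    make_succession_consensuses,
    plant_structural_variants,
    random_seq,
    simulate_succession,
    synthetic_internal_consensus,
    synthetic_ltr_consensus,
)
from malrkit import structvar


def small_family(name="MST", mu=0.3, copies=10, **kw):
    rng = np.random.default_rng(1)
    return FamilyActivity(name=name, mu=mu, sigma=0.05, copies=copies,
                          consensus=random_seq(rng, 300), **kw)


class TestSimulateSuccession:
    def test_deterministic_byte_identical_outputs(self, tmp_path):
        fam = [small_family()]
        t = SpeciesTree()
        a = simulate_succession(t, fam, seed=7, nest_prob=0.0)
        b = simulate_succession(t, fam, seed=7, nest_prob=0.0)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        a.write(d1)
        b.write(d2)
        for p in sorted(d1.iterdir()):
            assert p.read_bytes() == (d2 / p.name).read_bytes()

    def test_copy_budget_without_nesting_gives_one_row_per_copy(self):
        b = simulate_succession(SpeciesTree(), [small_family()], seed=7,
                                nest_prob=0.0)
        rows = b.copies["human"]
        assert len(rows) == 10
        assert len(group_entities(rows)) == 10

    def test_every_row_traces_to_one_truth_record(self, default_bundle):
        truth_ids = set(default_bundle.truth.insertion_id)
        for sp, rows in default_bundle.copies.items():
            for r in rows:
                assert r.repeat_id in truth_ids
        # and every truth record has at least one focal row
        focal_ids = {r.repeat_id for r in default_bundle.copies["human"]}
        assert focal_ids == truth_ids

    def test_branch_assignment_matches_species_outputs(self):
        # an insertion between the bushbaby and tarsier splits must appear
        # in the human and tarsier annotations but not the bushbaby one
        fam = [small_family(mu=0.45, copies=40)]
        b = simulate_succession(SpeciesTree(), fam, seed=13, nest_prob=0.0)
        between = b.truth[(b.truth.pseudo_time >= 0.35)
                          & (b.truth.pseudo_time < 0.55)]
        assert len(between) > 0
        tarsier_ids = {r.repeat_id for r in b.copies["tarsier"]}
        bushbaby_ids = {r.repeat_id for r in b.copies["bushbaby"]}
        for iid in between.insertion_id:
            assert iid in tarsier_ids
            assert iid not in bushbaby_ids

    def test_disjoint_windows_give_strictly_one_sided_nesting(self):
        old = small_family("OLD", mu=0.15, copies=60)
        young = small_family("YOUNG", mu=0.75, copies=60)
        old.sigma = young.sigma = 0.02
        b = simulate_succession(SpeciesTree(), [old, young], seed=5,
                                nest_prob=0.4)
        t = b.truth.set_index("insertion_id")
        pairs = [(t.loc[i, "family"], t.loc[p, "family"])
                 for i, p in zip(b.truth.insertion_id, b.truth.nesting_parent)
                 if p]
        assert pairs, "expected some nestings"
        assert ("OLD", "YOUNG") not in pairs
        assert any(p == ("YOUNG", "OLD") for p in pairs)

    def test_nested_host_split_into_two_fragments_sharing_id(self):
        b = simulate_succession(SpeciesTree(), [small_family(copies=80)],
                                seed=3, nest_prob=0.5)
        nested = b.truth[b.truth.nesting_parent > 0]
        assert len(nested) > 0
        ents = {e.repeat_id: e for e in group_entities(b.copies["human"])}
        for parent in nested.nesting_parent.unique():
            assert len(ents[parent].fragments) == 2

    def test_chains_valid_and_consistent_with_presence(self, default_bundle):
        truth = default_bundle.truth.set_index("insertion_id")
        chains = default_bundle.chains["bushbaby"]
        for e in group_entities(default_bundle.copies["human"])[:50]:
            present = bool(truth.loc[e.repeat_id, "present_bushbaby"])
            aligned = lifted_aligned_bases(chains, e.query_name, *e.span)
            if present:
                assert aligned > 0
            else:
                assert aligned == 0

    def test_written_chain_parses_back(self, tmp_path, default_bundle):
        default_bundle.write(tmp_path)
        chains = read_chain(tmp_path / "humanToBushbaby.chain")
        assert chains == default_bundle.chains["bushbaby"]

    def test_toy_genome_lengths_match_coordinates(self):
        b = simulate_succession(SpeciesTree(), [small_family(copies=5)],
                                seed=7, nest_prob=0.0, bg_length=5_000,
                                toy_genome=True)
        human = b.genome_fasta["human_chr1"]
        for row in b.copies["human"]:
            assert row.query_end <= len(human)

    def test_excessive_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            simulate_succession(SpeciesTree(),
                                [small_family(copies=100_000)],
                                seed=1, bg_length=500)


class TestDegradeChain:
    def test_zero_fraction_is_identity(self, default_bundle):
        c = default_bundle.chains["tarsier"][0]
        assert degrade_chain(c, 0.0, seed=1) is c

    def test_aligned_total_monotone_in_fraction(self, default_bundle):
        c = default_bundle.chains["tarsier"][0]
        totals = [degrade_chain(c, f, seed=9).aligned_bases
                  for f in (0.1, 0.2, 0.4, 0.6, 0.8)]
        assert totals == sorted(totals, reverse=True)

    def test_near_total_deletion_drops_element_below_presence(self):
        fam = [small_family(mu=0.2, copies=5)]
        b = simulate_succession(SpeciesTree(), fam, seed=7, nest_prob=0.0)
        c = degrade_chain(b.chains["bushbaby"][0], 0.995, seed=2, chunk=40)
        e = group_entities(b.copies["human"])[0]
        aligned = lifted_aligned_bases([c], e.query_name, *e.span)
        assert aligned < 50

    def test_header_spans_stay_consistent(self, default_bundle):
        c = degrade_chain(default_bundle.chains["bushbaby"][0], 0.3, seed=4)
        tspan = sum(s + dt for s, dt, _ in c.blocks)
        qspan = sum(s + dq for s, _, dq in c.blocks)
        assert tspan == c.target_end - c.target_start
        assert qspan == c.query_end - c.query_start


@pytest.fixture(scope="module")
def setup():
    ltr = synthetic_ltr_consensus()
    internal = synthetic_internal_consensus()
    defs = {n: d for n, d in structvar.load_variant_defs().items()
            if n in structvar.THE1A_VARIANTS}
    return ltr, internal, defs


class TestPlantStructuralVariants:

    def test_canonical_zero_divergence_carries_all_four_in_both(self, setup):
        ltr, internal, defs = setup
        elems, truth = plant_structural_variants(
            ltr, internal, defs, ["canonical"], seed=1, subst_rate=0.0)
        c5, c3 = structvar.call_element(next(iter(elems.values())), ltr, defs)
        assert c5.present == frozenset(structvar.THE1A_VARIANTS)
        assert c3.present == frozenset(structvar.THE1A_VARIANTS)

    def test_intermediate_has_204del_on_five_prime_only(self, setup):
        ltr, internal, defs = setup
        elems, truth = plant_structural_variants(
            ltr, internal, defs, ["intermediate"], seed=1, subst_rate=0.0)
        c5, c3 = structvar.call_element(next(iter(elems.values())), ltr, defs)
        assert "204del" in c5.present
        assert "204del" not in c3.present

    def test_full_recovery_of_planted_patterns_at_5pct_divergence(self, setup):
        ltr, internal, defs = setup
        stages = ["canonical"] * 40 + ["precursor"] * 30 + ["intermediate"] * 30
        elems, truth = plant_structural_variants(
            ltr, internal, defs, stages, seed=42, subst_rate=0.05)
        table = structvar.scan_for_stage(elems, ltr, defs)
        merged = table.merge(truth, on="element_id", suffixes=("_called", "_true"))
        assert (merged.stage_called == merged.stage_true).all()

    def test_unknown_stage_rejected(self, setup):
        ltr, internal, defs = setup
        with pytest.raises(ValueError, match="unknown stage"):
            plant_structural_variants(ltr, internal, defs, ["mosaic"], seed=1)


class TestSuccessionConsensuses:
    def test_chain_members_have_expected_length_and_alphabet(self):
        cons = make_succession_consensuses(4, length=300, region_len=30)
        assert len(cons) == 4
        for s in cons.values():
            assert len(s) == 300
            assert set(s) <= set("ACGT")

    def test_too_short_consensus_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_succession_consensuses(8, length=100, region_len=40)
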