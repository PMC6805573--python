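"""Per-ORF LCA, bit-score voting, query assignment, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_group
from oracles import brute_assign_terminals, random_orf_classifications

from taxvote.alignment import BinDefinition, OrfHitGroup
from taxvote.classify import (
    OrfClassification,
    Params,
    REASON_NO_HITS,
    REASON_NO_TAXID,
    STATUS_NO_HITS,
    assign,
    classify_bin,
    classify_contig,
    classify_orf,
    reduce_to_majority,
    vote,
)

THREE_ORF_VOTES = [  # (taxon, registered bit-score): b_sum = 240
    (60, 100.0), (61, 80.0), (50, 60.0),
]


def orfs_from(pairs):
    return [
        OrfClassification(f"q_{i}", "q", taxid, score, 1)
        for i, (taxid, score) in enumerate(pairs, start=1)
    ]


class TestParams:
    def test_defaults_per_mode(self):
        c, b = Params.contig_defaults(), Params.bin_defaults()
        assert (c.r, c.f) == (10.0, 0.5)
        assert (b.r, b.f) == (5.0, 0.3)

    @pytest.mark.parametrize("kwargs", [{"r": -1}, {"r": 101}, {"f": 0},
                                        {"f": 1.5}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Params(**kwargs)


class TestClassifyOrf:
    def test_range_ten_keeps_sibling_species(self, hand_tree, hand_protmap):
        group = make_group("c1_1", [("P60", 100), ("P61", 95), ("P70", 85)])
        orf = classify_orf(group, 10, hand_tree, hand_protmap)
        # threshold 90: {60, 61} → genus
        assert orf.lca_taxid == 50
        assert orf.registered_bitscore == 100
        assert orf.n_hits_in_range == 2

    def test_range_twenty_reaches_across_families(self, hand_tree, hand_protmap):
        group = make_group("c1_1", [("P60", 100), ("P61", 95), ("P70", 85)])
        orf = classify_orf(group, 20, hand_tree, hand_protmap)
        # threshold 80: {60, 61, 70} → shared order
        assert orf.lca_taxid == 30
        assert orf.n_hits_in_range == 3

    def test_single_hit_any_range(self, hand_tree, hand_protmap):
        group = make_group("c1_1", [("P60", 100)])
        for r in (0, 10, 50):
            orf = classify_orf(group, r, hand_tree, hand_protmap)
            assert (orf.lca_taxid, orf.registered_bitscore) == (60, 100)

    def test_empty_group_reason(self, hand_tree, hand_protmap):
        orf = classify_orf(OrfHitGroup("c1_1", "c1", []), 10,
                           hand_tree, hand_protmap)
        assert orf.lca_taxid is None and orf.reason == REASON_NO_HITS

    def test_unmappable_hits_reason(self, hand_tree, hand_protmap):
        group = make_group("c1_1", [("XX", 100), ("YY", 90)])
        orf = classify_orf(group, 10, hand_tree, hand_protmap)
        assert orf.lca_taxid is None and orf.reason == REASON_NO_TAXID

    def test_top_determined_after_dropping_unmapped(self, hand_tree,
                                                    hand_protmap):
        # unmappable 200-bit hit must not drag the range window up
        group = make_group("c1_1", [("XX", 200), ("P60", 100), ("P61", 95)])
        orf = classify_orf(group, 10, hand_tree, hand_protmap)
        assert orf.lca_taxid == 50
        assert orf.registered_bitscore == 100

    def test_range_boundary_inclusive(self, hand_tree, hand_protmap):
        group = make_group("c1_1", [("P60", 100), ("P61", 90)])
        orf = classify_orf(group, 10, hand_tree, hand_protmap)
        assert orf.n_hits_in_range == 2  # 90 == 100 × (1 − 10/100)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), r1=st.floats(0, 50),
           r2=st.floats(0, 50))
    def test_monotone_in_r(self, small_world, seed, r1, r2):
        """A wider range can only push the ORF LCA towards the root."""
        if r1 > r2:
            r1, r2 = r2, r1
        rng = np.random.default_rng(seed)
        accs = sorted(small_world.protmap.taxid_of)
        chosen = [accs[i] for i in rng.integers(0, len(accs), size=8)]
        group = make_group(
            "c1_1", [(a, float(rng.uniform(50, 100))) for a in chosen]
        )
        lo = classify_orf(group, r1, small_world.tree, small_world.protmap)
        hi = classify_orf(group, r2, small_world.tree, small_world.protmap)
        assert hi.lca_taxid in small_world.tree.lineage(lo.lca_taxid)


class TestVote:
    def test_three_orf_example(self, hand_tree):
        table = vote(orfs_from(THREE_ORF_VOTES), hand_tree)
        assert table.b_sum == 240
        assert table.support_of[50] == 240
        assert table.support_of[60] == 100
        assert table.support_of[61] == 80
        assert table.support_of[1] == 240  # conservation at the root

    def test_no_classified_orfs(self, hand_tree):
        unclassified = [OrfClassification("c1_1", "c1", None, 0.0, 0,
                                          reason=REASON_NO_HITS)]
        table = vote(unclassified, hand_tree)
        assert table.b_sum == 0 and table.support_of == {}

    def test_single_vote_covers_whole_lineage(self, hand_tree):
        table = vote(orfs_from([(60, 42.0)]), hand_tree)
        for node in hand_tree.lineage(60):
            assert table.support_of[node] == 42.0
        assert table.b_sum == 42.0

    def test_child_support_never_exceeds_parent(self, small_world, rng):
        tree = small_world.tree
        table = vote(random_orf_classifications(tree, rng, 20), tree)
        for taxid, parent in tree.parent_of.items():
            if taxid == tree.root_id or taxid not in table.support_of:
                continue
            assert table.support_of[taxid] <= table.support_of[parent] + 1e-9


class TestAssign:
    def test_majority_stops_at_genus(self, hand_tree):
        table = vote(orfs_from(THREE_ORF_VOTES), hand_tree)
        qc = assign("c1", table, 0.5, hand_tree)
        (lineage, fracs), = qc.lineages
        assert lineage[-1] == 50
        assert fracs[-1] == pytest.approx(1.0)
        # species 60 would have had support fraction 100/240
        assert 60 not in lineage

    def test_low_f_reports_both_species(self, hand_tree):
        table = vote(orfs_from(THREE_ORF_VOTES), hand_tree)
        qc = assign("c1", table, 0.3, hand_tree)
        terminals = {lin[-1] for lin, _ in qc.lineages}
        assert terminals == {60, 61}

    def test_unanimous_at_f_one(self, hand_tree):
        table = vote(orfs_from([(60, 10.0), (60, 20.0)]), hand_tree)
        qc = assign("c1", table, 1.0, hand_tree)
        (lineage, fracs), = qc.lineages
        assert lineage[-1] == 60
        assert all(x == pytest.approx(1.0) for x in fracs)

    def test_empty_votes_give_no_hits_status(self, hand_tree):
        from taxvote.classify import VoteTable
        qc = assign("c1", VoteTable(), 0.5, hand_tree)
        assert qc.status == STATUS_NO_HITS and qc.lineages == []

    def test_invalid_f_rejected(self, hand_tree):
        from taxvote.classify import VoteTable
        with pytest.raises(ValueError):
            assign("c1", VoteTable(), 0.0, hand_tree)

    def test_fractions_non_increasing_root_to_terminal(self, small_world, rng):
        tree = small_world.tree
        table = vote(random_orf_classifications(tree, rng, 15), tree)
        qc = assign("q", table, 0.2, tree)
        for _, fracs in qc.lineages:
            assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           f=st.sampled_from([0.1, 0.3, 0.5, 0.9]))
    def test_matches_bruteforce_enumeration(self, small_world, seed, f):
        tree = small_world.tree
        rng = np.random.default_rng(seed)
        orfs = random_orf_classifications(tree, rng, int(rng.integers(1, 15)))
        expected, support, b_sum = brute_assign_terminals(orfs, f, tree)
        qc = assign("q", vote(orfs, tree), f, tree)
        assert {lin[-1] for lin, _ in qc.lineages} == expected
        for lin, fracs in qc.lineages:
            for node, frac in zip(lin, fracs):
                assert frac == pytest.approx(support[node] / b_sum)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_at_most_one_lineage_at_majority_f(self, small_world, seed):
        tree = small_world.tree
        rng = np.random.default_rng(seed)
        orfs = random_orf_classifications(tree, rng, int(rng.integers(1, 15)))
        qc = assign("q", vote(orfs, tree), 0.5, tree)
        assert len(qc.lineages) <= 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           fa=st.sampled_from([0.1, 0.3, 0.5, 0.9]),
           fb=st.sampled_from([0.1, 0.3, 0.5, 0.9]))
    def test_monotone_in_f(self, small_world, seed, fa, fb):
        """Raising f can only move qualifying terminals towards the root."""
        f1, f2 = sorted((fa, fb))
        tree = small_world.tree
        rng = np.random.default_rng(seed)
        orfs = random_orf_classifications(tree, rng, int(rng.integers(1, 15)))
        votes = vote(orfs, tree)
        hi = assign("q", votes, f2, tree)
        lo = assign("q", votes, f1, tree)
        lo_terminals = {lin[-1] for lin, _ in lo.lineages}
        for lin, _ in hi.lineages:
            assert any(lin[-1] in tree.lineage(t) for t in lo_terminals)


class TestClassifyContigAndBin:
    def _groups(self):
        return [
            make_group("c1_1", [("P60", 100), ("P61", 95), ("P70", 85)]),
            make_group("c1_2", [("P61", 80)]),
            make_group("c1_3", [("P50", 60)]),
        ]

    def test_contig_defaults_make_genus_call(self, hand_tree, hand_protmap):
        qc, orfs = classify_contig("c1", self._groups(),
                                   Params.contig_defaults(),
                                   hand_tree, hand_protmap)
        (lineage, _), = qc.lineages
        assert lineage[-1] == 50
        assert qc.n_orfs_total == 3 and qc.n_orfs_classified == 3

    def test_contig_with_only_hitless_orf(self, hand_tree, hand_protmap):
        qc, _ = classify_contig("c1", [OrfHitGroup("c1_1", "c1", [])],
                                Params.contig_defaults(),
                                hand_tree, hand_protmap)
        assert qc.status == STATUS_NO_HITS

    def test_single_orf_passthrough(self, hand_tree, hand_protmap):
        qc, orfs = classify_contig(
            "c1", [make_group("c1_1", [("P60", 100)])],
            Params.contig_defaults(), hand_tree, hand_protmap)
        (lineage, _), = qc.lineages
        assert lineage[-1] == orfs[0].lca_taxid == 60

    def test_bin_pools_contigs_and_doubles_support(self, hand_tree,
                                                   hand_protmap):
        groups = {
            "c1": self._groups(),
            "c2": [make_group("c2_1", [("P60", 100), ("P61", 95),
                                       ("P70", 85)]),
                   make_group("c2_2", [("P61", 80)]),
                   make_group("c2_3", [("P50", 60)])],
        }
        params = Params(r=10, f=0.5, mode="bin")
        single, _ = classify_contig("c1", groups["c1"], params,
                                    hand_tree, hand_protmap)
        pooled, _ = classify_bin(
            BinDefinition("binA", {"c1", "c2"}), groups, params,
            hand_tree, hand_protmap)
        assert pooled.lineages[0][0][-1] == single.lineages[0][0][-1] == 50
        assert pooled.b_sum == pytest.approx(2 * single.b_sum)

    def test_bin_of_one_contig_reduces_to_contig_case(self, hand_tree,
                                                      hand_protmap):
        params = Params.bin_defaults()
        groups = {"c1": self._groups()}
        via_bin, _ = classify_bin(BinDefinition("binA", {"c1"}), groups,
                                  params, hand_tree, hand_protmap)
        direct, _ = classify_contig("c1", groups["c1"], params,
                                    hand_tree, hand_protmap)
        assert [lin for lin, _ in via_bin.lineages] == \
            [lin for lin, _ in direct.lineages]
        assert via_bin.b_sum == direct.b_sum


class TestReduceToMajority:
    def test_minority_species_collapse_to_genus(self, hand_tree):
        # 70% on species 60, 30% on sibling 61: only 60 has a majority
        table = vote(orfs_from([(60, 70.0), (61, 30.0)]), hand_tree)
        qc = assign("c1", table, 0.3, hand_tree)
        assert {lin[-1] for lin, _ in qc.lineages} == {60, 61}
        reduced = reduce_to_majority(qc, hand_tree)
        (lineage, _), = reduced.lineages
        assert lineage[-1] == 60

    def test_sub_majority_siblings_stop_at_parent(self, hand_tree):
        # 0.42 / 0.33 species split under a unanimous genus
        table = vote(orfs_from([(60, 42.0), (61, 33.0), (50, 25.0)]),
                     hand_tree)
        qc = assign("c1", table, 0.3, hand_tree)
        reduced = reduce_to_majority(qc, hand_tree)
        (lineage, _), = reduced.lineages
        assert lineage[-1] == 50

    def test_idempotent_on_majority_calls(self, hand_tree):
        table = vote(orfs_from(THREE_ORF_VOTES), hand_tree)
        qc = assign("c1", table, 0.5, hand_tree)
        reduced = reduce_to_majority(qc, hand_tree)
        assert reduced.lineages == qc.lineages

    def test_unanimous_species_retained(self, hand_tree):
        table = vote(orfs_from([(60, 50.0), (60, 10.0)]), hand_tree)
        qc = assign("c1", table, 0.3, hand_tree)
        reduced = reduce_to_majority(qc, hand_tree)
        assert reduced.lineages[0][0][-1] == 60

    def test_exact_half_split_is_not_a_majority(self, hand_tree):
        table = vote(orfs_from([(60, 50.0), (61, 50.0)]), hand_tree)
        qc = assign("c1", table, 0.3, hand_tree)
        reduced = reduce_to_majority(qc, hand_tree)
        assert reduced.lineages[0][0][-1] == 50
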