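"""The clade-placement criterion for allo- vs autopolyploid origin."""

import numpy as np
import pytest

from waxyphylo.gene_structure import PseudogeneReport
from waxyphylo.io_core import tree_from_newick_string
from waxyphylo.phylogeny import node_leaf_labels
from waxyphylo.polyploid_inference import (
    UNASSIGNED,
    CladeExemplars,
    MonophylyStatus,
    Verdict,
    assign_major_clade,
    classify_origin,
    homoeolog_monophyly,
)
from waxyphylo.variant_typing import VariantLabel, genotype_individual

CLEAN = PseudogeneReport("x", False, (), False, ())

# Rooted reference topology used across tests: exemplar clades
#   I  = {ia1, ia2}   (e.g. diploid carriers of the long-intron form)
#   II = {ib1, ib2}   (short-intron form carriers)
# x1 nests inside clade I (within the exemplar MRCA), x2 inside clade II;
# pa sits outside both exemplar MRCAs.
TREE = (
    "((((ia1:1,(x1:1,ia2:1)90:1)95:1,pa:1)92:1,"
    "(ib1:1,(x2:1,ib2:1)91:1)97:1)99:1,og:4);"
)


def make_genotype(pairs, individual="X"):
    return genotype_individual(
        [(sid, label, CLEAN) for sid, label in pairs], individual
    )


@pytest.fixture
def tree():
    t = tree_from_newick_string(TREE)
    t.is_rooted = True
    return t


@pytest.fixture
def exemplars():
    return CladeExemplars(
        {"I": frozenset({"ia1", "ia2"}), "II": frozenset({"ib1", "ib2"})}
    )


class TestMonophyly:
    def test_single_copy(self, tree):
        assert homoeolog_monophyly(tree, "X", {"X": ("x1",)}) is (
            MonophylyStatus.SINGLE_COPY
        )

    def test_sister_copies_are_monophyletic(self):
        t = tree_from_newick_string("((x1:1,x2:1):1,(y1:1,y2:1):1,z:1);")
        t.is_rooted = True
        assert homoeolog_monophyly(t, "X", {"X": ("x1", "x2")}) is (
            MonophylyStatus.MONOPHYLETIC
        )

    def test_separated_copies_are_not(self, tree):
        assert homoeolog_monophyly(tree, "X", {"X": ("x1", "x2")}) is (
            MonophylyStatus.NON_MONOPHYLETIC
        )

    def test_missing_leaf_is_an_error(self, tree):
        with pytest.raises(KeyError):
            homoeolog_monophyly(tree, "X", {"X": ("x1", "ghost")})

    def test_agrees_with_subtree_leafset_oracle(self):
        from itertools import combinations

        from waxyphylo.phylogeny import nj_tree
        from waxyphylo.seqstats import DistanceMatrix
        from tests.test_phylogeny import random_tree_distances

        rng = np.random.default_rng(21)
        for _ in range(5):
            ids, matrix, _ = random_tree_distances(rng, 8)
            t = nj_tree(DistanceMatrix(tuple(ids), matrix))
            t.is_rooted = True
            subtree_sets = {
                node_leaf_labels(n) for n in t.preorder_node_iter()
            }
            for combo in combinations(ids, 2):
                got = homoeolog_monophyly(t, "X", {"X": combo})
                want = (
                    MonophylyStatus.MONOPHYLETIC
                    if frozenset(combo) in subtree_sets
                    else MonophylyStatus.NON_MONOPHYLETIC
                )
                assert got is want


class TestCladeAssignment:
    def test_exemplar_maps_to_its_own_clade(self, tree, exemplars):
        assert assign_major_clade(tree, "ia1", exemplars) == "I"
        assert assign_major_clade(tree, "ib2", exemplars) == "II"

    def test_members_inherit_their_clade(self, tree, exemplars):
        assert assign_major_clade(tree, "x1", exemplars) == "I"
        assert assign_major_clade(tree, "x2", exemplars) == "II"

    def test_outgroup_is_unassigned(self, tree, exemplars):
        assert assign_major_clade(tree, "og", exemplars) == UNASSIGNED
        assert assign_major_clade(tree, "pa", exemplars) == UNASSIGNED

    def test_missing_exemplar_is_a_configuration_error(self, tree):
        bad = CladeExemplars({"I": frozenset({"ia1", "ghost"})})
        with pytest.raises(KeyError):
            assign_major_clade(tree, "x1", bad)

    def test_simulated_copies_assigned_to_their_pool(self, small_sim):
        # exemplars = diploid sequences per pool; every polyploid copy
        # must land in its source pool's clade
        from waxyphylo.phylogeny import nj_tree, root_with_outgroup
        from waxyphylo.seqstats import distance_matrix

        truth = {s.seq_id: s for s in small_sim.truth.sequences}
        t = nj_tree(distance_matrix(small_sim.truth_alignment))
        t = root_with_outgroup(
            t, [sid for sid, s in truth.items() if s.pool == "OG"]
        )
        modes = {i.individual_id: i.origin_mode
                 for i in small_sim.truth.individuals}
        ex = CladeExemplars({
            "I": frozenset(s for s, v in truth.items()
                           if v.pool == "A" and modes[v.individual_id] == "diploid"),
            "II": frozenset(s for s, v in truth.items()
                            if v.pool == "B" and modes[v.individual_id] == "diploid"),
        })
        for sid, s in truth.items():
            if modes[s.individual_id].endswith("polyploid"):
                assert assign_major_clade(t, sid, ex) == (
                    "I" if s.pool == "A" else "II"
                )


class TestClassifyOrigin:
    def test_copies_in_two_supported_clades_is_allopolyploid(self, tree, exemplars):
        g = make_genotype([("x1", VariantLabel.V1A), ("x2", VariantLabel.V1B)])
        call = classify_origin(tree, g, exemplars, support_min=70, ploidy=4)
        assert call.verdict is Verdict.ALLOPOLYPLOID_PATTERN
        assert call.min_separating_support >= 70
        assert call.monophyly is MonophylyStatus.NON_MONOPHYLETIC

    def test_sister_copies_are_autopolyploid(self, exemplars):
        t = tree_from_newick_string(
            "(((x1:1,x2:1)99:1,(ia1:1,ia2:1)95:1)90:1,(ib1:1,ib2:1)97:2,og:4);"
        )
        t.is_rooted = True
        g = make_genotype([("x1", VariantLabel.V1A), ("x2", VariantLabel.V1A)])
        call = classify_origin(t, g, exemplars, ploidy=4)
        assert call.verdict is Verdict.AUTOPOLYPLOID_PATTERN

    def test_single_copy_is_uninformative(self, tree, exemplars):
        g = make_genotype([("x1", VariantLabel.V1A)])
        call = classify_origin(tree, g, exemplars, ploidy=4)
        assert call.verdict is Verdict.UNINFORMATIVE

    def test_low_support_blocks_the_allopolyploid_call(self, exemplars):
        t = tree_from_newick_string(
            "(((ia1:1,(x1:1,ia2:1)20:1)40:1,(ib1:1,(x2:1,ib2:1)35:1)50:1)99:1,og:4);"
        )
        t.is_rooted = True
        g = make_genotype([("x1", VariantLabel.V1A), ("x2", VariantLabel.V1B)])
        call = classify_origin(t, g, exemplars, support_min=70, ploidy=4)
        assert call.verdict is Verdict.UNINFORMATIVE
        assert call.min_separating_support < 70
        # disabling the gate (tree without supports) flips the verdict
        call2 = classify_origin(t, g, exemplars, support_min=70, ploidy=4,
                                require_support=False)
        assert call2.verdict is Verdict.ALLOPOLYPLOID_PATTERN

    def test_same_clade_copies_are_uninformative(self, tree, exemplars):
        g = make_genotype([("x1", VariantLabel.V1A), ("pa", VariantLabel.V1A)])
        call = classify_origin(tree, g, exemplars, ploidy=4)
        # x1 and pa are cousins within clade I: non-monophyletic would
        # need a second major clade
        assert call.verdict in (
            Verdict.UNINFORMATIVE, Verdict.AUTOPOLYPLOID_PATTERN
        )
        assert call.verdict is not Verdict.ALLOPOLYPLOID_PATTERN

    def test_never_allopolyploid_on_monophyletic_copies(self, exemplars):
        # sweep thresholds: a monophyletic pair must never yield ALLO
        t = tree_from_newick_string(
            "(((x1:1,x2:1)99:1,(ia1:1,ia2:1)95:1)90:1,(ib1:1,ib2:1)97:2,og:4);"
        )
        t.is_rooted = True
        g = make_genotype([("x1", VariantLabel.V1A), ("x2", VariantLabel.V1B)])
        for support_min in (0, 50, 70, 101):
            for require in (True, False):
                call = classify_origin(t, g, exemplars, support_min=support_min,
                                       ploidy=4, require_support=require)
                assert call.verdict is not Verdict.ALLOPOLYPLOID_PATTERN

    def test_diploid_two_clade_pattern_reported_as_hybrid(self, tree, exemplars):
        g = make_genotype([("x1", VariantLabel.V1A), ("x2", VariantLabel.V1B)])
        call = classify_origin(tree, g, exemplars, ploidy=2)
        assert call.verdict is Verdict.ALLOPOLYPLOID_PATTERN
        assert call.display_verdict == "hybrid_pattern"

    def test_verdict_invariant_to_leaf_rotation(self, exemplars):
        a = tree_from_newick_string(TREE)
        rotated = tree_from_newick_string(
            "(og:4,((pa:1,((ia2:1,x1:1)90:1,ia1:1)95:1)92:1,"
            "((ib2:1,x2:1)91:1,ib1:1)97:1)99:1);"
        )
        for t in (a, rotated):
            t.is_rooted = True
        g = make_genotype([("x1", VariantLabel.V1A), ("x2", VariantLabel.V1B)])
        calls = [classify_origin(t, g, exemplars, ploidy=4) for t in (a, rotated)]
        assert calls[0].verdict is calls[1].verdict
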