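"""A/B/C topology classification and the T1/T2/T3 retention variant."""

from itertools import chain, combinations

import numpy as np
import pytest

from ppscan.errors import (
    AmbiguousRetentionError,
    NoFocalDuplicationError,
)
from ppscan.synthetic_data import ScenarioConfig, simulate_gene_trees
from ppscan.topotest import (
    GroupSpec,
    TopologyCall,
    _classify_sides,
    classify_duplication_topology,
    classify_pair_retention,
    summarize_topologies,
)
from ppscan.treeio import parse_gene_tree, parse_species_tree

from conftest import SMALL_NEWICK


@pytest.fixture
def st():
    return parse_species_tree(SMALL_NEWICK)


@pytest.fixture
def groups():
    return GroupSpec(focal_node="nIn", group1=frozenset({"O", "F"}),
                     group2=frozenset({"S", "M"}))


class TestClassifySides:
    def test_both_sides_hit_both_groups_is_a(self, groups):
        assert _classify_sides(frozenset("OFS"), frozenset("OM"), groups) == "A"

    def test_group1_only_side_is_b(self, groups):
        assert _classify_sides(frozenset("OF"), frozenset("OFSM"), groups) == "B"

    def test_group2_only_side_is_c(self, groups):
        assert _classify_sides(frozenset("SM"), frozenset("OS"), groups) == "C"

    def test_mutually_exclusive_sides_ambiguous(self, groups):
        assert _classify_sides(frozenset("OF"), frozenset("SM"), groups) == "AMBIG"

    def test_classes_exclusive_and_exhaustive_for_spanning_unions(self):
        """Brute force over all side bipartitions of up to 6 species."""
        g = GroupSpec(focal_node="x", group1=frozenset({"a", "b", "c"}),
                      group2=frozenset({"d", "e", "f"}))
        universe = sorted(g.group1 | g.group2)

        def subsets(items):
            return chain.from_iterable(
                combinations(items, r) for r in range(1, len(items) + 1)
            )

        n_checked = 0
        for s1 in subsets(universe):
            for s2 in subsets(universe):
                s1f, s2f = frozenset(s1), frozenset(s2)
                union = s1f | s2f
                klass = _classify_sides(s1f, s2f, g)
                if not (union & g.group1 and union & g.group2):
                    assert klass is None
                    continue
                assert klass in {"A", "B", "C", "AMBIG"}
                n_checked += 1
        assert n_checked > 1000


class TestClassifyTree:
    def test_zero_loss_auto_tree_is_a(self, st, groups):
        cfg = ScenarioConfig(species_tree=st, wgd_branch="nIn", mode="auto",
                             loss_prob=0.0, n_trees=5, seed=1)
        trees, _ = simulate_gene_trees(cfg)
        for gt in trees:
            assert classify_duplication_topology(gt, st, groups).klass == "A"

    def test_hand_built_b_tree(self, st, groups):
        gt = parse_gene_tree(
            "((((O_1,F_1),(S_1,M_1)),(O_2,F_2)),C_1);", tree_id="b"
        )
        assert classify_duplication_topology(gt, st, groups).klass == "B"

    def test_hand_built_c_tree(self, st, groups):
        gt = parse_gene_tree(
            "((((O_1,F_1),(S_1,M_1)),(S_2,M_2)),C_1);", tree_id="c"
        )
        assert classify_duplication_topology(gt, st, groups).klass == "C"

    def test_no_focal_duplication_is_distinct_error(self, st, groups):
        gt = parse_gene_tree("((O_1,F_1),C_1);")
        with pytest.raises(NoFocalDuplicationError):
            classify_duplication_topology(gt, st, groups)

    def test_min_support_filters_unsupported_duplications(self, st, groups):
        gt = parse_gene_tree(
            "((((O_1,F_1):1,(S_1,M_1):1)0.60:1,(O_2,F_2):1)0.60:1,C_1:1);",
            tree_id="weak",
        )
        assert classify_duplication_topology(gt, st, groups).klass == "B"
        with pytest.raises(NoFocalDuplicationError):
            classify_duplication_topology(gt, st, groups, min_support=0.95)


class TestSummarize:
    @staticmethod
    def _calls(**counts):
        out = []
        for klass, n in counts.items():
            out.extend(
                TopologyCall(f"{klass}{i}", klass, frozenset("O"), frozenset("S"))
                for i in range(n)
            )
        return out

    def test_percentages_over_abc(self):
        s = summarize_topologies(self._calls(B=77, A=13, C=10))
        assert s["percent"]["B"] == pytest.approx(77.0)
        assert s["percent"]["A"] == pytest.approx(13.0)
        assert s["b_vs_c_p_value"] < 1e-10

    def test_all_a_has_no_applicable_test(self):
        s = summarize_topologies(self._calls(A=10))
        assert s["percent"]["B"] == 0.0
        assert s["b_vs_c_p_value"] is None

    def test_ambig_excluded_from_percentages(self):
        s = summarize_topologies(self._calls(A=5, B=5, AMBIG=10))
        assert s["percent"]["A"] == pytest.approx(50.0)
        assert s["n_ambiguous"] == 10


class TestCohortDiscrimination:
    def _summary(self, st, groups, mode, wgd, parent, seed, loss=0.3, n=500):
        cfg = ScenarioConfig(species_tree=st, wgd_branch=wgd, mode=mode,
                             allo_parent_branch=parent, loss_prob=loss,
                             n_trees=n, seed=seed)
        trees, _ = simulate_gene_trees(cfg)
        calls = []
        for gt in trees:
            try:
                calls.append(classify_duplication_topology(gt, st, groups))
            except NoFocalDuplicationError:
                pass
        return summarize_topologies(calls)

    def test_allo_cohort_b_dominates_c(self, st, groups):
        s = self._summary(st, groups, "allo", "nOF", "nIn", seed=31)
        assert s["counts"]["B"] > s["counts"]["C"]
        assert s["b_vs_c_p_value"] < 0.01

    def test_auto_cohort_b_c_symmetric(self, st, groups):
        s = self._summary(st, groups, "auto", "nIn", None, seed=32, n=2000)
        b, c = s["counts"]["B"], s["counts"]["C"]
        assert abs(b - c) <= 3 * np.sqrt(b + c)

    def test_unbalanced_sampling_under_auto_favours_c(self):
        """With group2 twice the size of group1 and losses acting on
        species lineages independently (terminal loss model), random loss
        more easily empties the small group from one side: C should not
        lag B.  (Under the branch-loss model a single deep loss can erase
        the large clade wholesale, which breaks this sampling argument.)"""
        st = parse_species_tree(
            "((((O,F)g1,((S,M)x1,(U,V)x2)g2)nIn,C)r0,W)root;"
        )
        groups = GroupSpec(focal_node="nIn", group1=frozenset({"O", "F"}),
                           group2=frozenset({"S", "M", "U", "V"}))
        diffs = []
        for seed in (41, 42, 43):
            cfg = ScenarioConfig(species_tree=st, wgd_branch="nIn",
                                 mode="auto", loss_prob=0.4, n_trees=1000,
                                 loss_model="terminal", seed=seed)
            trees, _ = simulate_gene_trees(cfg)
            calls = []
            for gt in trees:
                try:
                    calls.append(classify_duplication_topology(gt, st, groups))
                except NoFocalDuplicationError:
                    pass
            s = summarize_topologies(calls)
            diffs.append(s["counts"]["C"] - s["counts"]["B"])
        assert np.mean(diffs) >= 0


class TestPairRetention:
    st2 = parse_species_tree("(((E,Y)nEY,P)nEYP,J)root;")

    def test_complete_tree_is_t1(self):
        gt = parse_gene_tree("(((E_1,Y_1),(E_2,Y_2)),P_1);")
        assert classify_pair_retention(gt, self.st2, "E", "Y") == "T1"

    def test_side_missing_second_genome_is_t2(self):
        gt = parse_gene_tree("((E_1,(E_2,Y_1)),P_1);")
        assert classify_pair_retention(gt, self.st2, "E", "Y") == "T2"

    def test_side_missing_first_genome_is_t3(self):
        gt = parse_gene_tree("((Y_1,(E_1,Y_2)),P_1);")
        assert classify_pair_retention(gt, self.st2, "E", "Y") == "T3"

    def test_fully_separated_sides_ambiguous(self):
        # with a third lineage Z under the two genomes' ancestor, a
        # duplication can carry E on one side and Y on the other only
        st3 = parse_species_tree("(((E,(Y,Z)nYZ)nEYZ,P)nX,J)root;")
        gt = parse_gene_tree("(((E_1,Z_1),(Y_1,Z_2)),P_1);")
        with pytest.raises(AmbiguousRetentionError):
            classify_pair_retention(gt, st3, "E", "Y")

    def test_no_qualifying_duplication_distinct_error(self):
        gt = parse_gene_tree("((E_1,P_1),J_1);")
        with pytest.raises(NoFocalDuplicationError):
            classify_pair_retention(gt, self.st2, "E", "Y")
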