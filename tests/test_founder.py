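"""Founder identification, dating, migration-time scans and scenarios."""

import numpy as np
import pytest

import mitofounder as mf
from mitofounder.founder import GRID_STEP, _derived_source_branch_count
from mitofounder.simulate import _f1f2_demo_tree
from mitofounder.tree import AnnotatedTree, Node, TreeError
from mitofounder.variants import Haplotype, Variant

from conftest import random_annotated_tree

DEMO_SCENARIO = mf.ScenarioPartition(
    name="demo",
    source_regions=frozenset({"Fertile Crescent"}),
    sink_regions=frozenset({"Arabian Peninsula"}))


def random_partition(tree, rng, p_sink=0.4):
    part = {}
    for leaf in tree.leaves():
        if leaf.haplotype is None:
            continue
        u = rng.random()
        part[leaf] = "sink" if u < p_sink else ("source" if u < 0.9
                                                else "excluded")
    return part


class TestPartitionLeaves:
    def test_membership_and_exclusion(self):
        tree = _f1f2_demo_tree()
        euro = tree.root.add_child(Node(name="E1", mutations=[Variant(999)]))
        euro.haplotype = Haplotype("E1", region="Europe")
        scen = mf.ScenarioPartition(
            name="ea", source_regions=frozenset({"Fertile Crescent"}),
            sink_regions=frozenset({"Eastern Africa"}))
        part = mf.partition_leaves(tree, scen)
        assert part[euro] == "excluded"          # Europe in neither set
        assert part[tree.leaf_map()["S1"]] == "source"

    def test_palestinian_modes(self):
        root = Node(name="root")
        leaf = root.add_child(Node(name="P1", mutations=[Variant(100)]))
        tree = AnnotatedTree(root)
        leaf.haplotype = Haplotype("P1", population="Palestinian",
                                   region="Fertile Crescent")
        base = dict(source_regions=frozenset({"Arabian Peninsula"}),
                    sink_regions=frozenset({"Eastern Africa"}))
        with_arabia = mf.ScenarioPartition(name="a", palestinian_mode="with_arabia", **base)
        with_fc = mf.ScenarioPartition(name="b", palestinian_mode="with_fertile_crescent", **base)
        unassigned = mf.ScenarioPartition(name="c", palestinian_mode="unassigned", **base)
        assert mf.partition_leaves(tree, with_arabia)[leaf] == "source"
        assert mf.partition_leaves(tree, with_fc)[leaf] == "excluded"
        assert mf.partition_leaves(tree, unassigned)[leaf] == "excluded"

    def test_iran_toggle(self):
        root = Node(name="root")
        leaf = root.add_child(Node(name="I1", mutations=[Variant(100)]))
        tree = AnnotatedTree(root)
        leaf.haplotype = Haplotype("I1", population="Iranian", region="Iran")
        scen_in = mf.SCENARIO_PRESETS["A"]
        scen_out = mf.ScenarioPartition(
            name="a2", source_regions=scen_in.source_regions,
            sink_regions=scen_in.sink_regions, include_iran_in_source=False)
        assert mf.partition_leaves(tree, scen_in)[leaf] == "source"
        assert mf.partition_leaves(tree, scen_out)[leaf] == "excluded"

    def test_reciprocal_swaps_classes_exactly(self, rng):
        tree = random_annotated_tree(
            rng, n_leaves=12,
            regions=("Fertile Crescent", "Arabian Peninsula"))
        scen = mf.ScenarioPartition(
            name="fwd", source_regions=frozenset({"Fertile Crescent"}),
            sink_regions=frozenset({"Arabian Peninsula"}))
        fwd = mf.partition_leaves(tree, scen)
        rev = mf.partition_leaves(tree, scen.reciprocal())
        swap = {"source": "sink", "sink": "source", "excluded": "excluded"}
        assert rev == {leaf: swap[cls] for leaf, cls in fwd.items()}

    def test_unknown_region_lists_offenders(self):
        root = Node(name="root")
        leaf = root.add_child(Node(name="X1", mutations=[Variant(100)]))
        tree = AnnotatedTree(root)
        leaf.haplotype = Haplotype("X1", region="Atlantis")
        with pytest.raises(TreeError, match="X1:Atlantis"):
            mf.partition_leaves(tree, DEMO_SCENARIO,
                                known_regions=mf.DEFAULT_REGIONS)

    def test_overlapping_source_sink_rejected(self):
        with pytest.raises(ValueError):
            mf.ScenarioPartition(name="bad",
                                 source_regions=frozenset({"Iran"}),
                                 sink_regions=frozenset({"Iran"}))


class TestIdentifyFounders:
    def test_worked_f1_f2_example(self):
        """f1 founder at F (one derived source branch S1); no node has two,
        so f2 falls back to the flagged root."""
        tree = _f1f2_demo_tree()
        part = mf.partition_leaves(tree, DEMO_SCENARIO)
        (c1,) = mf.identify_founders(tree, part, "f1")
        assert c1.founder_node.name == "F"
        assert {l.name for l in c1.sink_leaves} == {"K1", "K2"}
        assert not c1.at_root
        (c2,) = mf.identify_founders(tree, part, "f2")
        assert c2.founder_node is tree.root
        assert c2.at_root
        assert {l.name for l in c2.sink_leaves} == {"K1", "K2"}

    def test_zero_mutation_source_tip_does_not_count(self):
        tree = _f1f2_demo_tree()
        # add a zero-mutation source tip at F: still only one derived branch
        f = tree.find("F")
        tip = f.add_child(Node(name="S3"))
        tip.haplotype = Haplotype("S3", region="Fertile Crescent",
                                  variants=tree.state(tip))
        part = mf.partition_leaves(tree, DEMO_SCENARIO)
        assert _derived_source_branch_count(f, part) == 1

    def test_all_sink_gives_flagged_root_cluster(self):
        tree = _f1f2_demo_tree()
        part = {leaf: "sink" for leaf in tree.leaves()}
        (c,) = mf.identify_founders(tree, part, "f1")
        assert c.founder_node is tree.root and c.at_root
        assert c.n_sink == 4

    def test_invalid_criterion(self):
        tree = _f1f2_demo_tree()
        with pytest.raises(ValueError):
            mf.identify_founders(tree, {}, "f3")

    def test_partition_completeness_and_criterion_monotonicity(self, rng):
        """Clusters partition the sink leaves; each leaf's f2 founder is an
        ancestor-or-equal of its f1 founder; #f2 clusters <= #f1."""
        for _ in range(40):
            tree = random_annotated_tree(rng, n_leaves=int(rng.integers(4, 12)))
            part = random_partition(tree, rng)
            n_sink = sum(1 for v in part.values() if v == "sink")
            if n_sink == 0:
                continue
            cl1 = mf.identify_founders(tree, part, "f1")
            cl2 = mf.identify_founders(tree, part, "f2")
            for clusters in (cl1, cl2):
                leaves = [l for c in clusters for l in c.sink_leaves]
                assert len(leaves) == n_sink
                assert len(set(map(id, leaves))) == n_sink
            assert len(cl2) <= len(cl1)
            f1_of = {id(l): c.founder_node
                     for c in cl1 for l in c.sink_leaves}
            for c in cl2:
                for leaf in c.sink_leaves:
                    f1_founder = f1_of[id(leaf)]
                    rootward = {id(f1_founder)} | {
                        id(n) for n in _ancestors(f1_founder)}
                    assert id(c.founder_node) in rootward

    def test_rho_f_counts_only_sink_leaves(self):
        tree = _f1f2_demo_tree()
        part = mf.partition_leaves(tree, DEMO_SCENARIO)
        (c1,) = mf.identify_founders(tree, part, "f1")
        # K1 and K2 sit directly at F with no mutations
        assert c1.rho_f == 0.0 and c1.sigma_f == 0.0


def _ancestors(node):
    while node.parent is not None:
        node = node.parent
        yield node


class TestDateFounder:
    def _cluster(self, rho_f, sigma_f):
        return mf.FounderCluster(founder_node=Node(), criterion="f1",
                                 sink_leaves=[Node()], derived_source_branches=1,
                                 rho_f=rho_f, sigma_f=sigma_f)

    def test_linear_arithmetic(self):
        c = self._cluster(2.0, 0.0)
        assert mf.date_founder(c) == pytest.approx(5302.0)

    def test_zero_rho(self):
        assert mf.date_founder(self._cluster(0.0, 0.0)) == 0.0

    def test_sigma_propagated_linearly(self):
        c = self._cluster(1.0, 1.0)
        mf.date_founder(c)
        assert c.age_years == pytest.approx(2651.0)
        assert c.age_sigma_years == pytest.approx(2651.0)


class TestScanMigrations:
    def _cluster(self, rho_f, sigma_f, n=1):
        return mf.FounderCluster(founder_node=Node(), criterion="f2",
                                 sink_leaves=[Node() for _ in range(n)],
                                 derived_source_branches=2,
                                 rho_f=rho_f, sigma_f=sigma_f)

    def test_degenerate_sigma_all_mass_in_first_bin(self):
        scan = mf.scan_migrations([self._cluster(0.0, 0.0)])
        assert scan.total[0] == pytest.approx(1.0)
        assert scan.total[1:].sum() == pytest.approx(0.0)

    def test_two_separated_clusters_half_mass_each(self):
        scan = mf.scan_migrations([self._cluster(1.0, 0.1, n=5),
                                   self._cluster(10.0, 0.1, n=5)])
        assert scan.total.sum() == pytest.approx(1.0, abs=1e-9)
        assert scan.per_founder[0].sum() == pytest.approx(0.5, abs=1e-6)
        assert scan.per_founder[1].sum() == pytest.approx(0.5, abs=1e-6)

    def test_mass_sums_to_one_and_argmax_at_age_bin(self, rng):
        for _ in range(50):
            rho_f = float(rng.uniform(0, 15))
            sigma_f = float(rng.uniform(0, 2))
            scan = mf.scan_migrations([self._cluster(rho_f, sigma_f)])
            assert scan.total.sum() == pytest.approx(1.0, abs=1e-9)
            age = rho_f * 2651
            if sigma_f == 0 or age > 1000:  # mode at the age bin (not clipped)
                assert abs(scan.mode_years() - age) <= GRID_STEP

    def test_shift_property(self):
        base = [self._cluster(2.0, 0.5, n=3), self._cluster(4.0, 0.5, n=2)]
        shifted = [self._cluster(2.0 + 2.0, 0.5, n=3),
                   self._cluster(4.0 + 2.0, 0.5, n=2)]
        delta = 2.0 * 2651
        m0 = mf.scan_migrations(base).mode_years()
        m1 = mf.scan_migrations(shifted).mode_years()
        assert abs((m1 - m0) - delta) <= GRID_STEP

    def test_empty_cluster_list_rejected(self):
        with pytest.raises(ValueError):
            mf.scan_migrations([])

    def test_grid_shape(self):
        scan = mf.scan_migrations([self._cluster(1.0, 0.3)])
        assert len(scan.grid_starts) == 250
        assert scan.grid_starts[0] == 0.0 and scan.grid_starts[-1] == 49800.0


class TestRunScenario:
    def test_preset_list_is_complete(self):
        assert set(mf.SCENARIO_PRESETS) == set("ABCDEFG")
        # reciprocal analysis presets: D and E run Arabia as the source
        assert mf.SCENARIO_PRESETS["D"].source_regions == {"Arabian Peninsula"}
        assert "Iran" in mf.SCENARIO_PRESETS["D"].sink_regions
        assert "Iran" not in mf.SCENARIO_PRESETS["E"].sink_regions

    def test_deterministic_report(self):
        _, tree, _ = mf.simulate_genealogy(mf.SimConfig(seed=9))
        r1 = mf.run_scenario(tree, mf.SCENARIO_PRESETS["C"])
        r2 = mf.run_scenario(tree, mf.SCENARIO_PRESETS["C"])
        assert r1.class_counts == r2.class_counts
        for crit in ("f1", "f2"):
            np.testing.assert_array_equal(r1.scans[crit].total,
                                          r2.scans[crit].total)

    def test_swapping_source_sink_moves_founders(self):
        tree = _f1f2_demo_tree()
        fwd = mf.run_scenario(tree, DEMO_SCENARIO)
        rev = mf.run_scenario(tree, DEMO_SCENARIO.reciprocal())
        assert fwd.class_counts["sink"] == rev.class_counts["source"]
        # reversed: S1/S2 are now sink; their f1 founders differ from fwd
        fwd_sinks = {l.name for c in fwd.clusters["f1"] for l in c.sink_leaves}
        rev_sinks = {l.name for c in rev.clusters["f1"] for l in c.sink_leaves}
        assert fwd_sinks == {"K1", "K2"} and rev_sinks == {"S1", "S2"}

    def test_report_frames(self):
        _, tree, _ = mf.simulate_genealogy(mf.SimConfig(seed=9))
        rep = mf.run_scenario(tree, mf.SCENARIO_PRESETS["C"])
        cf = rep.clusters_frame()
        assert {"criterion", "n_sink", "rho_f", "age_years"} <= set(cf.columns)
        sf = rep.scan_frame()
        assert sf["f2_mass"].sum() == pytest.approx(1.0)
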