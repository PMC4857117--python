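"""Parsimony tree construction, replay, labelling, motifs and newick IO."""

import io
import itertools

import numpy as np
import pytest

import mitofounder as mf
from mitofounder.tree import AnnotatedTree, Node, TreeError
from mitofounder.variants import Haplotype, Variant


# ---------------------------------------------------------------------------
# Independent brute-force parsimony oracle: enumerate every rooted binary
# topology (bipartition recursion) and sum Fitch costs of all sites on the
# SAME topology; root state fixed to all-ancestral.

def _all_topologies(members):
    if len(members) == 1:
        yield members[0]
        return
    m0, rest = members[0], members[1:]
    for r in range(2 ** len(rest) - 1):  # left side always holds m0
        left = [m0] + [m for j, m in enumerate(rest) if r >> j & 1]
        right = [m for j, m in enumerate(rest) if not r >> j & 1]
        for lt in _all_topologies(left):
            for rt in _all_topologies(right):
                yield (lt, rt)


def _fitch_cost(topo, states):
    """(state set, changes) of one site on one topology."""
    if not isinstance(topo, tuple):
        return {states[topo]}, 0
    ls, lc = _fitch_cost(topo[0], states)
    rs, rc = _fitch_cost(topo[1], states)
    inter = ls & rs
    if inter:
        return inter, lc + rc
    return ls | rs, lc + rc + 1


def brute_force_parsimony(haplotypes):
    sites = sorted({v.site for h in haplotypes for v in h.variants})
    leaf_sets = [frozenset(v.site for v in h.variants) for h in haplotypes]
    if len(leaf_sets) == 1:
        return len(leaf_sets[0])
    per_site_states = [tuple(1 if s in ls else 0 for ls in leaf_sets)
                       for s in sites]
    best = None
    for topo in _all_topologies(list(range(len(leaf_sets)))):
        total = 0
        for states in per_site_states:
            top, cost = _fitch_cost(topo, states)
            total += cost + (0 if 0 in top else 1)
        best = total if best is None else min(best, total)
    return best or 0


def _rand_haps(rng, n_leaves, n_sites, p=0.45):
    out = []
    for i in range(n_leaves):
        sites = frozenset(Variant(1000 + s) for s in range(n_sites)
                          if rng.random() < p)
        out.append(Haplotype(f"h{i}", variants=sites))
    return out


class TestParsimonyBuild:
    def test_three_leaf_worked_example(self):
        haps = [Haplotype("A", variants=mf.parse_profile("100 200")),
                Haplotype("B", variants=mf.parse_profile("100 300")),
                Haplotype("C", variants=mf.parse_profile("100"))]
        tree = mf.build_parsimony_tree(haps)
        assert tree.parsimony_length() == 3
        # internal node carrying {100}, C a zero-mutation leaf at that node
        c = tree.leaf_map()["C"]
        assert c.mutations == []
        assert [str(m) for m in c.parent.mutations] == ["100"]
        assert {str(m) for m in tree.leaf_map()["A"].mutations} == {"200"}

    def test_single_haplotype_equal_to_root(self):
        tree = mf.build_parsimony_tree([Haplotype("A")])
        assert tree.parsimony_length() == 0
        assert tree.leaf_map()["A"].mutations == []

    def test_two_identical_haplotypes_share_a_node(self):
        haps = [Haplotype("A", variants=mf.parse_profile("500")),
                Haplotype("B", variants=mf.parse_profile("500"))]
        tree = mf.build_parsimony_tree(haps)
        assert tree.parsimony_length() == 1
        a, b = tree.leaf_map()["A"], tree.leaf_map()["B"]
        assert a.parent is b.parent
        assert a.mutations == [] and b.mutations == []

    def test_duplicate_sample_ids_rejected(self):
        haps = [Haplotype("A"), Haplotype("A")]
        with pytest.raises(TreeError, match="duplicate"):
            mf.build_parsimony_tree(haps)

    def test_matches_exhaustive_minimum_on_small_instances(self):
        """Default construction achieves the brute-force optimum for all
        instances of up to 5 leaves (random homoplasy-rich draws)."""
        rng = np.random.default_rng(7)
        for trial in range(40):
            n = int(rng.integers(2, 6))
            haps = _rand_haps(rng, n, int(rng.integers(2, 7)), p=0.5)
            tree = mf.build_parsimony_tree(haps)
            tree.replay_check()
            assert tree.parsimony_length() == brute_force_parsimony(haps)

    def test_star_tree_upper_bound_and_replay(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            haps = _rand_haps(rng, int(rng.integers(2, 11)), 8)
            tree = mf.build_parsimony_tree(haps, exact=False)
            tree.replay_check()
            assert tree.parsimony_length() <= sum(len(h.variants) for h in haps)

    def test_greedy_deterministic_and_seed_shuffle_valid(self):
        rng = np.random.default_rng(3)
        haps = _rand_haps(rng, 9, 7)
        t1 = mf.build_parsimony_tree(haps, exact=False)
        t2 = mf.build_parsimony_tree(list(reversed(haps)), exact=False)
        assert t1.parsimony_length() == t2.parsimony_length()
        t3 = mf.build_parsimony_tree(haps, exact=False, shuffle=True, seed=5)
        t3.replay_check()

    def test_root_state_conflict_warns_and_attaches_with_reversions(self):
        root_state = mf.parse_profile("700")
        haps = [Haplotype("A")]  # lacks the root's variant
        with pytest.warns(UserWarning, match="reversion"):
            tree = mf.build_parsimony_tree(haps, root_state=root_state)
        leaf = tree.leaf_map()["A"]
        assert any(m.is_reversion for m in leaf.mutations)

    def test_recurrence_report_flags_repeated_variants(self):
        root = Node(name="root")
        root.add_child(Node(name="L1", mutations=[Variant(16189)]))
        root.add_child(Node(name="L2", mutations=[Variant(16189)]))
        tree = AnnotatedTree(root)
        assert tree.recurrence_report() == {"16189": 2}


class TestLabelling:
    def _tree(self):
        root = Node(name="root")
        big = root.add_child(Node(mutations=[Variant(100), Variant(200)]))
        for i in range(3):
            big.add_child(Node(name=f"L{i}", mutations=[Variant(300 + i)]))
        lone = root.add_child(Node(mutations=[Variant(500)]))
        lone.add_child(Node(name="solo"))
        np60 = root.add_child(Node(mutations=[Variant(60)]))
        np60.add_child(Node(name="M1"))
        np60.add_child(Node(name="M2"))
        tree = AnnotatedTree(root)
        for leaf in tree.leaves():
            leaf.haplotype = Haplotype(leaf.name, variants=tree.state(leaf))
        return tree, big, lone, np60

    def test_eligibility_rules(self):
        tree, big, lone, np60 = self._tree()
        mf.label_haplogroups(tree, prefix="R0a")
        assert tree.root.haplogroup == "R0a"
        assert big.haplogroup == "R0a1"          # 3 haplotypes, 2 mutations
        assert lone.haplogroup == ""             # only 1 descendant
        assert np60.haplogroup == ""             # only mutation is np 60

    def test_labels_nest_with_depth(self):
        rng = np.random.default_rng(5)
        _, tree, haps = mf.simulate_genealogy(
            mf.SimConfig(seed=13, n_source=0, n_sink=25, pulse_time=20000))
        mf.label_haplogroups(tree, prefix="R0a")
        labels = [n.haplogroup for n in tree.root.preorder() if n.haplogroup]
        for lab in labels:
            assert lab.startswith("R0a")
        # nesting: every labelled node's nearest labelled ancestor's label
        # is a proper prefix of its own
        for node in tree.root.preorder():
            if not node.haplogroup or node is tree.root:
                continue
            anc = node.parent
            while anc is not None and not anc.haplogroup:
                anc = anc.parent
            assert anc is not None
            assert node.haplogroup.startswith(anc.haplogroup)


class TestMotifAssignment:
    MOTIFS = [
        mf.HaplogroupMotif("R0a", mf.parse_profile("16126 16362")),
        mf.HaplogroupMotif("R0a1", mf.parse_profile("16126 16362 16355"),
                           parent_label="R0a"),
        mf.HaplogroupMotif("R0a1a", mf.parse_profile("16126 16362 16355 16399"),
                           parent_label="R0a1"),
    ]

    def test_deepest_match_wins(self):
        h = Haplotype("x", variants=mf.parse_profile("16126 16362 16355 16399 73"))
        assert mf.assign_haplogroup(h, self.MOTIFS) == ("R0a1a", 4)

    def test_partial_match_stops_at_parent(self):
        h = Haplotype("x", variants=mf.parse_profile("16126 16362 73"))
        assert mf.assign_haplogroup(h, self.MOTIFS) == ("R0a", 2)

    def test_no_match_returns_none(self):
        h = Haplotype("x", variants=mf.parse_profile("73"))
        assert mf.assign_haplogroup(h, self.MOTIFS) == (None, 0)

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError):
            mf.assign_haplogroup(Haplotype("x"), [])


class TestNewickIO:
    def test_round_trip_topology_mutations_labels(self):
        haps = [Haplotype("A", population="Yemen", region="Arabian Peninsula",
                          variants=mf.parse_profile("100 200")),
                Haplotype("B", population="Iraq", region="Fertile Crescent",
                          variants=mf.parse_profile("100 300")),
                Haplotype("C", variants=mf.parse_profile("100"))]
        tree = mf.build_parsimony_tree(haps)
        mf.label_haplogroups(tree, prefix="R0a")
        buf = io.StringIO()
        mf.write_tree(tree, buf)
        back = mf.read_tree(io.StringIO(buf.getvalue()))
        assert back.parsimony_length() == tree.parsimony_length()
        assert sorted(back.leaf_map()) == ["A", "B", "C"]
        assert back.leaf_map()["A"].haplotype.population == "Yemen"
        assert back.leaf_map()["A"].haplotype.variants == haps[0].variants
        labels = {n.haplogroup for n in back.root.preorder() if n.haplogroup}
        assert labels == {n.haplogroup for n in tree.root.preorder()
                          if n.haplogroup}

    def test_reversion_flag_preserved(self):
        root = Node(name="root")
        leaf = root.add_child(Node(
            name="A", mutations=[mf.parse_variant("@16126")]))
        tree = AnnotatedTree(root, root_state=mf.parse_profile("16126"))
        leaf.haplotype = Haplotype("A", variants=tree.state(leaf))
        buf = io.StringIO()
        mf.write_tree(tree, buf)
        back = mf.read_tree(io.StringIO(buf.getvalue()))
        (mut,) = back.leaf_map()["A"].mutations
        assert mut.is_reversion and mut.position == 16126
        assert back.root_state == mf.parse_profile("16126")

    def test_empty_comment_means_zero_mutation_branch(self):
        back = mf.read_tree(io.StringIO("(A,B[muts=73]);"))
        assert back.leaf_map()["A"].mutations == []
        assert [str(m) for m in back.leaf_map()["B"].mutations] == ["73"]

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(TreeError):
            mf.read_tree(io.StringIO("((A,B);"))
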