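"""Maximum-parsimony construction of mutation-annotated haplotype trees.

Small instances (by default up to 8 haplotypes) are solved exactly by
enumerating all rooted binary topologies and scoring each site with the
Fitch algorithm against the fixed root state; larger instances are built
greedily, attaching haplotypes in order of decreasing profile size at the
node sharing the most derived variants, splitting branches so that private
variants shared by two or more lineages induce new internal nodes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import replace

import numpy as np

from mitofounder.tree import AnnotatedTree, Node, TreeError
from mitofounder.variants import Haplotype, Variant, render_profile

EXACT_MAX_LEAVES = 8


def _toggle_set(haplotype: Haplotype, root_state) -> dict:
    """Variants separating a haplotype from the root state, keyed by site.

    Sites present in the root state but absent from the profile become
    reversion-flagged variants (the haplotype has back-mutated, or the root
    state is derived relative to it).
    """
    prof = {v.site: v for v in haplotype.variants}
    root = {v.site: v for v in root_state}
    out = {}
    for site, v in prof.items():
        if site not in root:
            out[site] = v
    for site, v in root.items():
        if site not in prof:
            out[site] = replace(v, is_reversion=True)
    return out


def parsimony_score(tree: AnnotatedTree) -> int:
    """Total branch mutations of a built tree."""
    return tree.parsimony_length()


def build_parsimony_tree(haplotypes, backbone: AnnotatedTree | None = None,
                         seed: int = 0, root_state=frozenset(),
                         reference: str = "rCRS", shuffle: bool = False,
                         exact: bool | None = None) -> AnnotatedTree:
    """Build a mutation-annotated tree for a set of haplotypes.

    ``backbone`` optionally supplies a starting tree (e.g. an established
    nomenclature skeleton) into which the haplotypes are inserted; it plays
    the role of manual correction against a reference phylogeny. Without a
    backbone, instances of up to ``EXACT_MAX_LEAVES`` haplotypes are solved
    exactly; pass ``exact=False`` to force the greedy heuristic (or
    ``exact=True`` to require the exhaustive search).

    ``seed`` only matters with ``shuffle=True``, which randomises the
    greedy attachment order instead of the default (decreasing profile
    size, ties by sample id).
    """
    haps = list(haplotypes)
    ids = [h.sample_id for h in haps]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise TreeError(f"duplicate sample_ids: {dup}")
    if not haps:
        return AnnotatedTree(Node(name="root"), reference=reference,
                             root_state=frozenset(root_state))

    toggles = {h.sample_id: _toggle_set(h, root_state) for h in haps}
    for h in haps:
        revs = [v for v in toggles[h.sample_id].values() if v.is_reversion]
        if revs:
            warnings.warn(
                f"{h.sample_id} conflicts with the root state at "
                f"[{render_profile(revs)}]; attaching with reversions")

    order = sorted(haps, key=lambda h: (-len(toggles[h.sample_id]), h.sample_id))
    if shuffle:
        rng = np.random.default_rng(seed)
        order = list(order)
        rng.shuffle(order)

    if exact is None:
        exact = backbone is None and len(haps) <= EXACT_MAX_LEAVES
    if exact:
        if backbone is not None:
            raise TreeError("exact search does not support a backbone tree")
        tree = _exact_tree(order, toggles, root_state, reference)
    else:
        tree = _greedy_tree(order, toggles, backbone, root_state, reference)
    tree.collapse_zero_branches()
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Greedy insertion

def _greedy_tree(order, toggles, backbone, root_state, reference):
    if backbone is not None:
        tree = backbone
    else:
        tree = AnnotatedTree(Node(name="root"), reference=reference,
                             root_state=frozenset(root_state))
    for hap in order:
        _greedy_insert(tree.root, dict(toggles[hap.sample_id]), hap)
    return tree

def _greedy_insert(root: Node, remaining: dict, hap: Haplotype) -> None:
    node = root
    while True:
        best, best_overlap = None, set()
        for child in node.children:
            overlap = {m.site for m in child.mutations} & set(remaining)
            if len(overlap) > len(best_overlap):
                best, best_overlap = child, overlap
        if not best_overlap:
            break
        full = len(best_overlap) == len(best.mutations)
        if full and not best.is_leaf:
            for site in best_overlap:
                del remaining[site]
            node = best
            continue
        # split the branch: shared variants move to a new intermediate node
        shared = [m for m in best.mutations if m.site in best_overlap]
        rest = [m for m in best.mutations if m.site not in best_overlap]
        mid = Node(mutations=shared)
        idx = node.children.index(best)
        best.detach()
        node.children.insert(idx, mid)
        mid.parent = node
        best.mutations = rest
        mid.add_child(best)
        for site in best_overlap:
            del remaining[site]
        node = mid
    leaf = Node(name=hap.sample_id, haplotype=hap,
                mutations=sorted(remaining.values(),
                                 key=lambda v: (v.site, str(v))))
    node.add_child(leaf)


# ---------------------------------------------------------------------------
# Exact search: enumerate rooted binary topologies, Fitch-score each site

def _topologies(n: int):
    """All rooted binary topologies on leaf indices 0..n-1 (nested tuples)."""
    trees = [0]
    for leaf in range(1, n):
        nxt = []
        for t in trees:
            for u in _insert_everywhere(t, leaf):
                nxt.append(u)
        trees = nxt
    return trees

def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insert_everywhere(left, leaf):
            yield (sub, right)
        for sub in _insert_everywhere(right, leaf):
            yield (left, sub)

def _fitch_sets(tree, leaf_states):
    """Bottom-up Fitch state sets; returns (sets_by_subtree, score)."""
    if not isinstance(tree, tuple):
        return {tree: frozenset({leaf_states[tree]})}, 0
    lsets, lscore = _fitch_sets(tree[0], leaf_states)
    rsets, rscore = _fitch_sets(tree[1], leaf_states)
    sets = {**lsets, **rsets}
    a, b = lsets[tree[0]], rsets[tree[1]]
    inter = a & b
    if inter:
        sets[tree] = inter
        score = lscore + rscore
    else:
        sets[tree] = a | b
        score = lscore + rscore + 1
    return sets, score

def _score_topology(tree, char_leaf_states):
    total = 0
    roots = []
    for leaf_states in char_leaf_states:
        sets, score = _fitch_sets(tree, leaf_states)
        if 0 not in sets[tree]:
            score += 1  # root edge to the fixed all-ancestral root state
        total += score
        roots.append(sets)
    return total, roots

def _exact_tree(order, toggles, root_state, reference):
    n = len(order)
    sites = sorted({s for t in toggles.values() for s in t})
    # representative variant for each toggled site, keeping the reversion
    # flag chosen by _toggle_set (a root-state site toggled on a branch IS
    # a reversion)
    site_var = {}
    for t in toggles.values():
        for s, v in t.items():
            site_var.setdefault(s, v)
    char_leaf_states = [
        [1 if s in toggles[h.sample_id] else 0 for h in order] for s in sites
    ]
    best, best_score, best_sets = None, None, None
    for topo in _topologies(n):
        score, sets = _score_topology(topo, char_leaf_states)
        if best_score is None or score < best_score:
            best, best_score, best_sets = topo, score, sets
    root = Node(name="root")
    _realise(best, best_sets, [0] * len(sites), root, sites, site_var, order)
    return AnnotatedTree(root, reference=reference,
                         root_state=frozenset(root_state))

def _realise(tree, char_sets, parent_states, parent_node, sites, site_var, order):
    states = []
    for ci, sets in enumerate(char_sets):
        options = sets[tree]
        states.append(parent_states[ci] if parent_states[ci] in options
                      else min(options))
    muts = []
    for ci, (p, s) in enumerate(zip(parent_states, states)):
        if p != s:
            v = site_var[sites[ci]]
            muts.append(v if s == 1
                        else replace(v, is_reversion=not v.is_reversion))
    muts.sort(key=lambda v: (v.site, str(v)))
    if isinstance(tree, tuple):
        node = Node(mutations=muts)
        parent_node.add_child(node)
        _realise(tree[0], char_sets, states, node, sites, site_var, order)
        _realise(tree[1], char_sets, states, node, sites, site_var, order)
    else:
        hap = order[tree]
        parent_node.add_child(
            Node(name=hap.sample_id, haplotype=hap, mutations=muts))
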