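"""Mutation-annotated rooted trees of mtDNA haplotypes.

Nodes are haplotype states; each node's branch (to its parent) carries the
ordered list of mutations separating it from the parent state. Trees are
multifurcating in general: zero-mutation coalescences collapse onto a single
haplotype node, which is how published mtDNA trees are drawn. Leaves map to
sampled :class:`~mitofounder.variants.Haplotype` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from mitofounder.variants import Haplotype, Variant, render_profile


class TreeError(ValueError):
    pass


@dataclass(eq=False)
class Node:
    """A tree node. ``mutations`` sit on the branch from the parent."""

    name: str = ""
    mutations: list[Variant] = field(default_factory=list)
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    haplogroup: str = ""
    haplotype: Optional[Haplotype] = None
    # simulator bookkeeping: node age in years before present (optional)
    time: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def path_to_ancestor(self, ancestor: "Node") -> list["Node"]:
        """Nodes from self up to (and excluding) ancestor."""
        path, node = [], self
        while node is not ancestor:
            if node is None:
                raise TreeError("node is not a descendant of the given ancestor")
            path.append(node)
            node = node.parent
        return path

    def __repr__(self):  # pragma: no cover - debugging aid
        tag = self.name or self.haplogroup or "*"
        return f"<Node {tag} +[{render_profile(self.mutations)}]>"


@dataclass
class AnnotatedTree:
    """A rooted mutation-annotated tree with a declared root haplotype state.

    ``root_state`` is the root haplotype's variant set relative to the
    reference (empty when the root *is* the reference state, e.g. an
    RSRS-rooted tree expressed in RSRS coordinates).
    """

    root: Node
    reference: str = "rCRS"
    root_state: frozenset[Variant] = frozenset()

    def nodes(self) -> list[Node]:
        return list(self.root.preorder())

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_map(self) -> dict[str, Node]:
        out = {}
        for leaf in self.leaves():
            if leaf.haplotype is None:
                continue
            sid = leaf.haplotype.sample_id
            if sid in out:
                raise TreeError(f"duplicate sample_id {sid!r} among leaves")
            out[sid] = leaf
        return out

    def find(self, name: str) -> Node:
        for node in self.root.preorder():
            if node.name == name or node.haplogroup == name:
                return node
        raise TreeError(f"no node named {name!r}")

    def leaf_count_below(self, node: Node) -> int:
        return len(node.leaves())

    def state(self, node: Node) -> frozenset[Variant]:
        """Haplotype state at a node: root state with path mutations replayed.

        Replay toggles site membership, so a recurrent mutation at a site
        already in the state acts as a reversion (back mutation), matching
        the "@" notation.
        """
        path = list(reversed(node.path_to_ancestor(self.root)))
        state = {v.site: v for v in self.root_state}
        for hop in path:
            for mut in hop.mutations:
                if mut.site in state:
                    del state[mut.site]
                else:
                    state[mut.site] = mut
        return frozenset(state.values())

    def mutation_count(self, node: Node, ancestor: Node,
                       count=None) -> int:
        """Number of mutations on the path node -> ancestor.

        ``count`` optionally filters which mutations are counted
        (callable Variant -> bool), e.g. a dating exclusion context.
        """
        total = 0
        for hop in node.path_to_ancestor(ancestor):
            if count is None:
                total += len(hop.mutations)
            else:
                total += sum(1 for m in hop.mutations if count(m))
        return total

    def parsimony_length(self) -> int:
        """Total number of mutations on all branches."""
        return sum(len(n.mutations) for n in self.root.preorder())

    def recurrence_report(self) -> dict[str, int]:
        """Variants appearing on more than one branch (homoplasy)."""
        seen: dict[str, int] = {}
        for node in self.root.preorder():
            for m in node.mutations:
                key = render_profile([m]).lstrip("@")
                seen[key] = seen.get(key, 0) + 1
        return {k: c for k, c in seen.items() if c > 1}

    def collapse_zero_branches(self) -> "AnnotatedTree":
        """Contract internal branches carrying no mutations.

        Leaves are never removed; an internal node whose branch is empty is
        merged into its parent. This turns a binary genealogy into the
        multifurcating haplotype tree that founder analysis operates on.
        """
        for node in list(self.root.preorder()):
            if node is self.root or node.is_leaf:
                continue
            if not node.mutations:
                parent = node.parent
                idx = parent.children.index(node)
                node.detach()
                for i, child in enumerate(list(node.children)):
                    child.parent = parent
                    parent.children.insert(idx + i, child)
                node.children = []
        # also suppress unifurcations left by pruning (merge mutations)
        changed = True
        while changed:
            changed = False
            for node in list(self.root.preorder()):
                if node is self.root or node.is_leaf:
                    continue
                if len(node.children) == 1 and node.haplotype is None:
                    child = node.children[0]
                    child.mutations = node.mutations + child.mutations
                    parent = node.parent
                    idx = parent.children.index(node)
                    node.detach()
                    child.parent = parent
                    parent.children.insert(idx, child)
                    node.children = []
                    changed = True
        return self

    def validate(self) -> None:
        """Check structural invariants; raises TreeError on violation."""
        seen = set()
        for node in self.root.preorder():
            if id(node) in seen:
                raise TreeError("cycle detected")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("broken parent link")
        self.leaf_map()  # raises on duplicate sample ids

    def replay_check(self, context_filter=None) -> None:
        """Verify each leaf's replayed state equals its haplotype profile."""
        for leaf in self.leaves():
            if leaf.haplotype is None:
                continue
            expect = leaf.haplotype.variants
            if context_filter is not None:
                expect = frozenset(v for v in expect if context_filter(v))
            got = self.state(leaf)
            if {v.site for v in got} != {v.site for v in expect}:
                raise TreeError(
                    f"replayed state for {leaf.haplotype.sample_id} is "
                    f"[{render_profile(got)}], profile says "
                    f"[{render_profile(expect)}]")
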