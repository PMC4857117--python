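"""Haplogroup labelling of tree nodes and motif-based classification.

Labels follow the mtDNA nomenclature convention of alternating numeric and
alphabetic suffixes with depth (R0a -> R0a2 -> R0a2b -> R0a2b1 ...). A node
is eligible for a label only when it subtends at least two sampled
haplotypes and its branch carries at least one mutation — ignoring the
unreliable np 60, which is disregarded for clade identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import string

from mitofounder.tree import AnnotatedTree, Node
from mitofounder.variants import (
    ExclusionPolicy, DEFAULT_POLICY, Haplotype, Variant,
)


@dataclass(frozen=True)
class HaplogroupMotif:
    """A named haplogroup with its diagnostic variant motif."""

    label: str
    defining_variants: frozenset[Variant]
    parent_label: str | None = None
    low_confidence: bool = False

    def __post_init__(self):
        if not self.defining_variants:
            raise ValueError(f"motif {self.label} has no defining variants")

    def depth(self, motifs_by_label: dict[str, "HaplogroupMotif"]) -> int:
        d, cur = 0, self.parent_label
        while cur is not None:
            d += 1
            cur = motifs_by_label[cur].parent_label if cur in motifs_by_label else None
        return d


def _countable(node: Node, policy: ExclusionPolicy) -> list[Variant]:
    return [m for m in node.mutations
            if not policy.excludes(m, "clade_id")]


def label_haplogroups(tree: AnnotatedTree, prefix: str = "R0a",
                      policy: ExclusionPolicy = DEFAULT_POLICY,
                      min_haplotypes: int = 2) -> AnnotatedTree:
    """Assign nested haplogroup labels to eligible internal nodes in place.

    The root receives ``prefix``; below it, each eligible node appends an
    index to its labelled ancestor's name, alternating digits and letters
    with nesting depth. Eligibility: at least ``min_haplotypes`` descendant
    haplotypes and at least one branch mutation not at an excluded
    clade-identification site.
    """
    tree.root.haplogroup = prefix

    def walk(node: Node, parent_label: str, digit_level: bool):
        counters = {"i": 0}

        def next_suffix() -> str:
            counters["i"] += 1
            if digit_level:
                return str(counters["i"])
            i = counters["i"] - 1
            out = ""
            while True:
                out = string.ascii_lowercase[i % 26] + out
                i = i // 26 - 1
                if i < 0:
                    return out

        for child in node.children:
            n_haps = sum(1 for leaf in child.leaves()
                         if leaf.haplotype is not None)
            eligible = (not child.is_leaf
                        and n_haps >= min_haplotypes
                        and len(_countable(child, policy)) >= 1)
            if eligible:
                child.haplogroup = parent_label + next_suffix()
                walk(child, child.haplogroup, not digit_level)
            else:
                child.haplogroup = child.haplogroup or ""
                walk(child, parent_label, digit_level)

    # R0a-style prefixes end in a letter, so the first level is numeric
    walk(tree.root, prefix, digit_level=prefix[-1:].isalpha())
    return tree


def assign_haplogroup(haplotype: Haplotype, motifs) -> tuple[str | None, int]:
    """Classify a haplotype by its deepest fully-matched motif.

    Returns ``(label, score)`` where score is the number of matched
    defining variants; ``(None, 0)`` when no motif matches. Ties on depth
    break toward the motif with more defining variants, then the
    lexicographically smallest label. Motif positions outside the
    haplotype's sequenced range raise ``ValueError``.
    """
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif list")
    by_label = {m.label: m for m in motifs}
    sites = {v.site for v in haplotype.variants}
    best = None
    for m in motifs:
        outside = [v for v in m.defining_variants
                   if not haplotype.covers(v.position)]
        if outside:
            raise ValueError(
                f"motif {m.label} touches positions outside the haplotype's "
                f"sequenced range: {sorted(v.position for v in outside)}")
        if all(v.site in sites for v in m.defining_variants):
            key = (m.depth(by_label), len(m.defining_variants),
                   [-ord(c) for c in m.label])
            if best is None or key > best[0]:
                best = (key, m)
    if best is None:
        return None, 0
    return best[1].label, len(best[1].defining_variants)
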