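"""Reading and writing mutation-annotated trees as newick.

Branch mutation lists, haplogroup labels and leaf metadata travel in
square-bracket comment blocks of the form
``[muts=16126 522d @152|label=R0a2|pop=Yemen|region=Arabian Peninsula]``.
Dendropy does the newick parsing/serialisation; this module maps between
dendropy trees and :class:`~mitofounder.tree.AnnotatedTree`.
"""

from __future__ import annotations

import io

import dendropy

from mitofounder.tree import AnnotatedTree, Node, TreeError
from mitofounder.variants import (
    Haplotype, WHOLE_RANGE, parse_profile, render_profile,
)


def _encode_range(rng) -> str:
    return ",".join(f"{a}-{b}" for a, b in rng)


def _decode_range(text: str):
    return tuple(tuple(int(x) for x in part.split("-"))
                 for part in text.split(","))


def _node_comment(node: Node) -> str:
    fields = []
    if node.mutations:
        fields.append("muts=" + render_profile(node.mutations))
    if node.haplogroup:
        fields.append("label=" + node.haplogroup)
    if node.haplotype is not None:
        h = node.haplotype
        if h.population:
            fields.append("pop=" + h.population)
        if h.region and h.region != "unassigned":
            fields.append("region=" + h.region)
        if h.range != WHOLE_RANGE:
            fields.append("range=" + _encode_range(h.range))
    if node.time is not None:
        fields.append(f"time={node.time:.6g}")
    return "|".join(fields)


def _parse_comment(comment: str) -> dict:
    out = {}
    if not comment:
        return out
    for part in comment.split("|"):
        if "=" not in part:
            raise TreeError(f"malformed tree annotation field {part!r}")
        key, val = part.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def write_tree(tree: AnnotatedTree, file) -> None:
    """Serialise a tree (file may be a path or text handle)."""

    def render(node: Node) -> str:
        core = ""
        if node.children:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
        name = node.name if node.is_leaf else ""
        comment = _node_comment(node)
        return core + _quote(name) + (f"[{comment}]" if comment else "")

    header = ""
    root_fields = [f"reference={tree.reference}"]
    if tree.root_state:
        root_fields.append("root_state=" + render_profile(tree.root_state))
    header = "[" + "|".join(root_fields) + "]"
    text = header + render(tree.root) + ";\n"
    if hasattr(file, "write"):
        file.write(text)
    else:
        with open(file, "w") as fh:
            fh.write(text)


def _quote(name: str) -> str:
    if not name:
        return ""
    if any(c in name for c in "()[]{}:;,= \t\n'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def read_tree(file) -> AnnotatedTree:
    """Parse a newick file with mutation annotations back into a tree."""
    if hasattr(file, "read"):
        text = file.read()
    else:
        with open(file) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc

    reference, root_state = "rCRS", frozenset()
    # the tree-level header comment ends up attached to the dendropy tree
    # or its seed node depending on placement; check both
    header_comments = list(dtree.comments) + list(dtree.seed_node.comments)
    seed_fields = {}
    for comment in header_comments:
        fields = _parse_comment(comment)
        if "reference" in fields:
            reference = fields["reference"]
            if "root_state" in fields:
                root_state = parse_profile(fields["root_state"])
        else:
            seed_fields.update(fields)

    def convert(dnode, fields=None) -> Node:
        node = Node()
        merged = dict(fields or {})
        for comment in dnode.comments:
            parsed = _parse_comment(comment)
            if "reference" in parsed:
                continue
            merged.update(parsed)
        if "muts" in merged:
            node.mutations = sorted(parse_profile(merged["muts"]),
                                    key=lambda v: (v.site, str(v)))
        node.haplogroup = merged.get("label", "")
        if "time" in merged:
            node.time = float(merged["time"])
        if dnode.taxon is not None:
            node.name = dnode.taxon.label
        if not dnode.child_nodes() and node.name:
            node.haplotype = Haplotype(
                sample_id=node.name,
                population=merged.get("pop", ""),
                region=merged.get("region", "unassigned"),
                variants=frozenset(),  # filled by replay below
                reference=reference,
                range=(_decode_range(merged["range"])
                       if "range" in merged else WHOLE_RANGE),
            )
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node, seed_fields)
    root.name = root.name or "root"
    tree = AnnotatedTree(root, reference=reference, root_state=root_state)
    # reconstruct leaf profiles by replaying path mutations
    from dataclasses import replace as _replace
    for leaf in tree.leaves():
        if leaf.haplotype is not None:
            leaf.haplotype = _replace(leaf.haplotype,
                                      variants=tree.state(leaf))
    tree.validate()
    return tree
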