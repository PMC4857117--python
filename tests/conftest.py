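import numpy as np
import pytest

from mitofounder.tree import AnnotatedTree, Node
from mitofounder.variants import Haplotype, Variant


@pytest.fixture
def nested_toy_tree():
    """root -(1 mut)- X; X -(1)- L1, X -(1)- L2; root -(1)- L3."""
    root = Node(name="root")
    x = root.add_child(Node(name="X", mutations=[Variant(100)]))
    x.add_child(Node(name="L1", mutations=[Variant(200)]))
    x.add_child(Node(name="L2", mutations=[Variant(300)]))
    root.add_child(Node(name="L3", mutations=[Variant(400)]))
    tree = AnnotatedTree(root)
    for leaf in tree.leaves():
        leaf.haplotype = Haplotype(leaf.name, variants=tree.state(leaf))
    return tree


def random_annotated_tree(rng, n_leaves=8, regions=("A", "B")):
    """A random multifurcating mutation-annotated tree for property tests."""
    counter = iter(range(10_000))
    next_pos = iter(range(1000, 16000))
    root = Node(name="root")
    nodes = [root]
    for i in range(n_leaves):
        parent = nodes[rng.integers(len(nodes))]
        n_mut = int(rng.integers(0, 4))
        leaf = Node(name=f"L{i}",
                    mutations=[Variant(next(next_pos)) for _ in range(n_mut)])
        parent.add_child(leaf)
        if rng.random() < 0.5:
            # promote: give the leaf an internal twin so deeper structure grows
            inner = Node(name=f"I{next(counter)}",
                         mutations=[Variant(next(next_pos))
                                    for _ in range(int(rng.integers(0, 3)))])
            parent.add_child(inner)
            nodes.append(inner)
    for j, inner in enumerate(nodes[1:]):
        if not inner.children:  # no childless internal nodes
            inner.add_child(Node(name=f"L{n_leaves + j}",
                                 mutations=[Variant(next(next_pos))]))
    tree = AnnotatedTree(root)
    for leaf in tree.leaves():
        region = regions[int(rng.integers(len(regions)))]
        leaf.haplotype = Haplotype(leaf.name, population=region + "_pop",
                                   region=region, variants=tree.state(leaf))
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
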