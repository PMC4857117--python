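"""Coalescent simulation of mtDNA genealogies with known demographic truth.

The default demography emulates a refugium-expansion dispersal. The
source is an old, established population of constant size. The sink is
founded from the source at the pulse time T by a small founder group and
expands immediately — modelled as its star-phylogeny limit: a constant
large size below T with an explicit founder-coalescence event at T that
merges all surviving sink lineages. Above T both demes trace back to a
small common refugial pool, whose tight size makes the remaining lineages
coalesce rapidly just beyond the pulse. This produces the star-like
expansion clades and compact founder clusters that skyline and network
analyses report for postglacial mtDNA phylogeography. Deme sizes are
parametrised directly as expected pairwise coalescence times (years).

Mutations are Poisson on branches: under the linear clock the mean is
branch length / rate (default one mutation per 3,624 years over the whole
molecule); under the corrected mode the mean is the increment of the
purifying-selection clock's expected-divergence curve over the branch's
time span, which lets the linear-rate approximation used by founder
analysis be probed against a selection-shaped mutation process. Sites are
drawn uniformly over the molecule minus the conventionally excluded zones
(infinite sites), with an optional hotspot fraction re-using designated
positions to create recurrence.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from mitofounder.tree import AnnotatedTree, Node
from mitofounder.variants import (
    MT_LENGTH, Haplotype, Variant, render_profile,
)

_EXCLUDED_ZONES = ((16519, 16519), (302, 316), (513, 524), (60, 60))


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the seed fully determines the output."""

    seed: int = 0
    n_source: int = 100
    n_sink: int = 50
    pulse_time: float = 15_000.0           # years before present
    source_pairwise_tmrca: float = 60_000.0
    sink_pairwise_tmrca: float = 200_000.0
    refugium_pairwise_tmrca: float = 1_000.0
    founder_event: bool = True             # coalesce sink survivors at T
    mutation_rate_years: float = 3_624.0   # years per expected mutation
    clock_mode: str = "linear"             # linear | corrected
    hotspot_positions: tuple[int, ...] = ()
    hotspot_fraction: float = 0.0
    source_region: str = "Fertile Crescent"
    sink_region: str = "Arabian Peninsula"
    source_population: str = "SourcePop"
    sink_population: str = "SinkPop"

    def __post_init__(self):
        if self.n_sink < 1 or self.n_source < 0:
            raise ValueError("sample sizes must be >= 1 (source may be 0 for "
                             "single-deme clade simulations)")
        if self.pulse_time < 0:
            raise ValueError("pulse_time must be >= 0")
        for name in ("source_pairwise_tmrca", "sink_pairwise_tmrca",
                     "refugium_pairwise_tmrca", "mutation_rate_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clock_mode not in ("linear", "corrected"):
            raise ValueError(f"unknown clock_mode {self.clock_mode!r}")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if self.hotspot_fraction > 0 and not self.hotspot_positions:
            raise ValueError("hotspot_fraction > 0 requires hotspot_positions")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    config: SimConfig
    genealogy: AnnotatedTree          # binary, with node times (years)
    pulse_time: float
    root_time: float
    sink_mrca_time: float | None
    sink_leaf_ids: frozenset[str]
    source_leaf_ids: frozenset[str]

    def mrca_time(self, leaf_ids) -> float:
        """True age of the MRCA of the named leaves."""
        wanted = set(leaf_ids)
        node = None
        for leaf in self.genealogy.leaves():
            if leaf.name in wanted:
                node = leaf if node is None else node
        # climb from one member until all wanted leaves are below
        while node is not None:
            names = {l.name for l in node.leaves()}
            if wanted <= names:
                return node.time
            node = node.parent
        raise ValueError("leaves not found in genealogy")


def _coalesce_segment(rng, lineages, pairwise_tmrca, t, t_end, counter,
                      shrink_rate: float = 0.0):
    """Run a coalescent among ``lineages`` from time t until t_end (or
    until one lineage remains); returns the reached time.

    ``shrink_rate`` g models exponential growth forward in time: backward,
    the deme's pairwise coalescence scale is C(t) = C0 * exp(-g t), so the
    instantaneous rate with k lineages is k(k-1)/2 * exp(g t) / C0 and the
    waiting time has the closed-form inverse used below. g = 0 recovers
    the constant-size Kingman coalescent.
    """
    import math
    while len(lineages) > 1:
        k = len(lineages)
        pair = k * (k - 1) / 2.0
        draw = rng.exponential(1.0)
        if shrink_rate > 0:
            arg = math.exp(shrink_rate * t) \
                + shrink_rate * pairwise_tmrca * draw / pair
            t_next = math.log(arg) / shrink_rate
        else:
            t_next = t + draw * pairwise_tmrca / pair
        if t_end is not None and t_next > t_end:
            return t_end
        t = t_next
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = Node(name=f"n{next(counter)}", time=t)
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = parent
    return t


def _allowed_positions() -> np.ndarray:
    mask = np.ones(MT_LENGTH + 1, dtype=bool)
    mask[0] = False
    for lo, hi in _EXCLUDED_ZONES:
        mask[lo:hi + 1] = False
    return np.flatnonzero(mask)


def _drop_mutations(rng, tree: AnnotatedTree, config: SimConfig) -> None:
    if config.clock_mode == "corrected":
        from mitofounder.dating import default_corrected_clock
        curve = default_corrected_clock().expected_divergence
    else:
        curve = lambda t: t / config.mutation_rate_years
    pool = _allowed_positions()
    used: set[int] = set()
    hot = np.asarray(config.hotspot_positions, dtype=int)
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        mean = curve(node.parent.time) - curve(node.time)
        n_mut = rng.poisson(mean)
        muts = []
        for _ in range(n_mut):
            if hot.size and rng.random() < config.hotspot_fraction:
                pos = int(hot[rng.integers(hot.size)])
            else:
                pos = int(pool[rng.integers(pool.size)])
                while pos in used:  # infinite sites outside hotspots
                    pos = int(pool[rng.integers(pool.size)])
                used.add(pos)
            muts.append(Variant(pos))
        node.mutations = sorted(muts, key=lambda v: v.site)


def simulate_genealogy(config: SimConfig):
    """Simulate one dataset.

    Returns ``(truth, tree, haplotypes)``: the ground truth (including the
    binary genealogy with node times), the collapsed mutation-annotated
    haplotype tree ready for founder analysis and dating, and the sampled
    haplotype records. Fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    counter = iter(range(10 ** 9))

    sink = [Node(name=f"snk{i + 1:03d}", time=0.0)
            for i in range(config.n_sink)]
    source = [Node(name=f"src{i + 1:03d}", time=0.0)
              for i in range(config.n_source)]
    T = config.pulse_time
    t_sink = _coalesce_segment(rng, sink, config.sink_pairwise_tmrca,
                               0.0, T, counter)
    if config.founder_event:
        # the founding bottleneck: all surviving sink lineages coalesce at T
        while len(sink) > 1:
            i, j = sorted(rng.choice(len(sink), size=2, replace=False))
            parent = Node(name=f"n{next(counter)}", time=T)
            parent.add_child(sink[i])
            parent.add_child(sink[j])
            sink[j:j + 1] = []
            sink[i] = parent
    t_src = 0.0
    if source:
        t_src = _coalesce_segment(rng, source, config.source_pairwise_tmrca,
                                  0.0, T, counter)
    pool = sink + source
    t = max(t_sink, t_src, T)
    t = _coalesce_segment(rng, pool, config.refugium_pairwise_tmrca,
                          t, None, counter)
    root = pool[0]
    root.time = root.time if root.time is not None else t
    genealogy = AnnotatedTree(root)
    _drop_mutations(rng, genealogy, config)

    haplotypes = []
    for leaf in genealogy.leaves():
        is_sink = leaf.name.startswith("snk")
        hap = Haplotype(
            sample_id=leaf.name,
            population=(config.sink_population if is_sink
                        else config.source_population),
            region=config.sink_region if is_sink else config.source_region,
            variants=genealogy.state(leaf),
        )
        leaf.haplotype = hap
        haplotypes.append(hap)

    sink_ids = frozenset(h.sample_id for h in haplotypes
                         if h.sample_id.startswith("snk"))
    source_ids = frozenset(h.sample_id for h in haplotypes) - sink_ids

    truth = SimTruth(
        config=config, genealogy=genealogy, pulse_time=T,
        root_time=root.time,
        sink_mrca_time=None, sink_leaf_ids=sink_ids,
        source_leaf_ids=source_ids,
    )
    if sink_ids:
        truth.sink_mrca_time = truth.mrca_time(sink_ids)

    tree = copy.deepcopy(genealogy)
    tree.collapse_zero_branches()
    return truth, tree, haplotypes


def synthetic_reference(length: int = MT_LENGTH, seed: int = 16569) -> str:
    """A seeded synthetic reference sequence (stand-in for a real
    mitogenome reference, for tests and examples only)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Named fixtures

FIXTURE_PRESETS = ("toy_3leaf", "f1f2_demo", "pulse_15ka", "table1_shapes")


def _toy_3leaf_haplotypes():
    from mitofounder.variants import parse_profile
    return [
        Haplotype("A", variants=parse_profile("100 200")),
        Haplotype("B", variants=parse_profile("100 300")),
        Haplotype("C", variants=parse_profile("100")),
    ]


def _f1f2_demo_tree() -> AnnotatedTree:
    """Six-node worked example: sink leaves K1, K2 below node F; F has one
    derived source branch (S1), so F is the f1 founder; no node has two,
    so the f2 founder falls back to the (flagged) root."""
    root = Node(name="root")
    s2 = root.add_child(Node(name="S2", mutations=[Variant(200)]))
    f = root.add_child(Node(name="F", mutations=[Variant(100)]))
    s1 = f.add_child(Node(name="S1", mutations=[Variant(300)]))
    k1 = f.add_child(Node(name="K1"))
    k2 = f.add_child(Node(name="K2"))
    for node, region in ((s2, "Fertile Crescent"), (s1, "Fertile Crescent"),
                         (k1, "Arabian Peninsula"), (k2, "Arabian Peninsula")):
        tree_state = AnnotatedTree(root).state(node)
        node.haplotype = Haplotype(node.name, population=node.name,
                                   region=region, variants=tree_state)
    return AnnotatedTree(root)


def make_fixture(name: str, directory) -> dict:
    """Write a named test fixture to ``directory``; returns the file map."""
    import pathlib

    from mitofounder.profiles_io import write_profiles
    from mitofounder.treeio import write_tree

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    if name == "toy_3leaf":
        from mitofounder.parsimony import build_parsimony_tree
        haps = _toy_3leaf_haplotypes()
        tree = build_parsimony_tree(haps)
        files["profiles"] = directory / "toy_3leaf.tsv"
        files["tree"] = directory / "toy_3leaf.nwk"
        write_profiles(haps, files["profiles"])
        write_tree(tree, files["tree"])
    elif name == "f1f2_demo":
        tree = _f1f2_demo_tree()
        files["tree"] = directory / "f1f2_demo.nwk"
        files["profiles"] = directory / "f1f2_demo.tsv"
        files["scenario"] = directory / "f1f2_demo_scenario.yaml"
        write_tree(tree, files["tree"])
        write_profiles([l.haplotype for l in tree.leaves()],
                       files["profiles"])
        files["scenario"].write_text(
            "name: demo\n"
            "source_regions: [Fertile Crescent]\n"
            "sink_regions: [Arabian Peninsula]\n")
    elif name == "pulse_15ka":
        config = SimConfig(seed=42, n_source=100, n_sink=100,
                           pulse_time=15_000.0)
        truth, tree, haps = simulate_genealogy(config)
        files["tree"] = directory / "pulse_15ka.nwk"
        files["profiles"] = directory / "pulse_15ka.tsv"
        write_tree(tree, files["tree"])
        write_profiles(haps, files["profiles"])
    elif name == "table1_shapes":
        from mitofounder.dating import date_clades, default_clock_model
        from mitofounder.haplogroups import label_haplogroups
        config = SimConfig(seed=7, n_source=0, n_sink=60,
                           pulse_time=20_000.0)
        truth, tree, haps = simulate_genealogy(config)
        label_haplogroups(tree, prefix="S0a")
        table = date_clades(tree, default_clock_model(), context=None)
        files["tree"] = directory / "table1_shapes.nwk"
        files["ages"] = directory / "table1_shapes_ages.tsv"
        write_tree(tree, files["tree"])
        table.to_csv(files["ages"], sep="\t", index=False)
    else:
        raise ValueError(f"unknown fixture preset {name!r}; "
                         f"choose from {FIXTURE_PRESETS}")
    return files
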