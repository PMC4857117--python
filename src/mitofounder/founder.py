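"""Founder analysis: identifying, dating and scanning migration founders.

Given a mutation-annotated tree and a strict partition of sampled leaves
into a source and a sink population, each sink lineage is traced rootward
to its founder node — the first ancestor with at least one (criterion f1)
or two (f2) mutationally *derived* branches leading exclusively into
source-classed lineages. Requiring derived source branches guards against
homoplasy and back-migration by ensuring the founder match is not a tip of
the source phylogeny. Sink leaves sharing a founder node form a founder
cluster, dated by the rho statistic of its sink leaves from the founder
node times a linear founder rate (a time-dependent clock cannot be used
here, so the compromise constant 2,651 yr/mutation is the default for real
data). Founder ages are then scanned over a 0-50 ka grid of 200-year bins,
each cluster spreading its sink-frequency weight as a truncated normal
around its age estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from mitofounder.dating import ClockModel, rho, sigma_rho, FOUNDER_LINEAR_RATE
from mitofounder.tree import AnnotatedTree, Node, TreeError

GRID_START = 0.0
GRID_END = 50_000.0
GRID_STEP = 200.0


# ---------------------------------------------------------------------------
# Scenarios

@dataclass(frozen=True)
class ScenarioPartition:
    """A source/sink partition of regions, with the Palestinian-assignment
    and Iran toggles used for sensitivity analyses."""

    name: str
    source_regions: frozenset[str]
    sink_regions: frozenset[str]
    unassigned_regions: frozenset[str] = frozenset()
    palestinian_mode: str = "with_arabia"  # with_arabia | with_fertile_crescent | unassigned
    include_iran_in_source: bool = True
    palestinian_populations: frozenset[str] = frozenset({"Palestinian"})

    def __post_init__(self):
        if self.source_regions & self.sink_regions:
            raise ValueError(
                f"{self.name}: source and sink regions overlap: "
                f"{sorted(self.source_regions & self.sink_regions)}")
        if self.palestinian_mode not in (
                "with_arabia", "with_fertile_crescent", "unassigned"):
            raise ValueError(f"unknown palestinian_mode {self.palestinian_mode!r}")

    def reciprocal(self) -> "ScenarioPartition":
        return replace(self, name=self.name + "_reciprocal",
                       source_regions=self.sink_regions,
                       sink_regions=self.source_regions)

    def classify(self, region: str, population: str = "") -> str:
        if population in self.palestinian_populations:
            if self.palestinian_mode == "unassigned":
                return "excluded"
            region = ("Arabian Peninsula"
                      if self.palestinian_mode == "with_arabia"
                      else "Fertile Crescent")
        if region == "Iran" and not self.include_iran_in_source \
                and region in self.source_regions:
            return "excluded"
        if region in self.source_regions:
            return "source"
        if region in self.sink_regions:
            return "sink"
        return "excluded"


def _scenario(name, source, sink, **kw):
    return ScenarioPartition(name=name, source_regions=frozenset(source),
                             sink_regions=frozenset(sink), **kw)


#: The seven standard dispersal scenarios (A-G).
SCENARIO_PRESETS: dict[str, ScenarioPartition] = {
    "A": _scenario("southwest_asia_to_eastern_africa",
                   {"Fertile Crescent", "Caucasus", "Iran", "Arabian Peninsula"},
                   {"Eastern Africa"}),
    "B": _scenario("fertile_crescent_to_arabia_and_eastern_africa",
                   {"Fertile Crescent", "Caucasus"},
                   {"Arabian Peninsula", "Eastern Africa"}),
    "C": _scenario("fertile_crescent_to_arabia",
                   {"Fertile Crescent", "Caucasus"},
                   {"Arabian Peninsula"}),
    "D": _scenario("arabia_to_fertile_crescent_with_iran",
                   {"Arabian Peninsula"},
                   {"Fertile Crescent", "Iran", "Caucasus"}),
    "E": _scenario("arabia_to_fertile_crescent",
                   {"Arabian Peninsula"},
                   {"Fertile Crescent", "Caucasus"}),
    "F": _scenario("southwest_asia_to_south_asia",
                   {"Fertile Crescent", "Iran", "North Africa",
                    "Arabian Peninsula", "Caucasus"},
                   {"South Asia"}),
    "G": _scenario("southwest_asia_to_europe",
                   {"Fertile Crescent", "Caucasus", "Iran", "North Africa",
                    "Arabian Peninsula"},
                   {"Europe"}),
}


def partition_leaves(tree: AnnotatedTree, scenario: ScenarioPartition,
                     known_regions=None) -> dict:
    """Map every sampled leaf to ``source``/``sink``/``excluded``.

    ``known_regions`` optionally names the configured region label set;
    leaves with regions outside it raise, listing the offenders.
    """
    out = {}
    offenders = []
    for leaf in tree.leaves():
        if leaf.haplotype is None:
            continue
        h = leaf.haplotype
        if known_regions is not None and h.region not in known_regions:
            offenders.append(f"{h.sample_id}:{h.region}")
            continue
        out[leaf] = scenario.classify(h.region, h.population)
    if offenders:
        raise TreeError("leaves with unknown region: " + ", ".join(offenders))
    return out


# ---------------------------------------------------------------------------
# Founder identification

@dataclass
class FounderCluster:
    """A founder node with the sink leaves that trace back to it."""

    founder_node: Node
    criterion: str
    sink_leaves: list
    derived_source_branches: int
    rho_f: float
    sigma_f: float
    age_years: float = 0.0
    age_sigma_years: float = 0.0
    at_root: bool = False  # no qualifying ancestor: root used, flagged

    @property
    def n_sink(self) -> int:
        return len(self.sink_leaves)


def _derived_source_branch_count(node: Node, classes: dict) -> int:
    """Child branches of ``node`` with >=1 mutation whose (non-excluded)
    descendant leaves are all source-classed. Zero-mutation source tips do
    not count; excluded leaves are invisible."""
    count = 0
    for child in node.children:
        if not child.mutations:
            continue
        labels = {classes[l] for l in child.leaves() if l in classes}
        labels.discard("excluded")
        if labels == {"source"}:
            count += 1
    return count


def identify_founders(tree: AnnotatedTree, partition: dict,
                      criterion: str = "f2") -> list[FounderCluster]:
    """Cluster sink leaves by their founder node under f1 or f2.

    Every sink leaf belongs to exactly one cluster. A sink leaf with no
    qualifying ancestor clusters at the root, flagged ``at_root``.
    """
    need = {"f1": 1, "f2": 2}.get(criterion)
    if need is None:
        raise ValueError(f"criterion must be 'f1' or 'f2', got {criterion!r}")
    counts = {id(n): _derived_source_branch_count(n, partition)
              for n in tree.root.preorder()}
    clusters: dict[int, FounderCluster] = {}
    order: list[int] = []
    for leaf in tree.leaves():
        if partition.get(leaf) != "sink":
            continue
        node, founder, flagged = leaf.parent, None, False
        while node is not None:
            if counts[id(node)] >= need:
                founder = node
                break
            node = node.parent
        if founder is None:
            founder, flagged = tree.root, True
        key = id(founder)
        if key not in clusters:
            clusters[key] = FounderCluster(
                founder_node=founder, criterion=criterion, sink_leaves=[],
                derived_source_branches=counts[key],
                rho_f=0.0, sigma_f=0.0, at_root=flagged)
            order.append(key)
        clusters[key].sink_leaves.append(leaf)
        clusters[key].at_root = clusters[key].at_root or flagged
    out = [clusters[k] for k in order]
    for c in out:
        c.rho_f = rho(tree, c.founder_node, leaves=c.sink_leaves)
        c.sigma_f = sigma_rho(tree, c.founder_node, leaves=c.sink_leaves)
    return out


def date_founder(cluster: FounderCluster,
                 clock: ClockModel | None = None) -> float:
    """Linear founder dating: age = rho_f * founder rate, sigma propagated."""
    rate = (clock.founder_linear_rate if clock is not None
            else FOUNDER_LINEAR_RATE)
    cluster.age_years = cluster.rho_f * rate
    cluster.age_sigma_years = cluster.sigma_f * rate
    return cluster.age_years


# ---------------------------------------------------------------------------
# Migration-time scan

@dataclass
class MigrationScan:
    """Probabilistic distribution of founder clusters across migration times."""

    grid_starts: np.ndarray
    per_founder: list[np.ndarray]
    total: np.ndarray
    criterion: str
    weighting: str = "sink_count"

    @property
    def bin_centers(self) -> np.ndarray:
        return self.grid_starts + GRID_STEP / 2

    def mode_years(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.total))])


def _cluster_mass(age: float, sd: float, edges: np.ndarray) -> np.ndarray:
    if sd <= 0:
        mass = np.zeros(len(edges) - 1)
        idx = int(np.clip(np.searchsorted(edges, age, side="right") - 1,
                          0, len(mass) - 1))
        mass[idx] = 1.0
        return mass
    cdf = norm.cdf(edges, loc=age, scale=sd)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:  # age far outside the grid; degenerate but conserved
        return _cluster_mass(min(max(age, edges[0]), edges[-1] - 1), 0, edges)
    return mass / total  # truncate to the grid and renormalise


def scan_migrations(clusters, clock: ClockModel | None = None,
                    grid=(GRID_START, GRID_END, GRID_STEP),
                    weighting: str = "sink_count") -> MigrationScan:
    """Spread each dated founder cluster's weight over the migration grid.

    Each cluster contributes weight n_sink / total sink count (or an equal
    share with ``weighting="equal"``), distributed as a normal density
    with mean its age and standard deviation sigma_f times the founder
    rate, truncated at zero (and to the grid); a zero-sigma cluster puts
    all mass in the bin containing its age. The total vector sums to 1.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no founder clusters to scan")
    start, end, step = grid
    edges = np.arange(start, end + step / 2, step)
    starts = edges[:-1]
    for c in clusters:
        if c.age_years == 0.0:
            date_founder(c, clock)
    total_sink = sum(c.n_sink for c in clusters)
    per = []
    for c in clusters:
        w = (c.n_sink / total_sink if weighting == "sink_count"
             else 1.0 / len(clusters))
        per.append(w * _cluster_mass(c.age_years, c.age_sigma_years, edges))
    total = np.sum(per, axis=0)
    criterion = clusters[0].criterion
    return MigrationScan(grid_starts=starts, per_founder=per, total=total,
                         criterion=criterion, weighting=weighting)


# ---------------------------------------------------------------------------
# Scenario driver

@dataclass
class FounderReport:
    scenario: ScenarioPartition
    class_counts: dict
    clusters: dict                    # criterion -> list[FounderCluster]
    scans: dict                       # criterion -> MigrationScan

    def clusters_frame(self):
        import pandas as pd
        rows = []
        for crit, cl in self.clusters.items():
            for c in cl:
                rows.append({
                    "criterion": crit,
                    "founder": c.founder_node.haplogroup or c.founder_node.name or "(unnamed)",
                    "n_sink": c.n_sink,
                    "derived_source_branches": c.derived_source_branches,
                    "rho_f": c.rho_f, "sigma_f": c.sigma_f,
                    "age_years": c.age_years,
                    "age_sigma_years": c.age_sigma_years,
                    "at_root": c.at_root,
                })
        return pd.DataFrame(rows)

    def scan_frame(self):
        import pandas as pd
        data = {"bin_start_years": next(iter(self.scans.values())).grid_starts}
        for crit, scan in self.scans.items():
            data[f"{crit}_mass"] = scan.total
        return pd.DataFrame(data)


def run_scenario(tree: AnnotatedTree, scenario: ScenarioPartition,
                 clock: ClockModel | None = None,
                 criteria=("f1", "f2"),
                 weighting: str = "sink_count") -> FounderReport:
    """Partition, identify, date and scan founders for one scenario."""
    partition = partition_leaves(tree, scenario)
    counts = {"source": 0, "sink": 0, "excluded": 0}
    for cls in partition.values():
        counts[cls] += 1
    clusters, scans = {}, {}
    for crit in criteria:
        cl = identify_founders(tree, partition, crit)
        for c in cl:
            date_founder(c, clock)
        clusters[crit] = cl
        if cl:
            scans[crit] = scan_migrations(cl, clock, weighting=weighting)
    return FounderReport(scenario=scenario, class_counts=counts,
                         clusters=clusters, scans=scans)
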