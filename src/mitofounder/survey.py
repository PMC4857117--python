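"""Motif-based haplogroup frequency surveys of control-region databases.

Given per-population collections of control-region profiles and a
diagnostic mutational motif, counts carriers (profiles containing every
defining variant) and emits per-population frequency tables with optional
coordinates for downstream spatial interpolation, plus sample-size-weighted
regional roll-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from mitofounder.haplogroups import HaplogroupMotif
from mitofounder.variants import Haplotype


@dataclass
class PopulationSample:
    """One surveyed population: profiles plus location metadata."""

    population: str
    region: str
    profiles: list
    latitude: float | None = None
    longitude: float | None = None
    exclude_from_interpolation: bool = False

    @property
    def n(self) -> int:
        return len(self.profiles)


def _carries(profile: Haplotype, motif: HaplogroupMotif) -> bool:
    sites = {v.site for v in profile.variants}
    return all(v.site in sites for v in motif.defining_variants)


def motif_frequency(samples, motif: HaplogroupMotif) -> pd.DataFrame:
    """Per-population carrier counts and frequencies (percent) of a motif.

    Rejects zero-size populations and motifs touching positions outside a
    population's surveyed range. Populations flagged
    ``exclude_from_interpolation`` keep their frequencies but carry an
    ``exclude`` marker so outliers (e.g. small isolated islands) can be
    dropped before spatial interpolation.
    """
    rows = []
    for s in samples:
        if s.n == 0:
            raise ValueError(f"population {s.population!r} has no profiles")
        for prof in s.profiles:
            outside = [v.position for v in motif.defining_variants
                       if not prof.covers(v.position)]
            if outside:
                raise ValueError(
                    f"motif {motif.label} touches positions {sorted(outside)} "
                    f"outside the surveyed range of {s.population!r}")
        carriers = sum(1 for p in s.profiles if _carries(p, motif))
        rows.append({
            "population": s.population, "region": s.region,
            "lat": s.latitude, "lon": s.longitude,
            "n": s.n, "carriers": carriers,
            "freq_pct": 100.0 * carriers / s.n,
            "exclude_from_interpolation": s.exclude_from_interpolation,
            "low_confidence_motif": motif.low_confidence,
        })
    return pd.DataFrame(rows)


def regional_rollup(table: pd.DataFrame,
                    region_map: dict | None = None) -> pd.DataFrame:
    """Pooled per-region frequencies: sum(carriers) / sum(n) within region.

    ``region_map`` optionally reassigns populations to regions; every
    population must then be mapped.
    """
    df = table.copy()
    if region_map is not None:
        unmapped = sorted(set(df["population"]) - set(region_map))
        if unmapped:
            raise ValueError(f"populations not mapped to a region: {unmapped}")
        df["region"] = df["population"].map(region_map)
    grouped = df.groupby("region", sort=True).agg(
        n=("n", "sum"), carriers=("carriers", "sum"),
        n_populations=("population", "nunique"))
    grouped["freq_pct"] = 100.0 * grouped["carriers"] / grouped["n"]
    return grouped.reset_index()
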