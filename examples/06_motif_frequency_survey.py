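"""Survey control-region databases for a diagnostic haplogroup motif.

Builds three synthetic population samples, counts carriers of a two-site
motif, and rolls frequencies up by region — the table a spatial
interpolation tool would consume.
"""

import numpy as np

import mitofounder as mf
from mitofounder.variants import CONTROL_REGION_RANGE

rng = np.random.default_rng(0)
motif = mf.HaplogroupMotif("R0a", mf.parse_profile("16126 16362"))

def population(name, region, n, carrier_fraction, lat, lon):
    profiles = []
    for i in range(n):
        toks = "16126 16362" if rng.random() < carrier_fraction else "16223"
        profiles.append(mf.Haplotype(f"{name}_{i}", population=name,
                                     variants=mf.parse_profile(toks),
                                     range=CONTROL_REGION_RANGE))
    return mf.PopulationSample(population=name, region=region,
                               profiles=profiles, latitude=lat, longitude=lon)

samples = [
    population("Yemen", "Arabian Peninsula", 120, 0.25, 15.4, 47.5),
    population("Oman", "Arabian Peninsula", 80, 0.10, 21.0, 57.0),
    population("Ethiopia", "Eastern Africa", 150, 0.08, 9.0, 39.5),
]

table = mf.motif_frequency(samples, motif)
print(table[["population", "region", "n", "carriers", "freq_pct"]]
      .to_string(index=False))
print()
print(mf.regional_rollup(table).to_string(index=False))

# Per-population rows carry coordinates for mapping; the roll-up pools
# carriers over each region (sum of carriers / sum of n), so it always
# lies between the most and least frequent population of the region.
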