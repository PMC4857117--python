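"""Parse mtDNA mutation-notation profiles and apply site exclusions.

Builds three haplotypes from notation strings, filters them with the
conventional phylogeny exclusions (np 16519, the C-stretch length variants
around nps 309/315, the AC indels at nps 515-522), and prints both forms.
"""

import mitofounder as mf

raw = {
    "YEM001": "263 309.1C 315.1C 522d 16126 16362 16519",
    "YEM002": "263 315.1C 16126 16355 16362",
    "ETH001": "263 16093Y @152 16126 16362 16519",
}

for sample_id, tokens in raw.items():
    profile = mf.parse_profile(tokens)
    kept = mf.apply_exclusions(profile, context="phylogeny")
    print(f"{sample_id}: {mf.render_profile(profile)}")
    print(f"   phylogeny-informative: {mf.render_profile(kept)}")

# Each second line keeps only the variants that enter tree building;
# length variants and the hypermutable np 16519 are set aside, while
# heteroplasmies (Y) and reversions (@) survive with their flags.
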