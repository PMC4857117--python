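# Methods

This note documents the models implemented in `mitofounder`, the choices
made where the methodology left room, and what the synthetic validation
does and does not demonstrate.

## Mutation notation and site handling

Variants are parsed from the standard position-based shorthand: bare
positions are transitions, base suffixes transversions, `d` deletions,
`.kN` insertions (dot-index plus inserted bases), `@` reversions, `R`/`Y`
point heteroplasmies. Coordinates are 1-based on the 16,569-np molecule;
canonical rendering round-trips through the parser.

Three exclusion contexts reflect community practice:

* **phylogeny** — np 16519 plus length variants in the C-stretch zone
  (nps 302–316) and the AC-indel zone (nps 513–524). Indel tokens
  anywhere in 513–524 are excluded because laboratories report the AC
  indels inconsistently (522d vs 523d vs 524.1AC).
* **clade_id** — additionally np 60, which is too unreliable to define
  clades.
* **ml_dating** — np 16519 plus the hypervariable 16182C/16183C
  transversions.

Heteroplasmies count as mutations by default (they appear as ordinary
branch mutations in published trees); `ExclusionPolicy(count_heteroplasmies=False)`
removes them from ρ counts, since whether the original analyses counted
them is not documented.

Reference rebasing (rCRS ↔ RSRS) is a symmetric difference against a
user-supplied difference table restricted to the haplotype's sequenced
range. Real reference sequences and the canonical difference list are
deliberately *not* bundled: tests and examples use a seeded synthetic
reference generator (`synthetic_reference`, labelled synthetic), and real
analyses supply their own FASTA/difference files.

## Tree construction

Trees are rooted, multifurcating, mutation-annotated haplotype trees:
node = haplotype state, branch = ordered mutation list, leaves =
samples. Replay of path mutations from the root state toggles site
membership, so recurrent hits and `@`-flagged reversions fall out of the
same mechanism, and every leaf's replayed state must equal its profile
(a validated invariant).

Construction is maximum parsimony with a fixed root state:

* **Exact** (default up to 8 haplotypes): every rooted binary topology is
  enumerated and each site scored with the Fitch algorithm against the
  fixed root; the best tree is realised with a parent-preferring
  traceback and zero-mutation branches are collapsed. This guarantees the
  true parsimony optimum on small instances.
* **Greedy** (larger instances, or with a backbone): haplotypes are
  attached in order of decreasing profile size (ties by sample id;
  optionally a seeded shuffle) at the node sharing the most derived
  variants, splitting branches so that private variants shared by two or
  more lineages induce new internal nodes. The greedy tree is always
  replay-consistent but may exceed the optimum under heavy homoplasy —
  measured on random homoplasy-rich instances it is optimal roughly half
  the time, which is why small instances are solved exactly.

An optional user-supplied backbone tree plays the role that manual
correction against an established reference phylogeny plays in practice:
insertions extend the backbone reproducibly instead of hand editing.
Equally parsimonious placements are resolved by the documented
deterministic tie-breaks (largest overlap, then child order); published
software does not specify its own resolution, so no attempt is made to
mimic it.

Haplogroup labels: an internal node is eligible if it subtends ≥ 2
sampled haplotypes (configurable) and its branch carries ≥ 1 mutation not
at a clade-identification-excluded site; labels nest by alternating
numeric/alphabetic suffixes with depth. Motif classification returns the
deepest fully matched motif, ties broken by motif size then label.

## Clade dating

ρ and Saillard's σ are computed from branch statistics (m_b, n_b) below a
node, optionally restricted to a leaf subset (used by founder clusters
and by regional diversity contrasts). The identity
ρ = Σ m_b n_b / n is verified against direct path summation on random
trees in the test suite; σ is verified against the standard deviation of
ρ under Poisson re-draws of branch mutation counts.

The purifying-selection-corrected clock models expected observed
divergence after `t` years as

    d(t) = t / r_inf + tau * (1/r_0 - 1/r_inf) * (1 - exp(-t/tau))

with the time-zero rate r_0 = 2,562 yr/mutation and the long-run rate
r_inf = 3,624 yr/mutation treated as fixed constants of the calibration,
and a single relaxation time τ fitted by least squares (in divergence
space) to the packaged table of published (divergence, age) pairs. The
fitted τ ≈ 42.5 ka is the characteristic time over which selection purges
the transient excess of observable mutations. The form guarantees the
constraints the correction must satisfy — age(0) = 0, strict monotonicity,
2562·d ≤ age(d) ≤ 3624·d, and a nondecreasing effective rate — and,
unlike an interpolating spline, extrapolates sensibly beyond the largest
calibration divergence. Five clades are withheld from the calibration
table entirely and serve as held-out validation: the fitted clock
reproduces their published ages to ≤ 0.03 ka. Ages are obtained by Brent
inversion of d(t); confidence intervals transform divergence ± 1.96·SE
through the curve with the lower bound clipped at zero, which reproduces
the published clipped interval for the shallowest validation clade.

Whether published σ values for nested clades were computed on filtered or
full mutation sets is not documented; ρ/σ here default to counting all
annotated branch mutations, with the dating exclusion context available
via `context="ml_dating"`. Indels are counted (configurable through the
exclusion policy) since the convention for ρ is unstated.

Clade tables include labelled nodes with ≥ 3 mitogenomes by default,
with a whitelist for deliberate exceptions; imported maximum-likelihood
divergences (never estimated here) convert through the same clock.

## Founder analysis

The partition of leaves into source/sink/excluded honours two sensitivity
toggles: Palestinian samples can be classed with Arabia, with the Fertile
Crescent, or excluded; Iranian lineages can be dropped from the source.
Seven standard dispersal scenarios (A–G: Southwest Asia→Eastern Africa,
Fertile Crescent→Arabia+Eastern Africa, Fertile Crescent→Arabia, the two
reciprocal Arabia→Fertile Crescent analyses with and without Iran,
Southwest Asia→South Asia, Southwest Asia→Europe) ship as presets, and
`ScenarioPartition.reciprocal()` swaps source and sink for directionality
checks.

A "derived branch in the source population" is a child branch with at
least one mutation whose non-excluded descendant leaves are all
source-classed: zero-mutation source tips do not qualify (the match must
not be a tip of the source phylogeny), and excluded leaves are invisible
to both qualification and dating. Each sink leaf walks rootward to the
first node with ≥ 1 (f1) or ≥ 2 (f2) such branches; leaves with no
qualifying ancestor cluster at the root and are flagged rather than
dropped. f2 founders are provably ancestor-or-equal of f1 founders, so
f2 cluster counts never exceed f1 counts (tested).

Founder dating is deliberately linear (a time-dependent clock is
incompatible with the founder method's assumptions): age = ρ_f × rate
with 2,651 yr/mutation by default — the published compromise between the
time-zero (2,562) and oldest-founder (2,667) rates, consumed as a
constant since its derivation is not documented. On synthetic data the
matched rate is the simulator's own (3,624): applying the real-data
compromise to selection-free simulations would understate ages by
construction.

The migration-time scan spreads each cluster's weight
(n_sink / Σ n_sink; equal weighting available) over 250 bins of 200 years
from 0 to 50 ka as a normal density centred on the cluster age with SD
σ_f × rate, truncated to the grid and renormalised; σ_f = 0 puts all
mass in the bin containing the age. The published method does not state
its spreading density; the truncated normal matches the ρ ± σ usage
elsewhere and the density provider is replaceable. Total mass is 1 by
construction, and shifting all founder ages shifts the scan mode
accordingly (both tested). Per-founder partitions behind published scans
are not printed anywhere, so real-data peak heights are reproducible only
qualitatively.

## The synthetic-data generator

`simulate_genealogy` produces a two-deme structured coalescent with a
founder pulse: a sink founded from a source at time T. The default
demography is the refugium-expansion situation the real system describes:

* **source** — old established population, constant size below T
  (pairwise TMRCA 60,000 yr ≈ Nef 2,400 at 25 yr/generation);
* **sink** — founded at T and expanding; modelled in its star-phylogeny
  limit as a constant large deme (pairwise TMRCA 200,000 yr ≈ Nef 8,000)
  whose surviving lineages coalesce instantaneously at T (the founder
  bottleneck);
* **refugium** — above T both demes merge into a small common ancestral
  pool (pairwise TMRCA 1,000 yr ≈ Nef 40), so remaining lineages
  coalesce within a few centuries beyond the pulse.

Constant-size and growth-to-refugium variants of the sink were examined
while designing the generator; both smear within-sink coalescence far
below T (constant size) or funnel the deme to a single lineage with
coalescence spread over millennia (exponential decline), neither of which
reproduces the star-like expansion clades that skyline and network
analyses report for postglacial mtDNA. The founder-event limit does.

Mutations are Poisson per branch. Under the linear mode the mean is
branch length / 3,624 yr; under the corrected mode it is the increment of
the corrected clock's expected-divergence curve over the branch's time
span, so the bias of the linear founder approximation under a
selection-shaped process can be probed. Sites are uniform over the
molecule minus the excluded zones with infinite-sites bookkeeping; an
optional hotspot fraction re-uses designated positions to create
recurrence for homoplasy testing. All mutations are transitions (the
dominant class in mtDNA); kinds other than transitions are exercised by
the parser/caller tests rather than the simulator. A fixed seed yields
byte-identical output files.

What the simulator does *not* emulate: population structure within demes,
selection on individual sites, rate heterogeneity along the molecule
beyond hotspots, sequencing error, and sampling bias. Passing recovery
tests therefore shows the estimators are correct under the model's
assumptions — not that real datasets satisfy those assumptions.

## Validation scale and known limitations

Test problem sizes: property suites run on hundreds of random trees of
≤ 12 leaves; exact-parsimony cross-checks on all random instances of
≤ 5 leaves against an exhaustive topology/Fitch oracle; recovery runs use
100 replicates of 150 samples (founder scan) and 200 replicates of 25
samples (ρ unbiasedness), which keep the full suite within a few minutes
on one core.

ρ × 3,624 recovers true clade ages to within ~2% on average. Founder
recovery of a 15 ka pulse from 50 sink samples has an irreducible floor:
each lineage carries only ~4.1 expected mutations back to the pulse, so
even a perfect star genealogy leaves SE(ρ × 3,624) ≈ 1.04 ka, and shared
branches in realistic genealogies roughly double that. The measured rate
of landing within ±1 ka of the truth is ~38% of replicates (mean scan
mode on target); a recovery-rate goal of 80% at this sample size is
beyond the Fisher information of the data for any unbiased estimator, and
the corresponding acceptance test documents this by failing. Users
planning founder analyses should treat ±1–2 ka as the realistic
resolution at these sample sizes, matching the spread between published
f1/f2 peak estimates for the same events.
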