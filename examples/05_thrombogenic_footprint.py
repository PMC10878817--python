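"""The platelet stress-accumulation footprint of an implant analogue.

Platelet surrogates (3 um, 1125 kg/m^3) are seeded upstream, advected
through the steady leak flow, and each trajectory accumulates
SA = sum sigma dt from the viscous stress invariant along its path.
The endpoint-SA population yields a log-scale PDF, an activation
fraction against a threshold (here the dynamic-similarity image of
Hellum's 3.5 Pa s at the scaled drive), a bulk/tail split about that
threshold, and a bootstrap check that the fraction is independent of
the seeded population size.
"""

from stenoflow import (ActivationCriterion, AdvectionConfig,
                       analyze_population, advect, make_scenario, run_flow,
                       seed_particles)

sc = make_scenario("CAS_post_pvl", rng_seed=1)
flow = run_flow(sc, duration=10.0, output_stride=1000, drive="constant")

ens = seed_particles(10_000, sc.geometry, rng_seed=1,
                     initial_longitudinal_velocity=1.0)
umax = max(float(s.speed().max()) for s in flow.snapshots)
dt = min(0.2 * sc.geometry.lattice_spacing / umax, 0.08)
res = advect(ens, flow, AdvectionConfig(time_step=dt, max_time=0.8),
             sc.particles)
print("exit census:", res.counts_by_exit())

threshold = 3.5 * sc.gradient_scale  # scaled Hellum criterion
pop = analyze_population(res.sa, ActivationCriterion(threshold), rng_seed=1)
print(f"n = {pop.n}, activation fraction "
      f"{100 * pop.activation_fraction:.1f}% at {threshold:.2e} Pa s")
print(f"PDF bulk mode at {pop.pdf.mode:.3e} Pa s; "
      f"tail mass {pop.regions['tail'].mass:.3f}, "
      f"bulk mass {pop.regions['bulk'].mass:.3f}")
for size, (lo, hi) in pop.bootstrap.fraction_ci.items():
    print(f"  bootstrap n={size}: fraction CI [{100 * lo:.1f}%, "
          f"{100 * hi:.1f}%]")
print("population-size independent:", pop.bootstrap.compatible)
# The full-population fraction falling inside every resample-size CI
# shows the footprint statistics are not an artifact of particle count.
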