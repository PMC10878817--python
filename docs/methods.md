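# Methods

## Scope and model chain

stenoflow computes the haemodynamic chain of a comparative
valve-stenosis study on synthetic desk-scale geometries: a 2D channel
(longitudinal +x, walls on the first and last lattice rows) carries a
plate occluder perforated either by a stenotic/post-implant orifice or
by paravalvular gap channels. Flow is driven by a pressure difference
between the inlet and outlet faces; platelet surrogates are advected
through the resolved field and their viscous stress history is
integrated into a stress-accumulation (SA) population. The chain is
deliberately 2D: the comparative quantities of interest (jet ordering,
leak-volume ordering, activation-fraction similarity) are orifice-area-
and gap-width-driven mechanisms that a channel-plus-occluder plane
preserves, at a computational cost that allows the whole study to run
in minutes on one CPU. A 3D velocity set (D3Q19) is defined and tested
at the lattice level, but the stepping solver is 2D.

## Flow solver

D2Q9 BGK with half-way bounce-back at solid cells and Guo forcing for
body-force-driven cases. The collision operator is a pluggable callable
(`collide=` in `step`), BGK being the only shipped implementation: all
target flows are laminar and low-Mach, where single- and
multi-relaxation-time operators agree. Pressure boundaries are Zou–He
density conditions: the outlet column is held at the reference density
and the inlet column at 1 + Δp/(ρ c_s² (dx/dt)²). The six boundary
unknowns are closed by mass/momentum balance plus bounce-back of the
normal non-equilibrium part; the closure is verified against the
plane-Poiseuille closed form (L2 error 0.07% at 33 cells across, wall
shear within 2%, convergence order ≈ 1.9 over resolutions 16→64).

Unit mapping is diffusive: given spacing dx and relaxation time τ the
time step is dt = c_s²(τ−½) dx²/ν so the lattice viscosity reproduces
the fluid's kinematic viscosity exactly. τ ≤ ½ is refused, not
attempted. Each output frame logs max velocity, lattice Mach number and
the mass residual; a Mach number above 0.17 aborts with advice to
refine the lattice. Fluids initialise at rest; pulsatile runs discard a
configurable warm-up (default one cardiac period).

### Numerical caveats

* The Zou–He pair imposes a density (hence pressure) difference, so the
  *volumetric* flux varies along the channel by the relative density
  difference Δρ ≈ Δp/(ρ (dx/dt)² c_s²). At the preset τ = 1.0 this is a
  few percent; where sub-percent flux uniformity matters (the
  flux-conservation check), τ = 0.6 gives a finer time step and pushes
  the compressibility residual well below 1%.
* Start-up to steady state is governed by viscous diffusion across the
  channel, time constant H²/(π²ν) ≈ 3 s for the 10 mm presets; steady
  analyses run 8–10 s of physical time (the orderings are stable long
  before that).

## Synthetic scenarios

The presets encode the comparative design on a 10 mm channel at 0.2 mm
spacing (50 cells across), with upstream/downstream extensions of three
channel widths around the occluder:

| preset | opening | drive |
|---|---|---|
| healthy | 74.8% open fraction, circular | 10 mmHg half-sine peak |
| CAS_pre | 15.7% open, circular | 99 mmHg half-sine peak |
| FAS_pre | 17.7% open, triangular | 74 mmHg half-sine peak |
| CAS_post_pvl | sealed + 2 × 1.0 mm leaflet-stent gaps | constant 90/0 mmHg |
| FAS_post_pvl | sealed + 3 × 0.4 mm commissural gaps | constant 90/0 mmHg |

Open fractions are the clinical orifice areas (3.38, 0.71, 0.80 cm²)
divided by a 24 mm annulus reference area (4.52 cm²), so pre-implant
CAS < FAS and the healthy valve is wide open; the 10 mmHg healthy peak
is a typical normal transvalvular gradient. Post-implant gap layouts
mirror the observed leak morphologies: the calcific case leaks through
a few wide channels between the bulky native leaflets and the stent,
the fibrocalcific case through several narrow commissural channels.

Aperture rasters are cell-centre rasterisations corrected by toggling
boundary cells (ordered by signed distance) until the cell count
matches the requested area to within half a cell — so circular and
triangular apertures of equal requested area occupy equal cell counts.
In the 2D flow plane an aperture reduces to a centred slit of width
area/depth, with the out-of-plane depth defaulting to the channel
width; every reported area or volume records this conversion.

The waveform template is one half-sine over the first 37.5% of a 0.8 s
period (systole) and exactly zero for the remaining 500 ms (diastole);
only the amplitude differs between cases. The diastolic level is a free
choice (the clinical waveforms are only characterised by their peak);
zero is the simplest level consistent with a closed valve.

### Dynamic-similarity scaling of the drive

At clinical amplitudes the stenotic jet would reach ~5 m/s, i.e. jet
Reynolds numbers of order 10⁴ — transitional flow that no desk-scale
laminar lattice resolves. The presets therefore store the *true*
calibrated waveform (peaks 99/74 mmHg) together with an explicit
`gradient_scale` (10⁻⁵) that the solver applies to the driving pressure
difference. The factor is identical for every preset, so all
cross-preset orderings and ratios are preserved; reported magnitudes
(mm/s jets, ~10⁻² ml/beat leaks) are desk-scale analogues, not
physiological predictions. The scale is recorded in the scenario and in
run provenance.

Consistently, the activation threshold used for preset footprints is
the dynamic-similarity image of Hellum's criterion: stresses scale
linearly with the drive in this laminar regime and exposure times are
unscaled, so SA scales by `gradient_scale` and the scaled threshold is
3.5 Pa·s × 10⁻⁵. With an explicit threshold both the library and the
CLI use the unscaled 3.5 Pa·s.

## Particle transport

Platelet surrogates default to 3 µm diameter and 1125 kg/m³. Seeding is
uniform over an upstream (aortic-side) region with an initial
longitudinal velocity of 1 m/s; populations default to 10 000. Two
coupling modes:

* **tracer** — position integrated by euler or rk4 (default) on the
  multilinearly interpolated velocity;
* **stokes_drag** — the particle velocity relaxes toward the local
  fluid velocity with τ_p = ρ_p d²/(18 μ) ≈ 1.6·10⁻⁷ s, integrated by
  an exponential (exact-relaxation) update. τ_p makes the drag ODE far
  too stiff for explicit stepping at any practical Δt; the exponential
  scheme is exact for locally constant fluid velocity, reproduces the
  still-fluid decay v₀e^(−t/τ_p) to machine precision, and recovers
  tracer behaviour in the platelet limit (endpoint SA agrees with
  tracer within 1% on a parabolic channel).

Wall encounters are pure elastic collisions: the offending coordinate is
mirrored about the cell face and its velocity component flipped (speed
preserved to machine precision); a particle still in solid after
reflection is frozen and counted. The inlet face reflects; crossing the
outlet face ends the trajectory, as does reaching `max_time` (default
one cardiac period — single passage). Unsteady series are held
piecewise-constant between output frames; the default uses one frozen
snapshot (the steady/diastolic field), which matches how the footprint
is evaluated on a steady flow. The particle CFL (max speed × Δt /
spacing) must stay below 1 or the configuration is refused.

Velocity gradients are central differences of the grid field,
interpolated to the particle position (exact for linear fields,
second-order on smooth ones). Near walls the gradient uses the zeroed
solid-cell velocities, consistent with no-slip but smearing the
gradient over the last half cell.

## Stress accumulation and footprint statistics

2D gradients are embedded in 3D with zero out-of-plane components
before the invariant. SA uses left-Riemann quadrature (Σ σ_k Δt, the
discrete definition), trapezoid available by flag; SA is additive over
concatenated segments, and the constant-σ identity 7 Pa × 0.5 s =
3.5 Pa·s lands exactly on the activation threshold (strict inequality:
not activated).

The PDF uses 64 log-spaced bins spanning [min positive SA / 2,
2 × max SA]; zero-SA particles go to an explicit atom (log bins cannot
hold them) so continuous mass + zero atom = 1 exactly. Activation is
the fraction strictly above threshold. The bulk/tail split is taken at
the threshold (tail = activation-prone right tail); a percentile-based
alternative was considered and rejected as redundant with the
threshold-based one. Bootstrap defaults: resample sizes 1000, 2500,
5000, 10 000 with 1000 replicates and percentile 95% CIs; the
size-independence verdict is that the full-population fraction lies in
every size's CI.

## Metrics

* Plane flux: Σ u_long × (spacing × depth) over the open cells of a
  cross-section; positive = downstream (the regurgitant direction in
  leak presets, where the drive reverses the clinical orientation).
* Leak volume: |∫Q dt| over a 500 ms window, ml/beat; steady diastolic
  runs hold the final steady flux over the window, time-resolved series
  are integrated by trapezoid.
* EOA: continuity ratio Q/v_peak on the jet plane, evaluated *at the
  orifice plane*: at creeping-flow scale there is no inertial vena
  contracta, and a downstream plane sees the viscously spread jet
  rather than its core. A velocity-threshold variant (cells above half
  the peak) is available. The continuity EOA is bounded by the
  geometric opening on the stenotic presets (ratio ≈ 0.74,
  near-parabolic slit profiles).
* Wall shear stress: μ × one-sided second-order normal gradient with
  the no-slip plane half a cell beyond the first fluid row (the
  bounce-back wall location); exact on parabolic profiles. Occluder
  columns without two fluid neighbours are skipped and logged.
* Peak jet velocity: max speed over snapshots and cells, with time and
  location.

A note on the stenotic-jet mechanism: at *fixed pressure drive* the
peak jet speed is nearly independent of orifice area (the Bernoulli
limit, with viscous losses penalising the smallest openings), so "jet
speed rises as the orifice shrinks" holds per unit flow rate —
v_peak/Q increases strictly as the open area falls — which is the
continuity mechanism behind clinical stenotic jets and the form the
test suite asserts. The CAS-vs-FAS comparison itself (smaller orifice
*and* higher gradient versus larger orifice and lower gradient)
produces the expected jet ordering directly.

## Pipeline, seeding, provenance

`RunConfig` is schema-validated (unknown keys rejected). One global
seed fans out to per-stage seeds through `numpy.random.SeedSequence`,
so a stage can be re-run in isolation with an identical stream; all
seeds stay below 2³¹. Outputs (scenario JSON, VTK + npz flow series
with a JSON manifest, SA population CSV, PDF CSV, footprint summary
JSON, metric report JSON) are inventoried with SHA-256 checksums in a
run record whose config hash covers exactly the semantically meaningful
fields (not the output directory or log level). Fixed seeds give
byte-identical output trees. A stage failure leaves earlier outputs
intact and drops a `FAILED_<stage>.json` marker.

## What the synthetic scenarios do and do not show

The generator emulates: orifice-area-driven jet formation under
calibrated pressure pulses; commissural versus leaflet-stent leak
morphologies under a diastolic pressure difference; and the SA
footprint machinery end to end. It does not emulate: 3D sinus and
leaflet geometry, leaflet motion or any fluid-structure interaction,
transitional/turbulent jet physics at clinical amplitudes, or
patient-specific anatomy. Passing tests therefore validate the
numerical chain and the direction of the comparative effects, not
clinical magnitudes: leak volumes, jet speeds and activation fractions
are analogue-scale and become clinically meaningful only through the
orderings and ratios between presets run under identical scaling.

## Problem sizes

Default test and acceptance runs use: Poiseuille channels of 16–64
cells across; comparative presets on 52 × 303 lattices run for 8–10 s
of physical time (≈ 4000–5000 steps); 4000–10 000 particles; 1000
bootstrap replicates. These sizes keep the full suite and the
acceptance script in the minutes range on one CPU while leaving every
measured order/oracle comfortably inside its tolerance.
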