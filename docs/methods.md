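# Methods

## Scope and model chain

The package reconstructs the computational chain of a confined-space
blast-tube experiment: a high-pressure driver ruptures into a long driven
channel, the incident shock discharges through a diverging nozzle into a
closed cylindrical test room where an animal is exposed, and the biological
outcome is analysed as a 17-animal cohort.  Three model layers are
implemented and cross-checked against each other:

1. ideal (calorically perfect, inviscid, instantaneous-diaphragm)
   shock-tube theory;
2. an axisymmetric 2D compressible Euler solver;
3. the cohort statistics and a synthetic generative model of the
   experiment.

## Gas model and shock-tube theory

Air is treated as a perfect gas with γ = 1.4 and R = 287 J/(kg K).  Both
tube sections are taken at T = 293 K: the publication states the animal
room at 24 °C but never the tube temperature, so a single laboratory
temperature (and hence a₁ = a₄) is assumed, exactly as the "simple shock
tube theory" it invokes does.  The diaphragm-ratio relation is inverted by
Brent bracketing on the feasible Mach interval followed by a Newton polish
(relative tolerance 1e-12); the function is strictly increasing there, so
the root is unique.

At the operating point the ideal closure gives Ms(22.5) = 1.866 against the
measured 1.859 (+0.36%), and conversely P4/P1(1.859) = 22.04 against the
printed 22.5 (−2%).  The 2–3% gap is the printed rounding of the operating
point plus real-tube losses (finite double-diaphragm rupture, wall friction
and heat exchange), which is precisely why the effective driver pressure
2.3 MPa — not the nominal 3.0 MPa — reproduces the measured Mach number.
The 2.3/3.0 factor is extended proportionally to the other nominal settings
as a package convention; only the 3.0 MPa point is experimentally anchored.

## The WAF solver

The finite-volume scheme is the weighted-average-flux (WAF) method: the
intercell flux averages the physical fluxes of the local Riemann fan states
weighted by the fraction of the face each wave sweeps during the step,
with TVD limiting of the wave weights (van Leer limiter by default;
minmod and superbee available).  The fan is HLLC (PVRS pressure-based wave
speeds with Davis direct bounds as a safeguard); the exact Riemann solver
is kept as the verification oracle and for the Godunov reference scheme.
The limiter ratio uses the density jump carried by each wave at the upwind
interface.

The axisymmetric 2D update is dimension-split with alternating sweep order
(a Strang pair over two steps).  The radial sweep uses the geometric
(r-weighted) flux divergence plus a p/r pressure source on the radial
momentum only, so mass and energy are conserved exactly in closed domains
(verified to 1e-10 over 1000 steps) while uniform states are preserved to
round-off.  The time step is global CFL (default 0.4).

Solid geometry is a stair-stepped cell mask, exact for this axis-aligned
geometry except the thin nozzle lip, which collapses to one cell wherever
the mesh is coarser than its 5 mm wall (a warning is issued).  At every
fluid–solid face the flux is the exact one-sided Riemann wall solution
(shock branch by Newton, rarefaction branch closed-form), which has zero
mass and energy flux by construction — this keeps closed-domain
conservation exact and reproduces the analytic reflected-shock wall
pressure to 0.001% in the 1D test.  Closed outer boundaries use the same
wall flux; an outflow (zero-gradient) option exists for the open-room
comparison.

Because the scheme preserves uniform states and CFL < 1 bounds wave travel,
a run may restrict each step's sweeps to the axial window that has been
disturbed ("active window"); this is bit-equivalent up to round-off
(regression-tested) and roughly halves the cost while the shock transits
the 5.8 m channel.

Adaptive mesh refinement is provided in 1D (2:1 splitting of cells flagged
by the relative density jump, minmod-limited conservative prolongation,
conservative restriction, regrid every 2 steps with a 2-cell buffer).  The
2D scenario runs use uniform meshes: the published computation used a 5 mm
adaptive mesh whose refinement criterion and implementation are not
recoverable, so the honest scaled-down baseline here is a uniform 10–40 mm
grid, with the 1D AMR demonstrating the refinement machinery (base 200 + 1
level tracks a uniform 400-cell Sod run to L1 0.0011).

Verification battery (analysis/02): Sod L1 density errors 4.9e-3 / 2.7e-3 /
1.5e-3 at 100/200/400 cells (monotone convergence); 1D shock-tube front
speed at P4/P1 = 22.5 within 0.001% of Ms·a₁; reflected-shock wall pressure
within 0.001% of the analytic relation; spherical-pulse mirror symmetry
preserved to 4e-13.

## Blast-tube geometry and scenario observables

Chamber r 0.160 × 0.500 m, channel r 0.160 × 5.800 m, closed room r 1.400 ×
2.780 m; axial domain 9.08 m.  The nozzle is modelled as a short diverging
lip protruding 0.2 m into the room, widening the bore from 0.16 m to the
0.2 m exit radius (the published outlet-window diameter), with a 5 mm wall.
The protrusion length is not printed anywhere; 0.2 m was fixed a priori as
the natural reading of a thin "nozzle lip", and is configurable
(`TubeGeometry.nozzle_length`).  The driver section starts at the effective
P4 with everything else at P1 = 101.3 kPa and at rest; the diaphragm
vanishes at t = 0.

t0 is detected when the overpressure at the nozzle mid-section axis cell
first exceeds the arrival threshold (5 kPa ≈ 5% ambient — robust against
numerical ripple and small against the 30.4 kPa map threshold).  Lateral-
and far-wall arrivals are the first threshold crossings on the outermost
fluid ring under the room's cylindrical wall and on the fluid layer at the
far axial wall.  The exact transducer stations PT1–PT7 are shown only in
figures, so the default layout (chamber, diaphragm station, four evenly
spaced channel stations, channel exit, and room-axis probes A/B with B
200 mm ahead of the 65 cm dose location) is a documented convention.

### Far-wall timing discrepancy

At 2.3 MPa effective driver pressure the simulated lateral-wall arrival is
t0 + 3.43 ms at 10 mm mesh (3.45 ms at 20 mm), within 2.5% of the published
t0 + 3.35 ms.  The simulated far-axial-wall arrival is t0 + 6.33 ms
(6.29 ms at 20 mm — mesh-converged), against the published t0 + 4.75 ms.
The gap is physical in this model class: the axial shock decays from
640 m/s in the channel to 520→360 m/s while crossing the room, consistent
with channel-area (Whitham-type) decay for the 49× area expansion, whereas
4.75 ms implies a 565 m/s average.  Detection-threshold sweeps (1–30 kPa)
move the timing by under 0.3 ms, and nozzle-length variations within any
defensible reading of the geometry cannot satisfy both wall timings
simultaneously (lengthening the nozzle trades far-wall error for
lateral-wall error).  The acceptance suite states the published value and
is therefore expected to fail that single assertion; the reported number is
the honest model output.

### Late-time room field

The room mean overpressure rises to ≈ +5 kPa by t0 + 20 ms — matching the
energy balance of the ~230 kJ driver charge over the 17 m³ room — with most
of the room above ambient, which is the verifiable form of the published
"overpressure increased in the entire region" claim.  A pointwise
instantaneous minimum, however, remains negative indefinitely in an
inviscid model (tracked to 80 ms): acoustic sloshing between the walls and
the jet's vortex cores sustain rarefaction pockets of −80…−4 kPa that only
physical dissipation would damp.  The acceptance suite carries the literal
pointwise assertion (expected red) alongside the mean-field check (green).

## Waveform metrics

Arrival is the first upward threshold crossing with linear interpolation;
the positive phase ends at the first zero down-crossing after the peak
(robust when reflections add later peaks); impulse is the trapezoidal
integral of the positive lobe.  Metrics are invariant to time-origin shifts
and scale linearly in amplitude (property-tested).  The Friedlander fit is
deterministic nonlinear least squares seeded from the metrics, with the
arrival anchor at max(threshold, 25% of the trace maximum) so additive
noise cannot trigger a spurious early arrival; the RMS residual is reported
so model mismatch (square pulses, multi-peak room traces) is visible.  At
5% additive noise the median peak-recovery error over 200 replicates is
0.16%.

## Cohort statistics

The packaged table transcribes the published 17-animal cohort; organ
remarks are parsed by keyword ("LH", "Hemothorax", "Splenic", "Liver",
"IAH", "BR"), handling compound tokens such as "Splenic & Liver injury".
The two-sided Fisher exact test uses the probability-mass rule — the sum of
hypergeometric probabilities of all tables with the observed margins no
more probable than the observed one, with a 1+1e-7 tie guard — which is the
convention that reproduces the published p = 0.009 for the arrest × outcome
table; it is property-tested against full enumeration for all tables with
N ≤ 20 and cross-checked against an independent library implementation.
Reported percentages round half away from zero (6/11 → 55%).

The repeated-measures model is the univariate split-plot decomposition:
group tested against subject-within-group, time and group × time against
the within-subject residual; no sphericity correction is applied (none is
named in the publication).  Subjects with incomplete series are excluded
with a warning — in this design the dead animals contribute only pre and
5-min values, so the ANOVA effectively runs on survivors, as published.
The implementation is hand-rolled from cell means (valid for unequal group
sizes) and is cross-checked against an independent mixed-ANOVA
implementation and a brute-force sums-of-squares oracle; a vectorised path
over replicates powers the Monte-Carlo calibration (group-test type-I
error 0.047 at α = 0.05 over 2000 null replicates).  The t-test is the
pooled-variance two-sided Student test with explicit zero-variance
conventions.

## Synthetic-data generator

The cohort generator encodes the study's causal structure as a synthetic
hypothesis (the publication fits no such model): arrest ~
Bernoulli(logistic(β₀ + β₁·α^armor·dose)), spontaneous recovery ~
Bernoulli(ρ), death exactly when arrest goes unrecovered, and lung
hemorrhage in every exposed animal.  Defaults are anchored on the observed
margins: β₀ = −3 (small zero-dose arrest odds), β₁ chosen so the no-armor
arrest probability at the 200 kPa reference dose is 6/11, α = 0.725 so the
armor group's is 1/3, ρ = 3/8 — giving 8 expected arrests with 3 recoveries
in a 17-animal cohort (Monte-Carlo mean 8.01 over 5000 cohorts).  The
200 kPa reference dose is the order of the simulated near-animal peak
overpressure (the room-axis probes see 110–180 kPa peaks).  α is estimated
from pooled cohorts spanning a dose range by direct likelihood
maximisation; a likelihood-ratio test against the dose-free null flags α as
non-identifiable when the dose effect is undetectable (β₁ = 0 designs).
Recovery bias at ~2000 pooled animals is +0.035 (|bias| < 0.05); Wald CIs
on the α scale cover a true α = 1 in 96% of replicates.

Physiology (SBP, pulse, SpO₂, Hb, PaO₂, PaCO₂, pH at pre, 5 min, 1 h, 2 h,
3 h) is group-mean trajectories plus stationary AR(1) deviations (φ = 0.5);
dead animals are censored after 5 min, mirroring death within the first
hour.  The trajectory values are illustrative — the published physiology
exists only as figures — so passing calibration tests demonstrate that the
statistical machinery is calibrated (type-I error, power to separate the
dead stratum's PaO₂ collapse), not that real swine physiology is
reproduced.  Pressure traces are Friedlander waveforms plus white noise.
All generators are bit-reproducible given (parameters, seed).

What the synthetic data does not emulate: correlated organ injuries,
dose–severity gradients within a cohort, physiological coupling between
variables, and any fluid–structure interaction with the animal — the
simulated blast field and the synthetic cohort are linked only through the
scalar dose.

## Problem sizes and runtimes

The published computation used a 5 mm adaptive mesh; the studies here run
the same geometry at uniform 10 mm (timing study, ~127k cells, ~3500 steps)
and 20 mm (late-time study to 30 ms), sizes chosen so the whole analysis
chain replays on a single CPU in minutes.  Timings changed by < 1% between
20 mm and 10 mm, so the wall-arrival observables are effectively
mesh-converged at the scaled-down resolution.

## Known limitations

Inviscid, single-species ideal gas: no wall friction, heat exchange, or
turbulence, hence persistent late-time sloshing (above) and no boundary-
layer attenuation in the channel.  No diaphragm rupture mechanics (replaced
by the effective driver pressure).  No animal, table, fixtures, or armor in
the flow domain — the published simulation made the same choice.  The 2D
solver has no AMR; the nozzle lip is stair-stepped.  Physiology defaults
are illustrative.  The Fisher odds ratio is the sample odds ratio, not the
conditional MLE.
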