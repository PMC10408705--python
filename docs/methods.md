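# Methods

`squeezefilm` models the wet-adhesion mechanics of a climbing fish's
suction cup at three scales — the micro-setae squeeze film, the
plate-over-micro-column pressure field, and the whole-body suction
chamber — together with the measurement-side analysis used to quantify
them.  This note records the models, their assumptions, the parameters
that matter, and the choices made where the design was open.

## Squeeze-film (Stefan) forces

Two nearly parallel surfaces separated by a thin layer of an
incompressible Newtonian liquid resist normal motion because the film
must be drained or refilled through its edge.  In the lubrication limit
(film thickness ≪ lateral extent, negligible inertia, no slip) the
pressure field obeys the Reynolds equation, and for a rigid disc of
radius R at gap h moving at ḣ the resultant is the Stefan force

    F = 3π μ R⁴ ḣ / (2 h³),

linear in viscosity and speed, quartic in radius, inverse-cubic in gap.
The 1-D strip analogue is F = μ · depth · width³ · ḣ / h³.  Both closed
forms are verified in the tests against direct quadrature of the
lubrication pressure profile (< 1e-6 relative).

Sign convention: ḣ > 0 is separation, and the returned force is
positive when it resists the imposed motion, so "adhesion" is the film
force measured during separation.  Molecular attraction (van der Waals,
electrostatic, capillary) is deliberately absent: the measured approach
curves show no jump-in, so the film force is the only interfacial force
modelled.

**Cooperative effective-disc model.**  A patch of micro-setae (pillars
of radius a ≈ 2 µm, height ≈ 13 µm, areal density ≈ 9.5 × 10³ mm⁻²)
is modelled in two limits.  *Independent*: each seta is an isolated
disc and the patch force is N times the single-seta force — for a
handful of setae this is a few nN, below AFM detectability, matching
the observation that 4–5 contacting setae produce no measurable
adhesion.  *Cooperative*: a dense array whose inter-seta gaps are
sealed behaves hydrodynamically as one disc of the patch footprint,
R_eff = √(A/π), attenuated by a leakage factor `sealing_fraction`
S ∈ [0, 1].  Because of the R⁴ scaling, the cooperative force exceeds
the independent sum by S · R_eff⁴/(N a⁴) — three orders of magnitude
for realistic patches — which is the hydrodynamic origin of the
array's adhesion.  S is this package's one free leakage parameter; it
is not experimentally measurable here and defaults to 0.5 (half-sealed
rim).  Seta inclination is carried on the patch but does not enter the
effective-disc force; it only projects footprints in the field solver.

## Cantilever-coupled separation dynamics

The AFM experiment ramps a tip-less lever (spring constant
k = 0.24 N/m) toward and away from a setae patch at v = 4 µm/s between
nominal gaps of 1000 nm and 1 nm.  At µm/s ramp speeds the lever is far
below resonance, so a quasi-static massless balance holds:

    k (Z(t) − h) = C(h) ḣ,      C(h) = S · 3π μ R_eff⁴ / (2 h³),

a single stiff first-order ODE for the true gap h driven by the
triangular ramp Z(t).  It is integrated with an adaptive embedded
Runge–Kutta 4(5) pair (scipy's RK45), with an event clamping h at the
1 nm approach limit.  Default tolerances rtol = 1e-8, atol = 1e-18 m;
the atol sits far below rtol·h because the state is a gap of 1e-9 to
1e-6 m, and the tests verify both tolerance-halving convergence and
agreement (< 1e-3 on the peak) with a fixed-step classical RK4 run at
1e-5 of the ramp duration.

The measured force is the spring deflection k(h − Z): repulsive on
approach (h lags above Z), adhesive on retract (the film holds h back).
The default contact patch under the lever is not printed anywhere and
is the model's calibration surface: a 40 µm × 40 µm patch with S = 0.5.
With it, the simulated peak retract adhesion is ≈ 64 nN at 4 µm/s —
the same order of magnitude as the measured 112.83 ± 6.23 nN, which is
the level of agreement the underlying one-degree-of-freedom reduction
supports.  Peak adhesion grows strictly but sub-proportionally with
ramp speed (peak(8v)/peak(v) ≈ 1.7, not 8): the film sets both how
closely h tracks the ramp and how fast it releases.

## Plate / micro-column pressure field

The reference scene is four columns (diameter 5 µm, height 12 µm,
inclined 45°, edge spacing 5 µm) under a 90 µm plate separating at
10 µm/s in water.  The gap map g(x) puts `residual_film + lift` over
each projected footprint (length D/sin θ ≈ 7.07 µm; the projected
array is centred under the plate, since the lateral registration is
arbitrary) and adds the column height in the channels.  The steady 1-D
Reynolds equation

    d/dx ( g³ dp/dx ) = 12 μ ġ,     p = 0 at both plate ends,

is discretised by finite volumes with harmonic-mean g³ face
conductances — conservative across the sharp footprint/channel jumps —
and solved as one tridiagonal system (default 4001 nodes; the
discrete-balance residual is at machine precision and 2× refinement
moves the minimum pressure by < 0.2%).

Both bodies are rigid.  The reference computation for this scene is an
elastic fluid–structure simulation, so only order-of-magnitude
agreement is targeted.  `residual_film`, the plate-to-column-top film
at the "just separating" state, is not an observable of the rigid
reduction and is its declared calibration knob: it is set once, to
218 nm, so that the just-separating minimum pressure reproduces the
reference −1.63 kPa; it is configurable, and p_min scales roughly as
residual_film⁻³.  At 5 µm lift the footprint gaps no longer dominate
and the solver gives p_min ≈ −0.14 Pa essentially independent of the
knob — same order as the reference −0.2 Pa — a suction collapse of
four orders of magnitude, which is the mechanism that lets the animal
release cheaply while remaining attached.

## Suction-cup mechanics

The chamber filled with (nearly incompressible) water balances an
external pull-off force quasi-statically: ΔP = F/A while
ΔP ≤ seal_limit, beyond which the rim leaks and the state is returned
unsealed.  Defaults: cup area 203.2 mm² (the resting FTIR contact
area; whether the area under pull-off is identical is an open caveat)
and seal limit 58.07 kPa, giving a suction capacity of ≈ 11.8 N.
Membrane compliance only does volume bookkeeping.  The rim setae's
Stefan force is reported separately via the hydrodynamics module and
deliberately not added to the pull-off capacity: the setae act as the
seal, the negative pressure carries the load.

Friction under imposed pull-off load is summarised by an affine
Amontons-style law fitted by ordinary least squares; on the measured
triplet (0.5, 1, 2 N → 81, 92, 223 mN) this gives slope ≈ 0.100 and
baseline ≈ 15.5 mN, so friction at zero preload (< 20 mN) is three
orders of magnitude below the suction capacity — the low-friction /
high-adhesion balance stated as a testable inequality.

## Measurement analysis

* **Force-curve features.**  Baseline = mean force over the far 20% of
  the retract separation range (widened away from the dip with a
  warning if they overlap); adhesion force = dip depth below baseline;
  adhesion distance = span from the force minimum to the first return
  within `noise_threshold` (default 3) baseline SDs; adhesion work =
  area between force and baseline over that span.  Dips below the
  noise threshold are reported as non-events with zero features.  No
  extraction recipe is printed in the source experiments; this one is
  the package's own, chosen so the invariants (offset invariance,
  work ≤ force × distance) hold exactly.
* **Contact area.**  Pixels at or above a threshold (fixed counts or
  Otsu, the default, since the experiments report counts but no
  segmentation rule) times pixel area; peak intensity is the frame
  maximum.
* **Pressure statistics.**  Per-cycle peaks are local maxima separated
  by at least a minimum period (default 0.5 s); the summary is their
  pooled mean ± sample SD (SD absent for a single peak).
* **Group comparison.**  Mann–Whitney–Wilcoxon, exact when both
  n ≤ 12 with no ties (two-sided p by doubling the smaller exact tail,
  capped at 1), normal approximation with tie correction otherwise;
  the exact path is validated against exhaustive permutation
  enumeration for n ≤ 8.

## Synthetic generators

The generators emulate the *shape and summary statistics* of the
measured signals, not the instruments: a raised-cosine adhesive dip
(continuous first derivative, closed-form features: work =
force × distance / 2) with Gaussian force noise; elliptical contact
blobs with a narrow cosine rim centred on the programmed boundary, so
a midway threshold recovers the programmed area exactly, with optional
Poisson count noise; and sin²-bump pressure cycles whose per-cycle
peaks are Normal(mean, SD) floored at zero.  Curve presets carry the
reported adhesion values (setae 174.5 nN over 4.6 µm; flat base
122.2 nN over ~1 µm), frame presets the reported areas and peak counts
(203.20/182.33 mm², 980/1100 counts), and trace presets the three
state pressures.  Everything is a pure function of (spec, seed).

Passing round-trip tests on these signals demonstrates that the
analysis recovers programmed quantities under the stated noise models;
it does not demonstrate robustness to instrument drift, hydrodynamic
disturbance of the baseline, or non-Gaussian detector artefacts, none
of which are generated.

## Numerical choices and problem sizes

Default sizes keep every computation interactive on one CPU: 2000
samples per ODE phase, 4001 field nodes, 1200-sample synthetic curves,
220 × 220 frames.  Degenerate inputs fail loudly: non-positive gaps,
overlapping projected footprints, flat pressure traces, fewer than two
distinct friction loads.  Ties in the rank test fall back to the
approximate method; identical constant groups return p = 1 with a
warning.

## Known limitations

Rigid columns and plate (no elastic fluid–structure coupling); 1-D
reduction of the field scene with ambient-pressure ends as the declared
boundary condition; no slip, cavitation, or non-Newtonian rheology; the
quasi-static lever ignores torsion, inertia and thermal noise; the
effective-patch size and sealing fraction are calibration parameters,
not measurements; cup membrane compliance does not feed back on the
force balance.
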