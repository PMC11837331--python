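# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, in the spirit of a methods appendix: what is assumed,
what is configurable, and what the synthetic tests do and do not show
about real measurements.

## Wing system and kinematics

The wing is two rigid panels per side: an armwing (shoulder–wrist, length
0.1 m) and a handwing (wrist–tip, length `b = 0.1 m`), both of chord
`c = 0.2 m`.  Only the handwing carries membrane, so the reference area is
`S = 2bc = 0.04 m²`.  The armwing flaps through `φ(t)` measured from the
horizontal stroke plane; the handwing folds ventrally through `θ(t)`
relative to the armwing, giving it the absolute dihedral `ψ = φ − θ`.
Phase origin is the dorsal extreme of the stroke, so the downstroke is the
first half-cycle.

Commanded motions: the flap is a sinusoid of half-amplitude `Φ` (a
four-bar crank-rocker solver is provided for linkage-fidelity studies —
closed-form loop closure, Grashof-checked, extrema at the toggle angles);
the fold is zero until `t/T = 1/3` and then a single raised-cosine
fold-and-return pulse peaking at `θ₀` at `t/T = 2/3`, C¹ at onset and at
the cycle boundary.  The raised cosine is the simplest "sinusoidal"
waveform satisfying both endpoint conditions.

Realized motion differs from the command in two documented ways, emulated
by the generator: the fold lags by ≈0.1 cycle, and in the no-fold
condition the handwing oscillates passively within [−20°, +5°] (it is not
rigidly held).  The flap tracks its command closely and is passed through
unchanged.

`Φ` defaults to 44° so that the no-fold peak-to-peak tip excursion
`A = 2(L_a + b) sin Φ ≈ 0.278 m` gives `St = fA/U ≈ 0.21` at the baseline
condition `f = 3 Hz`, `U = 4 m s⁻¹`.  All time derivatives of sampled
series use a Savitzky–Golay filter of order 2 and frame length 5, with
periodic wrap when the series covers whole cycles; the order-2 filter
differentiates quadratics exactly and, at 83 bins per cycle,
underestimates the derivative amplitude of a pulse 0.3 cycles wide by
≈3–4% (the dominant numerical error in the clap-peak estimate).

## Quasi-steady blade-element model

Each element is treated at each instant as a steadily translating flat
plate at its instantaneous `U_eff = √(U² + w²)` and
`α_eff = atan2(−w, U)`, where `w = dz/dt` is the element's vertical
velocity (armwing `z = r sin φ`; handwing
`z = L_a sin φ + (r − L_a) sin ψ`).  Coefficient laws are the
translational flat-plate forms

    C_L(α) = A_L sin 2α,     C_D(α) = C_D0 + A_D (1 − cos 2α)

with defaults `A_L = 1.7`, `C_D0 = 0.05`, `A_D = 1.7` — standard
revolving/translating-plate values at these Reynolds numbers, exposed as
configuration constants rather than fitted quantities.

Element lift acts perpendicular to the relative wind in the section
plane, drag parallel to it; the section normal force is
`(dL·U − dD·w)/U_eff` per element.  Its lab-frame vertical component is
multiplied by `cos(panel dihedral)` (`cos φ` armwing, `cos ψ` handwing).
This projection is what makes folding profitable in the model: a strongly
folded handwing presents a reduced effective lifting area during the
upstroke, so the negative upstroke lift shrinks faster than the positive
downstroke lift, and the cycle-averaged `CL` rises monotonically with
`θ₀` (0 → 0.26 over θ₀ = 0–100° at St = 0.21).  Without the projection
the unfold late in the upstroke dominates and the trend inverts.

Power is the rate of work the wing does on the air through its
stroke-normal motion, `P = Σ(−dF_section · w)`, i.e. motor-side
mechanical power — the quantity a drivetrain measurement with mechanism
inertia removed reports.  It deliberately excludes the freestream's work
against drag (supplied by the tunnel, not the wing actuator), is kept
signed (air may briefly drive the wing), and excludes wing-structure
inertia (the handwing is ≈9 g; its inertial power is negligible).
Added-mass, rotational-circulation and leading-edge-vortex effects are
outside the model, and there is **no wing–wing interaction**: the model is
invariant to wingtip separation and therefore cannot produce clap lift.
That gap is the reason for the control-volume analysis.

## Control-volume jet analysis

A rectangle in the vertical mid-plane between the wingtips budgets the
upward reaction force on the wings, per unit depth, as

    L = −ρ d/dt ∫∫_CV w dA  −  ∮_CS ρ w (v·n̂) dl  +  ∫ (p_b − p_t) dx

(acceleration/storage, momentum flux with outward normals, vertical
pressure force).  The sign convention makes each term the named
contribution to lift: a downward jet gives positive `L`, and the budget
vanishes identically for body-free inviscid flow.  `total` is by
construction the exact sum of the three stored terms.

Gauge pressure on the top and bottom faces is recovered from the velocity
field by integrating the inviscid streamwise momentum equation,
`∂p/∂x = −ρ(∂u/∂t + u ∂u/∂x + w ∂u/∂z)`, from the upstream corner of each
face, where the flow is assumed undisturbed (`p = p∞`).  An unsteady
Bernoulli closure (with `∂φ/∂t ≈ ∫ ∂u/∂t dx`) is provided as a
cross-check; the two agree to within 5% of the budget scale on the
synthetic jet and exactly on steady potential flow.  Viscous stresses on
the control surface are neglected.  Out-of-plane gradients are
unavailable from planar data; the jet is assumed uniform over a spanwise
width of `2b`, which reduces the lift coefficient to `C_L = L/(q c)`.

Numerics: trapezoidal quadrature on edges and areas (smooth fields,
regular grids); phase derivatives Savitzky–Golay order 2, frame 5, with
periodic wrap; spatial derivatives the same filter without wrap.  A
turbulent-flux diagnostic `∮ ρ ⟨w′v′⟩·n̂ dl` is computed from the per-bin
variance fields and reported alongside the budget but never added to it.
The clap peak is the maximum of `C_L` within a phase window, default
[0.7, 0.9].

## Signal processing

Force traces (1000 Hz) and motor power (512 Hz) are low-passed with a
zero-phase 4th-order Butterworth at `f_c = 5f` (15 Hz at 3 Hz wingbeat;
order unspecified upstream, 4 chosen as common practice that preserves
the fundamental's phase).  The wings-off (inertia-only) trial is
phase-aligned to the wings-on trial and subtracted.  Alignment uses the
recorded trigger phase when present (the hardware-synchronized protocol);
the cross-correlation fallback is unbiased only when the two trials share
their waveform up to a shift — a strong aerodynamic component pulls the
correlation peak off the true lag, which is why the trigger metadata
exists.  Power is resampled to the force clock by linear interpolation
before normalization.  Phase averaging uses the same binning rule as the
velocity fields (bin `⌊τ n⌋`, bin-centre phases reported) and reports the
per-bin standard deviation as the spread band.  `θ₀` enters
`St_clap = f θ₀ b / U` in radians — `f θ₀ b` is the wingtip closing
speed, which requires a radian angle.  The clap-scaling summary reports a
least-squares slope and Spearman rank correlation; it asserts nothing.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (spec, seed); identical inputs give
bitwise-identical outputs.  Defaults mirror the study protocol: 3 Hz
wingbeat, 4 m s⁻¹ freestream, 40 cycles, 1000/512/500 Hz channels, 83
phase bins.

* Force traces = mechanism inertia (harmonics at `f` and `2f`, defaults
  2.0 and 0.8 N — larger than the aerodynamic signal, as in a geared
  flapper) + denormalized quasi-steady truth + homoscedastic Gaussian
  noise; wings-off trials carry the same inertia at a known trigger
  offset (0.03 cycles) plus independent noise.
* The clap jet is a Gaussian spatial core (radius 0.04 m) whose vertical
  speed follows a raised-cosine pulse (peak 4 m s⁻¹ downward, active over
  t/T ∈ [0.65, 0.95] — the interval in which the lagged fold holds the
  wingtips near the midline), preceded by a weaker upward "scooping" lobe
  (ratio 0.3, t/T ∈ [0.5, 0.7]) that reproduces the negative lift trough
  before the clap peak.  The generator's force budget is evaluated in
  closed form (error-function integrals, exact pulse derivatives),
  independent of the gridded analysis path, and serves as ground truth.

The generator does not emulate: jet advection and asymmetry, turbulence
spectra, correlated transducer noise, servo torque ripple, or any
wing–wing interaction physics — the jet is *prescribed*, not produced by
a clap.  Passing tests therefore demonstrate that the analysis chain
recovers forces faithfully from fields and traces with this structure,
not that the physical robot produces them.  Quantitative reproduction of
the measured robot forces is explicitly out of scope.

## Problem sizes and tolerances

Tests and the demo run the chain at the study's native sizes where cheap
(83 bins × 40 cycles of 500 Hz fields; 121 × 81 velocity grid at 5 mm
spacing; 400 samples/cycle for quasi-steady sweeps) and at reduced cycle
counts for unit tests.  Key verified tolerances: budget identity exact;
uniform-freestream `CL` ≡ 0 to machine precision; clap-peak recovery
within 5% of the analytic budget (dominated by the Savitzky–Golay phase
derivative bias); control-volume independence within 5% across nested
rectangles with ≥3 core-radii margins; Galilean shifts of `u` move the
peak by <2%; no-fold cycle-averaged `CL` below 1e-10; full-chain recovery
of cycle-averaged `CL` within 5% at SNR 10.

## Known limitations

* The coefficient-law constants are defaults of the standard flat-plate
  form, not values fitted to this wing.
* The pressure recovery assumes the upstream corners of the control
  volume sit in undisturbed flow; place the rectangle accordingly.
* Fractional-sample trigger offsets are aligned to the nearest sample
  (1/333 cycle at 1000 Hz and 3 Hz).
* The four-bar link lengths of the physical mechanism are unpublished;
  the sinusoid is the default flap waveform and the four-bar solver takes
  arbitrary Grashof crank-rocker geometry.
* The spanwise-uniform-jet assumption (width `2b`) is inherited from the
  planar measurement; the true jet width is unknown.
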