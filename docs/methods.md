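# Methods

## Physical model

A straight, constant-calibre vessel (inner diameter D₀ = 8 mm, outer
D₁ = 10 mm, wall thickness h = 1 mm) is divided into an inlet extension of
30 mm and three segments of 50 mm each (total length 180 mm). The wall is
linear elastic and isotropic with Poisson ratio ν = 0.499 (nearly
incompressible); the middle segment has Young's modulus E = 5 MPa, the end
segments 200 MPa, a 40× compliance mismatch of the kind produced when a
stiff graft is interposed in a compliant artery. The extension's stiffness
is not part of the reference description; it is assigned the stiff
end-segment material so that everything upstream of the compliant section
is homogeneous. Blood is incompressible and Newtonian, ρ = 1050 kg/m³,
μ = 3.5 mPa·s. Output probes sit at 70, 100 and 140 mm from the inlet, the
mid-points of the three segments.

With period T = 1 s this gives Womersley number
α = (D₀/2)√(2πρ/(Tμ)) = 5.49 (≈ 5.5) and a Reynolds envelope of 190–500
for the default waveform.

## Synthetic inlet waveform

Published carotid flow waveforms are plots, not tables, so the inlet
condition is an explicit closed-form family: a diastolic plateau plus a
single raised-cosine (Hann) systolic pulse, truncated to
`harmonics_retained` Fourier modes (default 12) so it is smooth and
band-limited. Defaults: period 1 s, peak at 0.15 T, pulse full width
0.25 T. The plateau and peak velocities are *derived at construction time*
from the target Reynolds envelope (Re = 190 diastole, 500 peak systole)
through V = Re·μ/(ρD₀), so overriding the fluid keeps the dimensionless
operating point; with the default fluid this gives 0.079 and 0.208 m/s.
Truncation clips the extremes of the raised cosine slightly, so the
band-limited series is affinely renormalised (against an internal fine
grid, making the result independent of the requested sampling) to span
exactly [diastolic, peak]. The generator is deterministic; an optional
noise overlay requires an explicit seed.

What this stand-in does *not* emulate: the dicrotic notch, secondary
systolic peaks, and any beat-to-beat variability of measured carotid
velocity. Tests that pass with it therefore validate the mechanics and
numerics under a realistic amplitude/frequency envelope, not agreement
with any particular measured waveform; a digitised measurement can be
substituted through the two-column CSV interface
(`time_s,mean_velocity_m_per_s`).

## Analytic rigid-tube solution

Each Fourier mode of the mean velocity drives the classical axisymmetric
oscillatory pipe-flow solution (J₀/J₁ Bessel form with argument
λ = i^{3/2}α_k, α_k = α√k), normalised so the mode's cross-sectional
average equals its harmonic coefficient; the steady mode carries the
Poiseuille parabola. Wall shear stress is evaluated from the analytic
radial derivative at the wall (positive for forward flow), and the driving
pressure gradient per mode is recovered from the momentum balance. The
solution is flow-driven, not pressure-driven, because the model prescribes
an inlet velocity. For α_k < 10⁻³ the Bessel expressions are replaced by
their exact quasi-steady (parabolic) limit to avoid cancellation. Reverse
flow is handled upstream by |V| when a Reynolds number is requested.

## 1D pulse-wave solver

The central modelling decision of the package: the 3D fluid–structure
problem is reduced to the standard 1D area-averaged system, because the
phenomenon of interest — reflection and strain concentration at stiffness
junctions — is governed by axial wave mechanics:

- mass: ∂A/∂t + ∂Q/∂x = 0
- momentum: ∂Q/∂t + ∂(Q²/A)/∂x + (A/ρ)∂p/∂x = −8πν·Q/A
- tube law: p = p_ext + β(√A − √A₀), β = √π·h·E/((1−ν²)A₀)

The (1−ν²) plane-strain factor matches a long, axially constrained tube;
a flat momentum-correction factor and laminar Poiseuille friction close
the momentum equation. Characteristic speed c = √(β√A/2ρ); at A₀ this is
the plane-strain Moens–Korteweg speed √(hE/(2ρR₀(1−ν²))) — 28.2 m/s for
the compliant segment, 178.1 m/s (√40×) for the stiff ones.

**Discretisation.** Two-step MacCormack (forward predictor / backward
corrector, second order) on a uniform cell-centred grid, default
dx = 0.5 mm (360 cells), with the interior time step set by
CFL ≤ 0.8 against the stiff-segment wave speed (dt ≈ 2.2 µs) and chosen to
subdivide the 10 ms output cadence exactly. The mass equation is advanced
in flux form, so the volume balance against the recorded discrete boundary
fluxes telescopes to machine rounding (the audit is reported per run and
asserted ≤ 10⁻⁸ relative; observed ~10⁻¹⁶). The pressure-gradient term is
differenced non-conservatively from the nodal tube-law pressure: since a
rest state has p ≡ 0 regardless of how β(x) jumps, rest is preserved
*exactly* across the 40× stiffness junctions (verified bit-for-bit),
which is the well-balancing property that matters here; no artificial
viscosity is added. An optional `junction_ramp` linearly blends β over a
set axial distance (default 0 = sharp one-cell transition; the measured
reflection coefficient is insensitive to ramps much shorter than the
pulse length).

**Boundaries.** Written in the Riemann invariants W± = u ± 4c of the
tube-law system, applied through ghost cells. The inlet prescribes the
waveform velocity against the outgoing invariant extrapolated from the
first interior cell (so Q_in = A_in·V(t) with A_in consistent with the
outgoing characteristic); the outlet holds the incoming invariant at its
rest value −4c₀ — a non-reflecting termination, the 1D reading of a
zero-normal-traction outflow. Ghost areas are reconstructed from the wave
speed as a *ratio* against the adjacent interior cell
(A_g = A_ref·(c_g/c_ref)⁴) rather than by invert-and-square, which makes
the rest state an exact fixed point in floating-point arithmetic. Initial
conditions are zero everywhere (A = A₀, Q = 0, zero gauge pressure);
three cycles are run and the final cycle reported, with the cycle-to-cycle
maximum relative pressure change per probe recorded (default tolerance
10⁻⁴; non-convergence is flagged in the diagnostics, not fatal).

A consequence of the matched outlet worth stating: a non-reflecting
boundary terminates the vessel like an infinite matched tube, so the
outlet pressure is Z·Q (Z = ρc₀/A₀ ≈ 3.7·10⁹ Pa·s/m³ for the stiff
calibre), and probe pressures carry a mean component of order 15–40 kPa.
A 3D zero-traction outlet instead pins the outlet pressure near zero, so
absolute pressure/stress/strain magnitudes are not comparable between the
two formulations — only waveform shapes, probe-to-probe differences and
orderings are, and those are what the package reports and tests. The
compliant probe's cycle-max kinematic strain exceeds the stiff probes' by
roughly the 40× modulus ratio, the expected ordering.

**Wall shear stress closure.** Default "poiseuille":
τ_w = 4μQ/(πR³) from the instantaneous local flow and radius — simple and
local, but quasi-steady: at α ≈ 5.5 it misses the oscillatory boundary
layer and deviates ~50% from the analytic WSS at the higher harmonics.
The "womersley" option decomposes the simulated local mean velocity into
harmonics and applies the per-mode analytic wall-shear transfer function;
this is the closure used when comparing the near-rigid limit against the
analytic oracle (agreement within 5%; observed <1%).

## Wall mechanics

Hoop stress uses the full Lamé thick-cylinder solution (the wall has
h/a = 0.25, far from thin); the wall-shear traction (~1 Pa) is neglected
against pressure loads (~10³–10⁴ Pa), external (perivascular) pressure
defaults to zero, and the axial state defaults to plane strain with a
documented `sigma_z` override. Strain comes kinematically from the
simulated distension, ε_θ = (√A−√A₀)/√A₀, which inherits the segment-wise
modulus through the tube law — this is the route used for probe
comparisons — or constitutively from Hooke's law. The two routes are both
linearisations of a thin-wall tube and agree within ~7% at h/R₀ = 0.05;
at the reference h/R₀ = 0.25 they differ by ~40% (thick-wall Lamé factor
and σ_r terms), so cross-route comparisons are made in the thin-wall
regime only.

## Reporting choices

Extrema are taken over the final cycle; ordering flags use absolute
extrema; exact ties report "tie". Waveform similarity is the normalised
zero-lag cross-correlation after mean removal, clamped to [0, 1] (two
constants: 1; constant vs varying: 0). The 0.95 pressure-similarity
threshold is this package's operationalisation of "the probe pressures
look alike" and is a soft check (warning in the pipeline report, not a
failure). The pipeline is deterministic: identical configs produce
bit-identical outputs.

## Problem sizes and numerical tolerances

Default production run: 3 cycles × 1 s, 360 cells, dt ≈ 2.24 µs
(~1.3·10⁶ steps), ~10 s with the compiled kernel. Validation cases use a
uniform 800-cell/0.4 m tube for pulse-propagation and reflection
measurements (1% area pulses for wave speed; 0.1% for reflection, where
linear theory applies), a 2-cycle steady-inflow run for the Poiseuille
oracle, and a dx = 1 mm run for the grid-refinement comparison. Observed
margins: pulse speed within 0.2% of c(A₀) (tolerance 2%), measured
junction reflection within 2% of (Z₂−Z₁)/(Z₁+Z₂) (tolerance 5%), steady
pressure drop within 0.2% of Poiseuille (tolerance 5%), halving dx/dt
changes probe pressures <0.1% (tolerance 1%), final-cycle periodicity
~10⁻¹² (tolerance 1%).

## Known limitations

- No wall inertia, viscoelasticity, longitudinal tethering or
  axial-displacement mechanics; no buckling, hence no non-axisymmetric
  velocity profiles. Effects that originate in 3D distension (e.g. which
  segment sees the highest WSS) are reported but cannot be claimed by a
  1D model.
- Laminar Newtonian flow with a flat momentum profile; no turbulence,
  non-Newtonian rheology or anisotropic/nonlinear wall behaviour.
- Absolute pressure/stress/strain levels depend on the outlet impedance
  (see above); orderings and waveform shapes are the meaningful outputs.
- The junction is a material discontinuity only; suture-line geometry and
  mechanics are outside the model.
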