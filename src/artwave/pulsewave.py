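"""1D area-averaged fluid-structure pulse-wave solver.

The three-dimensional mechanics of a compliant artery is reduced to the
standard one-dimensional system for cross-sectional area A(x, t) and
volumetric flow Q(x, t),

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dp/dx = -8 pi nu Q / A,

closed by the thin-wall elastic tube law

    p(A) = p_ext + beta (sqrt(A) - sqrt(A0)),
    beta = sqrt(pi) h E / ((1 - nu_w^2) A0),

whose stiffness coefficient carries the segment-wise Young's modulus.  The
characteristic wave speed is c^2 = beta sqrt(A) / (2 rho); at the reference
area this is the plane-strain Moens-Korteweg speed
sqrt(h E / (2 rho R0 (1 - nu_w^2))).

Discretisation: explicit two-step MacCormack (second order) on a uniform
cell-centred grid with one ghost cell per end.  The mass equation is
advanced in flux form, so the discrete volume balance against the recorded
boundary fluxes telescopes to machine precision.  The pressure-gradient term
is differenced non-conservatively from the nodal tube-law pressure, which
preserves rest states exactly across stiffness jumps.  Boundary conditions
enter through the Riemann invariants W+- = u +- 4c of the tube-law system:
the inlet prescribes the mean velocity (hence Q = A V) against the outgoing
invariant, and the outlet is non-reflecting (the incoming invariant is held
at its rest value), the 1D counterpart of a zero-normal-traction outflow.

The inner loop is compiled with numba when available and falls back to the
same pure-Python code otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    FluidProperties,
    SegmentedVessel,
    VesselGeometry,
    WallMaterial,
    default_fluid,
)
from .waveform import (
    MeanVelocitySeries,
    decompose,
    default_waveform_params,
    generate_waveform,
)

__all__ = [
    "TubeLaw",
    "tube_law_for",
    "wave_speed",
    "characteristic_impedance",
    "junction_reflection",
    "PulseWaveState",
    "SolverSettings",
    "SolverError",
    "step",
    "advance",
    "simulate",
    "PulseWaveModel",
    "SimulationResult",
]


class SolverError(RuntimeError):
    """Raised when the explicit scheme leaves its stability envelope."""


@dataclass(frozen=True)
class TubeLaw:
    """Pressure-area closure p = p_ext + beta (sqrt(A) - sqrt(A0))."""

    reference_area: float
    stiffness_coefficient: float  # beta, Pa/m
    external_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_area <= 0:
            raise ValueError("reference_area must be > 0")
        if self.stiffness_coefficient < 0:
            raise ValueError("stiffness_coefficient must be >= 0")

    def pressure(self, area) -> np.ndarray:
        a = np.asarray(area, dtype=float)
        return self.external_pressure + self.stiffness_coefficient * (
            np.sqrt(a) - math.sqrt(self.reference_area)
        )


def tube_law_for(
    geometry: VesselGeometry,
    material: WallMaterial,
    external_pressure: float = 0.0,
) -> TubeLaw:
    """Thin-wall elastic tube law for a segment's wall material.

    Uses the plane-strain factor (1 - nu^2), appropriate for a long
    axially-constrained tube.
    """
    A0 = geometry.lumen_area
    beta = (
        math.sqrt(math.pi)
        * geometry.wall_thickness
        * material.youngs_modulus
        / ((1.0 - material.poissons_ratio**2) * A0)
    )
    return TubeLaw(reference_area=A0, stiffness_coefficient=beta,
                   external_pressure=external_pressure)


def wave_speed(law: TubeLaw, area: float, fluid: FluidProperties) -> float:
    """Characteristic speed c = sqrt(beta sqrt(A) / (2 rho))."""
    if area <= 0:
        raise ValueError("area must be > 0")
    return math.sqrt(law.stiffness_coefficient * math.sqrt(area)
                     / (2.0 * fluid.density))


def characteristic_impedance(law: TubeLaw, fluid: FluidProperties) -> float:
    """Z = rho c0 / A0 at the reference area."""
    c0 = wave_speed(law, law.reference_area, fluid)
    return fluid.density * c0 / law.reference_area


def junction_reflection(
    law_upstream: TubeLaw, law_downstream: TubeLaw, fluid: FluidProperties
) -> float:
    """Linear pressure reflection coefficient at an area-matched junction.

    For a wave incident from the upstream tube (impedance Z1) onto the
    downstream tube (Z2), the reflected/incident pressure-amplitude ratio is
    (Z2 - Z1) / (Z1 + Z2): negative when a stiff tube feeds a more compliant
    one, as at the proximal junction of a stiff graft into a compliant
    artery.
    """
    z1 = characteristic_impedance(law_upstream, fluid)
    z2 = characteristic_impedance(law_downstream, fluid)
    return (z2 - z1) / (z1 + z2)


@dataclass(frozen=True)
class PulseWaveState:
    """Discrete (A, Q) state on a uniform cell-centred grid at one time."""

    x_grid: np.ndarray
    area: np.ndarray
    flow: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid, dtype=float)
        a = np.asarray(self.area, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        if not (x.shape == a.shape == q.shape) or x.ndim != 1:
            raise ValueError("x_grid, area, flow must be equal-length 1-D arrays")
        if np.any(a <= 0):
            raise ValueError("area must be positive everywhere")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(q))):
            raise ValueError("state fields must be finite")
        object.__setattr__(self, "x_grid", x)
        object.__setattr__(self, "area", a)
        object.__setattr__(self, "flow", q)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the pulse-wave solver.

    ``dx`` is the cell size (m); the interior time step is set from the CFL
    condition and subdivides ``output_dt``, the cadence (s) at which probe
    waveforms are recorded.  ``cycles`` periods are run from zero initial
    conditions and the final cycle is reported.  ``convergence_tolerance``
    is the cycle-to-cycle relative change of probe pressure below which the
    run is flagged converged.  ``wss_model`` selects the wall-shear closure:
    "poiseuille" (tau = 4 mu Q / (pi R^3) from the instantaneous local flow)
    or "womersley" (frequency-corrected from the local harmonic content).
    ``junction_ramp`` linearly blends the tube-law stiffness over that axial
    distance around each material junction (0 = sharp, one-cell transition).
    """

    dx: float = 5e-4
    output_dt: float = 0.01
    cycles: int = 3
    cfl_limit: float = 0.8
    convergence_tolerance: float = 1e-4
    wss_model: str = "poiseuille"
    wss_harmonics: int = 12
    junction_ramp: float = 0.0

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.output_dt <= 0:
            raise ValueError("dx and output_dt must be > 0")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0 < self.cfl_limit < 1:
            raise ValueError("cfl_limit must lie in (0, 1)")
        if self.wss_model not in ("poiseuille", "womersley"):
            raise ValueError("wss_model must be 'poiseuille' or 'womersley'")


# ---------------------------------------------------------------------------
# compiled inner loop
# ---------------------------------------------------------------------------

_INLET_PRESCRIBED = 0
_INLET_NONREFLECTING = 1


def _advance_impl(A, Q, beta, sqrt_a0, dx, dt, uin, inlet_mode, rho, nu):
    """Advance ``uin.size - 1`` MacCormack steps in place.

    ``A``, ``Q``, ``beta`` have one ghost cell per end (length N + 2).
    Returns ``(status, influx, outflux, cfl_max)`` where status is 0 on
    success, 1 on a CFL violation and 2 on a non-positive area; influx and
    outflux are the time-integrated discrete boundary volume fluxes, so
    ``dx * sum(dA_interior) == influx - outflux`` to roundoff.

    Ghost areas are reconstructed from the characteristic wave speed as a
    ratio against the adjacent interior cell, so the rest state (A = A0,
    Q = 0) is an exact fixed point of the scheme.
    """
    n_tot = A.size
    N = n_tot - 2
    nsub = uin.size - 1
    lam = dt / dx
    kp = dt / (rho * dx)
    fric = 8.0 * math.pi * nu
    fin = 0.0
    fout = 0.0
    cfl_max = 0.0
    As = np.empty(n_tot)
    Qs = np.empty(n_tot)
    p = np.empty(n_tot)
    adv = np.empty(n_tot)
    ps = np.empty(n_tot)
    advs = np.empty(n_tot)

    for j in range(nsub):
        # --- ghost cells at level n ---
        u1 = Q[1] / A[1]
        c1 = math.sqrt(beta[1] * math.sqrt(A[1]) / (2.0 * rho))
        c0_in = math.sqrt(beta[1] * sqrt_a0 / (2.0 * rho))
        wm = u1 - 4.0 * c1
        if inlet_mode == _INLET_PRESCRIBED:
            ug = uin[j]
            cg = (ug - wm) / 4.0
        else:
            ug = (4.0 * c0_in + wm) / 2.0
            cg = (4.0 * c0_in - wm) / 8.0
        r = (cg / c1) * (cg / c1)
        A[0] = A[1] * (r * r)
        Q[0] = A[0] * ug

        uN = Q[N] / A[N]
        cN = math.sqrt(beta[N] * math.sqrt(A[N]) / (2.0 * rho))
        c0_out = math.sqrt(beta[N] * sqrt_a0 / (2.0 * rho))
        wp = uN + 4.0 * cN
        ug2 = (wp - 4.0 * c0_out) / 2.0
        cg2 = (wp + 4.0 * c0_out) / 8.0
        r = (cg2 / cN) * (cg2 / cN)
        A[n_tot - 1] = A[N] * (r * r)
        Q[n_tot - 1] = A[n_tot - 1] * ug2

        # --- predictor (forward differences) ---
        cfl_loc = 0.0
        for i in range(n_tot):
            sa = math.sqrt(A[i])
            p[i] = beta[i] * (sa - sqrt_a0)
            adv[i] = Q[i] * Q[i] / A[i]
            if 1 <= i <= N:
                s = abs(Q[i] / A[i]) + math.sqrt(beta[i] * sa / (2.0 * rho))
                if s > cfl_loc:
                    cfl_loc = s
        cfl_loc = cfl_loc * lam
        if cfl_loc > cfl_max:
            cfl_max = cfl_loc
        if cfl_loc > 1.0:
            return 1, fin, fout, cfl_max

        for i in range(1, N + 1):
            As[i] = A[i] - lam * (Q[i + 1] - Q[i])
            Qs[i] = (Q[i] - lam * (adv[i + 1] - adv[i])
                     - kp * A[i] * (p[i + 1] - p[i])
                     - dt * fric * Q[i] / A[i])
            if As[i] <= 0.0:
                return 2, fin, fout, cfl_max

        # --- ghost cells for the predicted level ---
        u1 = Qs[1] / As[1]
        c1 = math.sqrt(beta[1] * math.sqrt(As[1]) / (2.0 * rho))
        c0_in = math.sqrt(beta[1] * sqrt_a0 / (2.0 * rho))
        wm = u1 - 4.0 * c1
        if inlet_mode == _INLET_PRESCRIBED:
            ug = uin[j + 1]
            cg = (ug - wm) / 4.0
        else:
            ug = (4.0 * c0_in + wm) / 2.0
            cg = (4.0 * c0_in - wm) / 8.0
        r = (cg / c1) * (cg / c1)
        As[0] = As[1] * (r * r)
        Qs[0] = As[0] * ug

        uN = Qs[N] / As[N]
        cN = math.sqrt(beta[N] * math.sqrt(As[N]) / (2.0 * rho))
        c0_out = math.sqrt(beta[N] * sqrt_a0 / (2.0 * rho))
        wp = uN + 4.0 * cN
        ug2 = (wp - 4.0 * c0_out) / 2.0
        cg2 = (wp + 4.0 * c0_out) / 8.0
        r = (cg2 / cN) * (cg2 / cN)
        As[n_tot - 1] = As[N] * (r * r)
        Qs[n_tot - 1] = As[n_tot - 1] * ug2

        # --- corrector (backward differences) ---
        for i in range(n_tot):
            sa = math.sqrt(As[i])
            ps[i] = beta[i] * (sa - sqrt_a0)
            advs[i] = Qs[i] * Qs[i] / As[i]

        fin += dt * 0.5 * (Q[1] + Qs[0])
        fout += dt * 0.5 * (Q[n_tot - 1] + Qs[N])

        for i in range(1, N + 1):
            a_new = 0.5 * (A[i] + As[i] - lam * (Qs[i] - Qs[i - 1]))
            q_new = 0.5 * (Q[i] + Qs[i]
                           - lam * (advs[i] - advs[i - 1])
                           - kp * As[i] * (ps[i] - ps[i - 1])
                           - dt * fric * Qs[i] / As[i])
            A[i] = a_new
            Q[i] = q_new
            if A[i] <= 0.0:
                return 2, fin, fout, cfl_max

    return 0, fin, fout, cfl_max


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _advance = njit(cache=True)(_advance_impl)
except ImportError:  # pragma: no cover
    _advance = _advance_impl


# ---------------------------------------------------------------------------
# driver-level helpers
# ---------------------------------------------------------------------------


def _laws_to_beta(laws, n: int):
    """Per-cell beta array (+ ghost padding) and reference area from laws."""
    if isinstance(laws, TubeLaw):
        laws = [laws] * n
    laws = list(laws)
    if len(laws) != n:
        raise ValueError(f"need one TubeLaw per cell ({n}), got {len(laws)}")
    a0 = laws[0].reference_area
    for law in laws:
        if abs(law.reference_area - a0) > 1e-12 * a0:
            raise ValueError("all tube laws must share the reference area")
    beta = np.empty(n + 2)
    beta[1:-1] = [law.stiffness_coefficient for law in laws]
    beta[0] = beta[1]
    beta[-1] = beta[-2]
    return beta, a0


def _run_kernel(state, beta, a0, fluid, dt, uin, inlet_mode):
    n = state.x_grid.size
    A = np.empty(n + 2)
    Q = np.empty(n + 2)
    A[1:-1] = state.area
    Q[1:-1] = state.flow
    A[0] = A[1]
    A[-1] = A[-2]
    Q[0] = Q[1]
    Q[-1] = Q[-2]
    dx = float(state.x_grid[1] - state.x_grid[0]) if n > 1 else 1.0
    status, fin, fout, cfl_max = _advance(
        A, Q, beta, math.sqrt(a0), dx, dt, uin, inlet_mode,
        fluid.density, fluid.kinematic_viscosity,
    )
    if status == 1:
        raise SolverError(
            f"CFL violation at t ~ {state.time:.6g} s: "
            f"max CFL {cfl_max:.3f} > 1; reduce dt or dx"
        )
    if status == 2:
        raise SolverError(
            f"non-positive cross-sectional area at t ~ {state.time:.6g} s; "
            "the scheme left its stability envelope"
        )
    new = PulseWaveState(
        x_grid=state.x_grid,
        area=A[1:-1].copy(),
        flow=Q[1:-1].copy(),
        time=state.time + dt * (uin.size - 1),
    )
    return new, {"influx": fin, "outflux": fout, "cfl_max": cfl_max}


def step(
    state: PulseWaveState,
    laws,
    fluid: FluidProperties,
    dt: float,
    inlet_velocity=None,
) -> PulseWaveState:
    """Advance a single MacCormack step.

    ``laws`` is a TubeLaw (uniform) or one per cell.  ``inlet_velocity`` is
    None for a non-reflecting inlet, a scalar held over the step, or a pair
    ``(u_now, u_next)``.  Raises :class:`SolverError` on CFL violation or
    non-positive area.
    """
    new, _ = advance(state, laws, fluid, dt, 1, inlet_velocity)
    return new


def advance(
    state: PulseWaveState,
    laws,
    fluid: FluidProperties,
    dt: float,
    n_steps: int,
    inlet_velocity=None,
):
    """Advance ``n_steps`` steps; returns ``(state, audit)``.

    ``audit`` carries the discrete boundary-flux integrals and the volume
    balance residual |dV - (influx - outflux)| relative to the initial
    volume.
    """
    if inlet_velocity is None:
        uin = np.zeros(n_steps + 1)
        mode = _INLET_NONREFLECTING
    else:
        arr = np.asarray(inlet_velocity, dtype=float)
        if arr.ndim == 0:
            uin = np.full(n_steps + 1, float(arr))
        else:
            if arr.size != n_steps + 1:
                raise ValueError("inlet_velocity array must have n_steps + 1 samples")
            uin = arr
        mode = _INLET_PRESCRIBED
    beta, a0 = _laws_to_beta(laws, state.x_grid.size)
    dx = float(state.x_grid[1] - state.x_grid[0])
    v_start = float(np.sum(state.area)) * dx
    new, info = _run_kernel(state, beta, a0, fluid, dt, uin, mode)
    v_end = float(np.sum(new.area)) * dx
    residual = abs((v_end - v_start) - (info["influx"] - info["outflux"]))
    audit = {
        "volume_start": v_start,
        "volume_end": v_end,
        "influx": info["influx"],
        "outflux": info["outflux"],
        "volume_residual_rel": residual / v_start,
        "cfl_max": info["cfl_max"],
    }
    return new, audit


# ---------------------------------------------------------------------------
# full simulation of the segmented vessel
# ---------------------------------------------------------------------------


def _stiffness_field(vessel: SegmentedVessel, settings: SolverSettings):
    """Cell-centred beta(x) (with ghosts) for the segmented vessel."""
    L = vessel.total_length
    n = max(int(round(L / settings.dx)), 4)
    dx = L / n
    x = (np.arange(n) + 0.5) * dx
    geo = vessel.geometry
    beta_cells = np.empty(n)
    for i, xi in enumerate(x):
        law = tube_law_for(geo, vessel.material_at(xi))
        beta_cells[i] = law.stiffness_coefficient
    ramp = settings.junction_ramp
    if ramp > 0:
        for xb in vessel.boundaries():
            lo, hi = xb - ramp / 2, xb + ramp / 2
            b_lo = tube_law_for(geo, vessel.material_at(max(lo, 0.0))
                                ).stiffness_coefficient
            b_hi = tube_law_for(geo, vessel.material_at(min(hi, L))
                                ).stiffness_coefficient
            sel = (x > lo) & (x < hi)
            beta_cells[sel] = b_lo + (b_hi - b_lo) * (x[sel] - lo) / ramp
    beta = np.empty(n + 2)
    beta[1:-1] = beta_cells
    beta[0] = beta[1]
    beta[-1] = beta[-2]
    return x, dx, beta


@dataclass
class SimulationResult:
    """Location-resolved output of a pulse-wave run.

    ``probes`` maps each probe position (m) to a final-cycle DataFrame with
    columns time_s, pressure_Pa, area_m2, flow_m3_per_s, wss_Pa.
    ``history`` carries the same quantities over all simulated cycles, and
    ``diagnostics`` the convergence, conservation and CFL record.
    """

    vessel: SegmentedVessel
    fluid: FluidProperties
    settings: SolverSettings
    waveform: MeanVelocitySeries
    probes: dict
    history: dict
    diagnostics: dict

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics["converged"])

    def summary(self) -> pd.DataFrame:
        """Per-probe cycle extrema of WSS, pressure, hoop stress and strain."""
        from .report import summarize

        return summarize(self).table

    def to_csv(self, outdir) -> list:
        """Write one tidy CSV per probe; returns the paths written."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for xpos, df in self.probes.items():
            path = outdir / f"probe_{int(round(xpos * 1000))}mm.csv"
            df.to_csv(path, index=False)
            paths.append(path)
        return paths


def simulate(
    vessel: SegmentedVessel,
    waveform: MeanVelocitySeries | None = None,
    fluid: FluidProperties | None = None,
    settings: SolverSettings | None = None,
) -> SimulationResult:
    """Propagate the inlet waveform through the segmented vessel.

    Runs ``settings.cycles`` periods from zero initial conditions (A = A0,
    Q = 0, zero gauge pressure), prescribing the mean-velocity waveform at
    the inlet through the characteristic relations and a non-reflecting
    outlet, then reports final-cycle pressure, area, flow and wall shear
    stress at each probe position together with convergence and
    conservation diagnostics.
    """
    fluid = fluid or default_fluid()
    settings = settings or SolverSettings()
    if waveform is None:
        waveform = generate_waveform(
            default_waveform_params(fluid, vessel.geometry.inner_diameter)
        )
    T = waveform.period
    x, dx, beta = _stiffness_field(vessel, settings)
    n = x.size
    a0 = vessel.geometry.lumen_area
    rho = fluid.density

    c0_cells = np.sqrt(beta[1:-1] * math.sqrt(a0) / (2.0 * rho))
    u_peak = float(np.max(np.abs(waveform.values)))
    c_est = float(np.max(c0_cells)) + 2.0 * max(u_peak, 0.1)
    n_sub = max(int(math.ceil(settings.output_dt * c_est
                              / (settings.cfl_limit * dx))), 1)
    dt = settings.output_dt / n_sub

    n_out_cycle = int(round(T / settings.output_dt))
    if abs(n_out_cycle * settings.output_dt - T) > 1e-9 * T:
        raise ValueError("output_dt must divide the waveform period")
    n_out = settings.cycles * n_out_cycle

    # inlet velocity on the substep grid, via a band-limited fine resample
    if waveform.times.size < 4097:
        fine_n = 4096
        dec = decompose(waveform, harmonics=(waveform.times.size - 1) // 2)
        t_fine = np.linspace(0.0, T, fine_n + 1)
        v_fine = dec.reconstruct(t_fine)
    else:
        t_fine = waveform.times
        v_fine = waveform.values
    t_sub = np.arange(n_out * n_sub + 1) * dt
    u_sub = np.interp(np.mod(t_sub, T), t_fine, v_fine)

    probe_idx = np.array(
        [int(np.argmin(np.abs(x - xp))) for xp in vessel.probe_positions]
    )
    beta_probe = beta[1:-1][probe_idx]

    state = PulseWaveState(
        x_grid=x, area=np.full(n, a0), flow=np.zeros(n), time=0.0
    )
    rec_A = np.empty((n_out + 1, probe_idx.size))
    rec_Q = np.empty((n_out + 1, probe_idx.size))
    rec_A[0] = state.area[probe_idx]
    rec_Q[0] = state.flow[probe_idx]

    fin = fout = 0.0
    cfl_max = 0.0
    v_start = float(np.sum(state.area)) * dx
    for k in range(n_out):
        uin = u_sub[k * n_sub : (k + 1) * n_sub + 1]
        state, info = _run_kernel(state, beta, a0, fluid, dt, uin,
                                  _INLET_PRESCRIBED)
        fin += info["influx"]
        fout += info["outflux"]
        cfl_max = max(cfl_max, info["cfl_max"])
        rec_A[k + 1] = state.area[probe_idx]
        rec_Q[k + 1] = state.flow[probe_idx]
    v_end = float(np.sum(state.area)) * dx
    audit_rel = abs((v_end - v_start) - (fin - fout)) / v_start

    t_out = np.arange(n_out + 1) * settings.output_dt
    press = (np.sqrt(rec_A) - math.sqrt(a0)) * beta_probe[None, :]

    # cycle-to-cycle convergence of probe pressure
    convergence = []
    for c in range(1, settings.cycles):
        lo_prev, hi_prev = (c - 1) * n_out_cycle, c * n_out_cycle + 1
        lo, hi = c * n_out_cycle, (c + 1) * n_out_cycle + 1
        diff = np.max(np.abs(press[lo:hi] - press[lo_prev:hi_prev]), axis=0)
        scale = np.maximum(np.max(np.abs(press[lo_prev:hi_prev]), axis=0), 1e-300)
        convergence.append(diff / scale)
    last_change = (convergence[-1] if convergence
                   else np.full(probe_idx.size, np.nan))
    converged = bool(convergence and
                     np.all(last_change <= settings.convergence_tolerance))

    # final-cycle series and WSS closure per probe
    lo = (settings.cycles - 1) * n_out_cycle
    t_cycle = t_out[lo:] - t_out[lo]
    mu = fluid.dynamic_viscosity
    probes = {}
    history = {}
    for j, xp in enumerate(vessel.probe_positions):
        A_fin = rec_A[lo:, j]
        Q_fin = rec_Q[lo:, j]
        p_fin = press[lo:, j]
        R_inst = np.sqrt(A_fin / math.pi)
        if settings.wss_model == "poiseuille":
            wss = 4.0 * mu * Q_fin / (math.pi * R_inst**3)
        else:
            from .womersley import mode_wall_shear

            u_mean = Q_fin / A_fin
            u_closed = u_mean.copy()
            closure = 0.5 * (u_closed[0] + u_closed[-1])
            u_closed[0] = u_closed[-1] = closure
            series = MeanVelocitySeries(times=t_cycle, values=u_closed)
            dec_p = decompose(
                series,
                harmonics=min(settings.wss_harmonics, (t_cycle.size - 1) // 2),
            )
            wss = mode_wall_shear(fluid, vessel.geometry, dec_p, t_cycle)
        probes[xp] = pd.DataFrame(
            {
                "time_s": t_cycle,
                "pressure_Pa": p_fin,
                "area_m2": A_fin,
                "flow_m3_per_s": Q_fin,
                "wss_Pa": wss,
            }
        )
        history[xp] = pd.DataFrame(
            {
                "time_s": t_out,
                "pressure_Pa": press[:, j],
                "area_m2": rec_A[:, j],
                "flow_m3_per_s": rec_Q[:, j],
            }
        )

    seg_speeds = {"extension": wave_speed(
        tube_law_for(vessel.geometry, vessel.extension_material), a0, fluid
    )}
    for i, (_, m) in enumerate(vessel.segments):
        seg_speeds[f"segment_{i}"] = wave_speed(
            tube_law_for(vessel.geometry, m), a0, fluid
        )

    diagnostics = {
        "dt": dt,
        "dx": dx,
        "n_cells": n,
        "n_substeps_per_output": n_sub,
        "cfl_max": cfl_max,
        "volume_audit_rel": audit_rel,
        "cycle_convergence": {
            float(xp): float(last_change[j])
            for j, xp in enumerate(vessel.probe_positions)
        },
        "converged": converged,
        "convergence_tolerance": settings.convergence_tolerance,
        "wave_speeds_m_per_s": seg_speeds,
        "probe_cell_positions_m": [float(x[i]) for i in probe_idx],
    }
    return SimulationResult(
        vessel=vessel,
        fluid=fluid,
        settings=settings,
        waveform=waveform,
        probes=probes,
        history=history,
        diagnostics=diagnostics,
    )


class PulseWaveModel:
    """Segmented-vessel pulse-wave model: vessel + inlet waveform + fluid.

    A thin model object over :func:`simulate`; ``run()`` returns a
    :class:`SimulationResult` whose ``summary()`` tabulates the per-probe
    cycle extrema.
    """

    def __init__(
        self,
        vessel: SegmentedVessel,
        waveform: MeanVelocitySeries | None = None,
        fluid: FluidProperties | None = None,
        settings: SolverSettings | None = None,
    ):
        self.vessel = vessel
        self.fluid = fluid or default_fluid()
        self.waveform = waveform
        self.settings = settings or SolverSettings()

    @classmethod
    def from_config(cls, path) -> "PulseWaveModel":
        from .model import load_config
        from .waveform import WaveformParams

        cfg = load_config(path)
        settings = SolverSettings(**cfg.get("solver", {}))
        wf = None
        if "waveform" in cfg:
            params = WaveformParams(period=cfg["period"], **cfg["waveform"])
            wf = generate_waveform(params)
        return cls(cfg["vessel"], wf, cfg["fluid"], settings)

    def run(self) -> SimulationResult:
        return simulate(self.vessel, self.waveform, self.fluid, self.settings)
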