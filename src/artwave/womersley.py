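"""Closed-form pulsatile flow in a rigid straight tube.

Implements the classical oscillatory pipe-flow solution: for each Fourier
mode of the prescribed cross-sectional mean velocity, the axial velocity
profile is the Bessel-function (J0/J1) solution of the linearised
axisymmetric Navier-Stokes equations, normalised so its cross-sectional
average reproduces that mode's coefficient.  The steady mode carries the
Poiseuille parabola.  Wall shear stress and the per-mode driving pressure
gradient are recovered analytically.

This module is the analytic oracle for the 1D compliant-tube solver in the
rigid-wall limit, and supplies the model's dimensionless numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import jv

from .model import FluidProperties, VesselGeometry
from .waveform import HarmonicDecomposition

__all__ = [
    "womersley_number",
    "reynolds_number",
    "FlowField",
    "solve_womersley",
    "wss_series",
    "mode_wall_shear",
]

# below this mode Womersley number the Bessel expressions lose accuracy to
# cancellation; substitute the exact quasi-steady (Poiseuille) limit
_ALPHA_QUASI_STEADY = 1e-3


def womersley_number(
    fluid: FluidProperties, geometry: VesselGeometry, period: float
) -> float:
    """alpha = (D0/2) * sqrt(2*pi*rho / (T*mu)).

    Ratio of oscillatory inertia to viscous forces for the fundamental
    cardiac frequency; about 5.5 for an 8 mm carotid lumen at T = 1 s.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    return geometry.inner_radius * math.sqrt(
        2 * math.pi * fluid.density / (period * fluid.dynamic_viscosity)
    )


def reynolds_number(
    fluid: FluidProperties, inner_diameter: float, mean_velocity: float
) -> float:
    """Re = rho * D0 * V / mu for the instantaneous mean velocity V >= 0."""
    if inner_diameter <= 0:
        raise ValueError("inner_diameter must be > 0")
    if mean_velocity < 0:
        raise ValueError(
            "mean_velocity must be >= 0; take abs() upstream for reverse flow"
        )
    return fluid.density * inner_diameter * mean_velocity / fluid.dynamic_viscosity


@dataclass(frozen=True)
class FlowField:
    """Axisymmetric velocity field u(r, t) in a rigid tube with derived WSS.

    ``axial_velocity`` has shape (n_radii, n_times); ``wall_shear_stress``
    (positive for forward flow) and ``pressure_gradient`` (-dp/dx) are time
    series on ``times``.
    """

    radial_grid: np.ndarray
    times: np.ndarray
    axial_velocity: np.ndarray
    wall_shear_stress: np.ndarray
    pressure_gradient: np.ndarray

    def mean_velocity(self) -> np.ndarray:
        """Cross-sectional average (2/R^2) * int u r dr by trapezoid."""
        r = self.radial_grid
        R = r[-1]
        return 2.0 / R**2 * np.trapezoid(self.axial_velocity * r[:, None], r, axis=0)


def _mode_quantities(alpha_k: float):
    """Profile shape phi(r_hat), wall-derivative and pressure factors of a mode.

    Returns ``(phi, dphi_wall, pg_factor)`` where, for a mode with mean
    velocity coefficient c, the velocity is ``c * phi(r_hat)``, the wall
    shear stress is ``-mu/R * c * dphi_wall``, and the driving -dp/dx is
    ``pg_factor * rho * omega_k * c`` (complex amplitudes throughout).
    """
    lam = 1j**1.5 * alpha_k

    def phi(r_hat: np.ndarray) -> np.ndarray:
        D = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
        return (1.0 - jv(0, lam * r_hat) / jv(0, lam)) / D

    D = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    dphi_wall = lam * jv(1, lam) / (jv(0, lam) * D)
    pg_factor = -1j / D
    return phi, dphi_wall, pg_factor


def solve_womersley(
    fluid: FluidProperties,
    geometry: VesselGeometry,
    harmonics: HarmonicDecomposition,
    radial_points: int = 64,
    times: np.ndarray | None = None,
) -> FlowField:
    """Superpose per-mode rigid-tube profiles driven by mean-velocity harmonics.

    Mode 0 contributes the Poiseuille parabola with the signal's steady mean;
    each oscillatory mode contributes the classical profile normalised so its
    cross-sectional average equals the corresponding harmonic coefficient.
    """
    if radial_points < 8:
        raise ValueError("radial_points must be >= 8")
    R = geometry.inner_radius
    mu = fluid.dynamic_viscosity
    rho = fluid.density
    omega0 = harmonics.fundamental_frequency
    if times is None:
        T = 2 * math.pi / omega0
        times = np.linspace(0.0, T, 201)
    times = np.asarray(times, dtype=float)
    r = np.linspace(0.0, R, radial_points)
    r_hat = r / R
    coeffs = harmonics.complex_coefficients

    u = np.zeros((r.size, times.size))
    tau = np.zeros(times.size)
    pgrad = np.zeros(times.size)

    # steady mode: Poiseuille
    u0 = coeffs[0].real
    u += 2.0 * u0 * (1.0 - r_hat**2)[:, None]
    tau += 4.0 * mu * u0 / R
    pgrad += 8.0 * mu * u0 / R**2

    for k in range(1, coeffs.size):
        c = coeffs[k]
        if c == 0:
            continue
        omega_k = k * omega0
        alpha_k = R * math.sqrt(omega_k * rho / mu)
        phase = np.exp(1j * omega_k * times)
        if alpha_k < _ALPHA_QUASI_STEADY:
            # quasi-steady limit: parabola oscillating in lockstep
            u += np.real(np.outer(2.0 * (1.0 - r_hat**2), c * phase))
            tau += np.real(4.0 * mu * c / R * phase)
            pgrad += np.real(8.0 * mu * c / R**2 * phase)
            continue
        phi, dphi_wall, pg_factor = _mode_quantities(alpha_k)
        u += np.real(np.outer(phi(r_hat), c * phase))
        tau += np.real(-mu / R * c * dphi_wall * phase)
        pgrad += np.real(pg_factor * rho * omega_k * c * phase)

    u[-1, :] = 0.0  # no-slip, exact
    return FlowField(
        radial_grid=r,
        times=times,
        axial_velocity=u,
        wall_shear_stress=tau,
        pressure_gradient=pgrad,
    )


def mode_wall_shear(
    fluid: FluidProperties,
    geometry: VesselGeometry,
    harmonics: HarmonicDecomposition,
    times: np.ndarray,
) -> np.ndarray:
    """Wall shear stress series implied by mean-velocity harmonics alone.

    Same per-mode analytics as :func:`solve_womersley` without building the
    full radial field; used as the frequency-corrected WSS closure for the
    1D solver.
    """
    R = geometry.inner_radius
    mu = fluid.dynamic_viscosity
    rho = fluid.density
    omega0 = harmonics.fundamental_frequency
    times = np.asarray(times, dtype=float)
    coeffs = harmonics.complex_coefficients
    tau = np.full(times.size, 4.0 * mu * coeffs[0].real / R)
    for k in range(1, coeffs.size):
        c = coeffs[k]
        if c == 0:
            continue
        omega_k = k * omega0
        alpha_k = R * math.sqrt(omega_k * rho / mu)
        phase = np.exp(1j * omega_k * times)
        if alpha_k < _ALPHA_QUASI_STEADY:
            tau += np.real(4.0 * mu * c / R * phase)
        else:
            _, dphi_wall, _ = _mode_quantities(alpha_k)
            tau += np.real(-mu / R * c * dphi_wall * phase)
    return tau


def wss_series(flowfield: FlowField) -> pd.DataFrame:
    """Wall-shear-stress time series with cycle extrema attached.

    Returns a DataFrame (time_s, wss_Pa) whose ``attrs`` carry the cycle
    ``max``, ``min`` and ``mean``.
    """
    df = pd.DataFrame(
        {"time_s": flowfield.times, "wss_Pa": flowfield.wall_shear_stress}
    )
    df.attrs["max"] = float(df["wss_Pa"].max())
    df.attrs["min"] = float(df["wss_Pa"].min())
    df.attrs["mean"] = float(np.trapezoid(df["wss_Pa"], df["time_s"])
                             / (df["time_s"].iloc[-1] - df["time_s"].iloc[0]))
    return df
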