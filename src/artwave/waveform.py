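"""Synthetic carotid-like inlet waveform.

The inlet boundary condition is a periodic cross-sectional mean velocity with
a diastolic plateau and a single systolic pulse, a stand-in for a measured
carotid flow waveform.  The shape is an explicit closed form — plateau plus a
raised-cosine (Hann) systolic bump — truncated to a configurable number of
Fourier harmonics so it is smooth and band-limited.  Default velocity levels
are derived from the target Reynolds-number envelope (about 190 in diastole
to 500 at peak systole for an 8 mm lumen) rather than hard-coded, so fluid
property overrides stay consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import FluidProperties, default_fluid

__all__ = [
    "WaveformParams",
    "MeanVelocitySeries",
    "HarmonicDecomposition",
    "generate_waveform",
    "decompose",
    "default_waveform_params",
    "velocity_for_reynolds",
    "RE_DIASTOLE",
    "RE_SYSTOLE",
]

#: Reynolds-number envelope of the reference inlet waveform
RE_DIASTOLE = 190.0
RE_SYSTOLE = 500.0


def velocity_for_reynolds(
    reynolds: float, fluid: FluidProperties, inner_diameter: float
) -> float:
    """Mean velocity (m/s) giving the requested Re = rho*D*V/mu."""
    if reynolds < 0:
        raise ValueError("Reynolds number must be >= 0")
    return reynolds * fluid.dynamic_viscosity / (fluid.density * inner_diameter)


@dataclass(frozen=True)
class WaveformParams:
    """Closed-form waveform family: plateau + raised-cosine systolic pulse.

    ``peak_time_fraction`` locates the systolic peak within the cycle and
    ``systolic_width_fraction`` is the full width of the raised-cosine bump,
    both as fractions of the period.  The series is band-limited to
    ``harmonics_retained`` Fourier modes.
    """

    period: float = 1.0
    diastolic_mean_velocity: float = 0.08
    peak_mean_velocity: float = 0.21
    peak_time_fraction: float = 0.15
    systolic_width_fraction: float = 0.25
    harmonics_retained: int = 12

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.diastolic_mean_velocity < 0:
            raise ValueError("diastolic_mean_velocity must be >= 0")
        if self.peak_mean_velocity < self.diastolic_mean_velocity:
            raise ValueError("peak velocity must be >= diastolic velocity")
        if not 0 < self.peak_time_fraction < 1:
            raise ValueError("peak_time_fraction must lie in (0, 1)")
        if not 0 < self.systolic_width_fraction < 1:
            raise ValueError("systolic_width_fraction must lie in (0, 1)")
        if self.harmonics_retained < 1:
            raise ValueError("harmonics_retained must be >= 1")


def default_waveform_params(
    fluid: FluidProperties | None = None,
    inner_diameter: float = 0.008,
    re_diastole: float = RE_DIASTOLE,
    re_systole: float = RE_SYSTOLE,
    period: float = 1.0,
) -> WaveformParams:
    """Reference waveform whose Re envelope matches the stated range."""
    fluid = fluid or default_fluid()
    return WaveformParams(
        period=period,
        diastolic_mean_velocity=velocity_for_reynolds(
            re_diastole, fluid, inner_diameter
        ),
        peak_mean_velocity=velocity_for_reynolds(re_systole, fluid, inner_diameter),
    )


@dataclass(frozen=True)
class MeanVelocitySeries:
    """One period of cross-sectional mean velocity on a uniform time grid.

    ``times`` runs from 0 to the period inclusive; the first and last values
    coincide (periodic closure).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 3:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        scale = max(np.max(np.abs(v)), 1.0)
        if abs(v[0] - v[-1]) > 1e-12 * scale:
            raise ValueError("series must be periodic: first and last values differ")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def time_average(self) -> float:
        """Trapezoidal mean over one period."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def evaluate(self, t) -> np.ndarray:
        """Periodic evaluation at arbitrary times via the full DFT."""
        dec = decompose(self, harmonics=(self.times.size - 1) // 2)
        return dec.reconstruct(t)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.times, "mean_velocity_m_per_s": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeanVelocitySeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(float),
            values=df["mean_velocity_m_per_s"].to_numpy(float),
        )


@dataclass(frozen=True)
class HarmonicDecomposition:
    """One-sided Fourier representation of a periodic signal.

    ``complex_coefficients[k]`` is the coefficient of mode k in
    ``v(t) = Re( sum_k c_k exp(i k w0 t) )``; c_0 is the real steady mean.
    """

    fundamental_frequency: float  # rad/s
    complex_coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.complex_coefficients, dtype=complex)
        if abs(c[0].imag) > 1e-12 * max(abs(c[0]), 1.0):
            raise ValueError("mode-0 coefficient must be real")
        object.__setattr__(self, "complex_coefficients", c)

    @property
    def n_harmonics(self) -> int:
        return self.complex_coefficients.size - 1

    @property
    def mean(self) -> float:
        return float(self.complex_coefficients[0].real)

    def reconstruct(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.arange(self.complex_coefficients.size)
        phases = np.exp(
            1j * self.fundamental_frequency * np.multiply.outer(t, k)
        )
        out = np.real(phases @ self.complex_coefficients)
        return out if out.shape else float(out)

    def power(self) -> float:
        """Mean-square signal power, sum over modes of |c_k|^2 weights."""
        c = self.complex_coefficients
        return float(abs(c[0]) ** 2 + 0.5 * np.sum(np.abs(c[1:]) ** 2))


def _closed_form(params: WaveformParams, t: np.ndarray) -> np.ndarray:
    """Plateau + raised-cosine bump, before band-limiting."""
    T = params.period
    amp = params.peak_mean_velocity - params.diastolic_mean_velocity
    tp = params.peak_time_fraction * T
    w = params.systolic_width_fraction * T
    # wrapped distance from the peak
    d = np.mod(t - tp + T / 2, T) - T / 2
    bump = np.where(
        np.abs(d) <= w / 2, 0.5 * (1 + np.cos(2 * math.pi * d / w)), 0.0
    )
    return params.diastolic_mean_velocity + amp * bump


def generate_waveform(params: WaveformParams, n_samples: int = 256) -> MeanVelocitySeries:
    """Sample one period of the band-limited waveform on a uniform grid.

    The closed form is evaluated on a fine grid, truncated to
    ``harmonics_retained`` Fourier modes, affinely renormalised so the
    band-limited series still spans exactly [diastolic, peak] velocity
    (truncation otherwise clips the extremes slightly), and resampled at
    ``n_samples`` points (plus the periodic closing point).
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    T = params.period
    if params.peak_mean_velocity == params.diastolic_mean_velocity:
        t = np.linspace(0.0, T, n_samples + 1)
        return MeanVelocitySeries(t, np.full(n_samples + 1, params.peak_mean_velocity))
    # band-limit on a fine grid so the retained coefficients are converged
    n_fine = max(4096, 8 * n_samples)
    t_fine = np.arange(n_fine) * (T / n_fine)
    v_fine = _closed_form(params, t_fine)
    spec = np.fft.rfft(v_fine) / n_fine
    K = min(params.harmonics_retained, spec.size - 1)
    coeffs = np.zeros(K + 1, dtype=complex)
    coeffs[0] = spec[0].real
    coeffs[1:] = 2.0 * spec[1 : K + 1]
    dec = HarmonicDecomposition(2 * math.pi / T, coeffs)
    # renormalise against the fine grid (grid-independent), not the output grid
    v_ref = dec.reconstruct(t_fine)
    lo, hi = float(np.min(v_ref)), float(np.max(v_ref))
    gain = (params.peak_mean_velocity - params.diastolic_mean_velocity) / (hi - lo)
    offset = params.diastolic_mean_velocity - gain * lo
    t = np.linspace(0.0, T, n_samples + 1)
    v = offset + gain * dec.reconstruct(t)
    # enforce exact periodic closure (reconstruct is periodic up to roundoff)
    v[-1] = v[0]
    return MeanVelocitySeries(t, v)


def decompose(series: MeanVelocitySeries, harmonics: int) -> HarmonicDecomposition:
    """Discrete Fourier analysis of one period, truncated to ``harmonics`` modes.

    Requires a uniform grid; the duplicated closing sample is dropped before
    the FFT.  Mode 0 equals the time average of the series.
    """
    t = series.times
    dt = np.diff(t)
    if np.max(dt) - np.min(dt) > 1e-9 * np.mean(dt):
        raise ValueError("decompose requires a uniform time grid")
    v = series.values[:-1]  # drop periodic duplicate
    n = v.size
    if harmonics < 0 or harmonics > n // 2:
        raise ValueError(
            f"harmonics must lie in [0, {n // 2}] for an {n}-sample grid"
        )
    spec = np.fft.rfft(v) / n
    coeffs = np.zeros(harmonics + 1, dtype=complex)
    coeffs[0] = spec[0].real
    kmax = min(harmonics, spec.size - 1)
    coeffs[1 : kmax + 1] = 2.0 * spec[1 : kmax + 1]
    if n % 2 == 0 and harmonics >= n // 2:
        coeffs[n // 2] *= 0.5  # Nyquist mode is not doubled
    return HarmonicDecomposition(2 * math.pi / series.period, coeffs)


def with_noise(
    series: MeanVelocitySeries, amplitude: float, seed: int
) -> MeanVelocitySeries:
    """Optional measurement-noise overlay (periodic, zero at the closure)."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, amplitude, series.values.size)
    noise[-1] = noise[0]
    return replace(series, values=series.values + noise)
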