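"""Linear-elastic wall stress and strain post-processing.

Circumferential (hoop) stress at the inner wall follows the classical Lamé
thick-walled-cylinder solution for an internally/externally pressurised
tube.  Hoop strain is available through two routes: constitutive
(generalised Hooke's law from the Lamé stresses, plane-strain axial state by
default) and kinematic (engineering strain of the mid-wall circumference
implied by the 1D solver's cross-sectional area).  The kinematic route
inherits the segment-wise stiffness through the tube law and is the one
used for probe-to-probe strain comparison.
"""

from __future__ import annotations

import numpy as np

from .model import VesselGeometry, WallMaterial

__all__ = [
    "lame_hoop_stress",
    "lame_radial_stress",
    "hoop_strain_constitutive",
    "hoop_strain_kinematic",
    "hoop_series",
]


def _check_radius(geometry: VesselGeometry, r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    a, b = geometry.inner_radius, geometry.outer_radius
    if np.any(r < a - 1e-15) or np.any(r > b + 1e-15):
        raise ValueError(f"radius {r} outside wall [{a}, {b}] m")
    return r


def lame_hoop_stress(p_in, p_out, geometry: VesselGeometry, r) -> np.ndarray:
    """Hoop stress sigma_theta(r) of a pressurised thick-walled cylinder.

    sigma_theta = (p_in a^2 - p_out b^2)/(b^2 - a^2)
                  + (p_in - p_out) a^2 b^2 / ((b^2 - a^2) r^2)
    with a, b the inner and outer wall radii.  ``p_in`` may be a time
    series; broadcasting follows numpy rules.
    """
    r = _check_radius(geometry, r)
    p_in = np.asarray(p_in, dtype=float)
    p_out = np.asarray(p_out, dtype=float)
    a2 = geometry.inner_radius**2
    b2 = geometry.outer_radius**2
    denom = b2 - a2
    return (p_in * a2 - p_out * b2) / denom + (p_in - p_out) * a2 * b2 / (
        denom * r**2
    )


def lame_radial_stress(p_in, p_out, geometry: VesselGeometry, r) -> np.ndarray:
    """Radial stress sigma_r(r); equals -p_in at r = a and -p_out at r = b."""
    r = _check_radius(geometry, r)
    p_in = np.asarray(p_in, dtype=float)
    p_out = np.asarray(p_out, dtype=float)
    a2 = geometry.inner_radius**2
    b2 = geometry.outer_radius**2
    denom = b2 - a2
    return (p_in * a2 - p_out * b2) / denom - (p_in - p_out) * a2 * b2 / (
        denom * r**2
    )


def hoop_strain_constitutive(
    sigma_theta,
    sigma_r,
    material: WallMaterial,
    sigma_z=None,
) -> np.ndarray:
    """Hooke's-law hoop strain eps_theta = (s_theta - nu (s_r + s_z)) / E.

    When ``sigma_z`` is omitted the plane-strain axial stress
    ``nu (s_theta + s_r)`` is used, appropriate for a long constrained tube.
    """
    sigma_theta = np.asarray(sigma_theta, dtype=float)
    sigma_r = np.asarray(sigma_r, dtype=float)
    nu = material.poissons_ratio
    if sigma_z is None:
        sigma_z = nu * (sigma_theta + sigma_r)
    else:
        sigma_z = np.asarray(sigma_z, dtype=float)
    return (sigma_theta - nu * (sigma_r + sigma_z)) / material.youngs_modulus


def hoop_strain_kinematic(area_series, reference_area: float) -> np.ndarray:
    """Circumferential engineering strain from lumen distension.

    eps_theta = (sqrt(A) - sqrt(A0)) / sqrt(A0) = dR / R0, the strain route
    used for probe-wise comparison of the simulated vessel.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be > 0")
    a = np.asarray(area_series, dtype=float)
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    s0 = np.sqrt(reference_area)
    return (np.sqrt(a) - s0) / s0


def hoop_series(
    pressure_series,
    area_series,
    geometry: VesselGeometry,
    material: WallMaterial,
    external_pressure: float = 0.0,
):
    """Inner-wall hoop stress and kinematic hoop strain time series.

    Returns ``(stress, strain)`` arrays: Lamé hoop stress at the inner
    radius driven by the simulated lumen pressure, and kinematic strain from
    the simulated area.
    """
    stress = lame_hoop_stress(
        pressure_series, external_pressure, geometry, geometry.inner_radius
    )
    strain = hoop_strain_kinematic(area_series, geometry.lumen_area)
    return stress, strain
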