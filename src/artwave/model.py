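"""Physical model definition: fluid, wall materials, geometry, segmentation.

The reference configuration is a straight, constant-diameter vessel made of
three 50 mm segments whose middle segment is 40x more compliant than its
neighbours (Young's modulus 5 MPa vs 200 MPa), preceded by a 30 mm inlet
extension.  All quantities are SI internally; the config-file loader accepts
mm / MPa with explicit unit keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "FluidProperties",
    "WallMaterial",
    "VesselGeometry",
    "SegmentedVessel",
    "build_default_model",
    "default_fluid",
    "load_config",
    "save_config",
]

#: blood density (kg/m^3) and dynamic viscosity (Pa s) of the reference model
BLOOD_DENSITY = 1050.0
BLOOD_VISCOSITY = 0.0035

#: cardiac period of the reference inlet waveform (s)
DEFAULT_PERIOD = 1.0

#: default axial probe positions, measured from the inlet (m)
DEFAULT_PROBES = (0.070, 0.100, 0.140)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian incompressible fluid: density (kg/m^3), viscosity (Pa s)."""

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.dynamic_viscosity <= 0:
            raise ValueError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class WallMaterial:
    """Linear-elastic, isotropic wall: Young's modulus (Pa), Poisson ratio."""

    youngs_modulus: float
    poissons_ratio: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError(f"youngs_modulus must be > 0, got {self.youngs_modulus}")
        if not 0.0 <= self.poissons_ratio < 0.5:
            raise ValueError(
                f"poissons_ratio must lie in [0, 0.5), got {self.poissons_ratio}"
            )


@dataclass(frozen=True)
class VesselGeometry:
    """Cross-sectional geometry of a straight round vessel (SI metres)."""

    inner_diameter: float
    outer_diameter: float

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError(
                "need outer_diameter > inner_diameter > 0, got "
                f"inner={self.inner_diameter}, outer={self.outer_diameter}"
            )

    @property
    def wall_thickness(self) -> float:
        return (self.outer_diameter - self.inner_diameter) / 2.0

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def lumen_area(self) -> float:
        import math

        return math.pi * self.inner_radius**2


@dataclass(frozen=True)
class SegmentedVessel:
    """Axially segmented vessel with per-segment wall material.

    ``segments`` is an ordered list of ``(length_m, WallMaterial)`` pairs laid
    out downstream of an inlet extension of length
    ``inlet_extension_length`` whose material is
    ``extension_material``.  ``probe_positions`` are axial distances from the
    inlet at which the solver records waveforms.
    """

    segments: tuple[tuple[float, WallMaterial], ...]
    inlet_extension_length: float
    extension_material: WallMaterial
    geometry: VesselGeometry
    probe_positions: tuple[float, ...] = field(default=DEFAULT_PROBES)

    def __post_init__(self) -> None:
        if self.inlet_extension_length < 0:
            raise ValueError("inlet_extension_length must be >= 0")
        if not self.segments:
            raise ValueError("at least one segment is required")
        for length, _ in self.segments:
            if length <= 0:
                raise ValueError("segment lengths must be > 0")
        total = self.total_length
        for x in self.probe_positions:
            if not 0.0 <= x <= total:
                raise ValueError(
                    f"probe position {x} m outside vessel [0, {total}] m"
                )

    @property
    def total_length(self) -> float:
        return self.inlet_extension_length + sum(L for L, _ in self.segments)

    def boundaries(self) -> list[float]:
        """Axial positions of the interior material transitions (m)."""
        edges = []
        x = self.inlet_extension_length
        if x > 0:
            edges.append(x)
        for length, _ in self.segments[:-1]:
            x += length
            edges.append(x)
        return edges

    def material_at(self, x: float) -> WallMaterial:
        """Wall material of the segment containing axial position ``x``.

        A point exactly on a junction belongs to the downstream segment.
        """
        if not 0.0 <= x <= self.total_length:
            raise ValueError(
                f"axial position {x} m outside vessel [0, {self.total_length}] m"
            )
        if x < self.inlet_extension_length:
            return self.extension_material
        upstream_end = self.inlet_extension_length
        for i, (length, material) in enumerate(self.segments):
            upstream_end += length
            last = i == len(self.segments) - 1
            if x < upstream_end or last:
                return material
        raise AssertionError("unreachable")  # pragma: no cover


def default_fluid() -> FluidProperties:
    """Blood as modelled: rho = 1050 kg/m^3, mu = 3.5 mPa s."""
    return FluidProperties(density=BLOOD_DENSITY, dynamic_viscosity=BLOOD_VISCOSITY)


def build_default_model() -> SegmentedVessel:
    """Reference stiff-compliant-stiff vessel.

    30 mm stiff inlet extension, then 50 mm at 200 MPa, 50 mm at 5 MPa,
    50 mm at 200 MPa (total 180 mm); inner/outer diameters 8/10 mm;
    Poisson ratio 0.499 throughout; probes at 70, 100 and 140 mm.

    The stiffness of the inlet extension is not part of the reference
    description; it is assigned the stiff end-segment material so the vessel
    upstream of the compliant section is homogeneous.
    """
    stiff = WallMaterial(youngs_modulus=200e6, poissons_ratio=0.499)
    compliant = WallMaterial(youngs_modulus=5e6, poissons_ratio=0.499)
    return SegmentedVessel(
        segments=((0.050, stiff), (0.050, compliant), (0.050, stiff)),
        inlet_extension_length=0.030,
        extension_material=stiff,
        geometry=VesselGeometry(inner_diameter=0.008, outer_diameter=0.010),
        probe_positions=DEFAULT_PROBES,
    )


# ---------------------------------------------------------------------------
# Config file I/O.  Schema (YAML):
#
#   geometry:
#     inner_diameter_mm: 8.0
#     outer_diameter_mm: 10.0
#   wall:
#     poissons_ratio: 0.499
#     extension: {length_mm: 30.0, youngs_modulus_MPa: 200.0}
#     segments:
#       - {length_mm: 50.0, youngs_modulus_MPa: 200.0}
#       - {length_mm: 50.0, youngs_modulus_MPa: 5.0}
#       - {length_mm: 50.0, youngs_modulus_MPa: 200.0}
#   fluid: {density_kg_m3: 1050.0, dynamic_viscosity_Pa_s: 0.0035}
#   period_s: 1.0
#   probe_positions_mm: [70.0, 100.0, 140.0]
#   solver: {...}          # optional, passed through to SolverSettings
#   waveform: {...}        # optional, passed through to WaveformParams
# ---------------------------------------------------------------------------

_MM = 1e-3
_MPA = 1e6


def _vessel_to_dict(model: SegmentedVessel) -> dict:
    return {
        "geometry": {
            "inner_diameter_mm": model.geometry.inner_diameter / _MM,
            "outer_diameter_mm": model.geometry.outer_diameter / _MM,
        },
        "wall": {
            "poissons_ratio": model.segments[0][1].poissons_ratio,
            "extension": {
                "length_mm": model.inlet_extension_length / _MM,
                "youngs_modulus_MPa": model.extension_material.youngs_modulus / _MPA,
            },
            "segments": [
                {"length_mm": L / _MM, "youngs_modulus_MPa": m.youngs_modulus / _MPA}
                for L, m in model.segments
            ],
        },
        "probe_positions_mm": [x / _MM for x in model.probe_positions],
    }


def _vessel_from_dict(cfg: dict) -> SegmentedVessel:
    geo = cfg["geometry"]
    wall = cfg["wall"]
    nu = float(wall["poissons_ratio"])
    ext = wall["extension"]
    segments = tuple(
        (float(s["length_mm"]) * _MM,
         WallMaterial(float(s["youngs_modulus_MPa"]) * _MPA, nu))
        for s in wall["segments"]
    )
    return SegmentedVessel(
        segments=segments,
        inlet_extension_length=float(ext["length_mm"]) * _MM,
        extension_material=WallMaterial(
            float(ext["youngs_modulus_MPa"]) * _MPA, nu
        ),
        geometry=VesselGeometry(
            inner_diameter=float(geo["inner_diameter_mm"]) * _MM,
            outer_diameter=float(geo["outer_diameter_mm"]) * _MM,
        ),
        probe_positions=tuple(float(x) * _MM for x in cfg["probe_positions_mm"]),
    )


def save_config(
    path,
    model: SegmentedVessel,
    fluid: FluidProperties | None = None,
    period: float = DEFAULT_PERIOD,
    solver: dict | None = None,
    waveform: dict | None = None,
) -> None:
    """Write a run configuration (vessel + fluid + period + settings) as YAML."""
    fluid = fluid or default_fluid()
    cfg = _vessel_to_dict(model)
    cfg["fluid"] = {
        "density_kg_m3": fluid.density,
        "dynamic_viscosity_Pa_s": fluid.dynamic_viscosity,
    }
    cfg["period_s"] = period
    if solver:
        cfg["solver"] = solver
    if waveform:
        cfg["waveform"] = waveform
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> dict:
    """Read a YAML run configuration; returns a dict with SI-unit objects.

    Keys: ``vessel`` (SegmentedVessel), ``fluid`` (FluidProperties),
    ``period`` (s), plus raw ``solver`` / ``waveform`` dicts when present.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    fl = cfg.get("fluid", {})
    fluid = FluidProperties(
        density=float(fl.get("density_kg_m3", BLOOD_DENSITY)),
        dynamic_viscosity=float(fl.get("dynamic_viscosity_Pa_s", BLOOD_VISCOSITY)),
    )
    out = {
        "vessel": _vessel_from_dict(cfg),
        "fluid": fluid,
        "period": float(cfg.get("period_s", DEFAULT_PERIOD)),
    }
    if "solver" in cfg:
        out["solver"] = cfg["solver"]
    if "waveform" in cfg:
        out["waveform"] = cfg["waveform"]
    return out
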