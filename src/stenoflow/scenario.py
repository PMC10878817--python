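"""Synthetic valve-scenario generation.

This module builds the desk-scale stand-ins for patient-specific valve
geometries: a straight 2D channel (flow along +x, walls at the first and
last rows) carrying an occluder plate perforated either by a stenotic /
post-implant orifice or, for paravalvular-leak studies, by narrow gap
channels at prescribed locations. It also generates the driving pressure
waveforms calibrated to echocardiographic peak gradients, bundles fluid
and platelet-surrogate properties, and exposes named presets encoding the
comparative structure of calcific (CAS) versus fibrocalcific (FAS)
stenosis, before and after valve implantation.

Geometric conventions: grid indices are 0-based, fields are cell-centred,
``occupancy[y, x]`` is True on solid cells, and the longitudinal axis is
+x. The channel width spans the interior (non-wall) rows; upstream and
downstream fluid extensions are ``extension_factor`` channel widths long
on each side of the occluder. 2D masks carry an out-of-plane ``depth``
used whenever an area or a volume is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DomainError, GeometryError, ResolutionError
from .units import MMHG_TO_PA, mmhg_to_pa

SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# property bundles


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid properties (defaults: whole blood).

    dynamic_viscosity in Pa*s, fluid_density in kg/m^3.
    """

    dynamic_viscosity: float = 3.5e-3
    fluid_density: float = 1060.0

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0 or self.fluid_density <= 0:
            raise DomainError("viscosity and density must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.fluid_density


@dataclass(frozen=True)
class ParticleProperties:
    """Platelet-surrogate particle properties.

    Defaults follow the standard platelet surrogate: density 1125 kg/m^3,
    diameter 3 um, near-neutrally-buoyant spheres.
    """

    particle_density: float = 1125.0
    diameter: float = 3.0e-6
    drag_mode: str = "tracer"  # "tracer" | "stokes_drag"

    def __post_init__(self) -> None:
        if self.particle_density <= 0 or self.diameter <= 0:
            raise DomainError("particle density and diameter must be positive")
        if self.drag_mode not in ("tracer", "stokes_drag"):
            raise ConfigError(f"unknown drag_mode {self.drag_mode!r}")

    def relaxation_time(self, fluid: FluidProperties) -> float:
        """Stokes particle relaxation time tau_p = rho_p d^2 / (18 mu)."""
        return self.particle_density * self.diameter**2 / (
            18.0 * fluid.dynamic_viscosity
        )


# ---------------------------------------------------------------------------
# pressure waveform


@dataclass(frozen=True)
class PressureWaveform:
    """Upstream-minus-downstream pressure difference over one cardiac period.

    ``times`` are uniform samples in seconds over [0, period);
    ``pressure_gradient`` is the corresponding difference in Pa;
    ``peak_gradient`` is its maximum in Pa.
    """

    times: np.ndarray
    pressure_gradient: np.ndarray
    period: float
    peak_gradient: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressure_gradient, dtype=float)
        if self.period <= 0:
            raise DomainError("period must be positive")
        if t.shape != p.shape or t.ndim != 1:
            raise DomainError("times and pressure_gradient must be 1D and congruent")
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise DomainError("waveform samples must be uniformly spaced")
        if self.peak_gradient > 0 and not np.isclose(
            p.max(), self.peak_gradient, rtol=1e-3
        ):
            raise DomainError("sample maximum disagrees with peak_gradient")

    def at(self, t: float) -> float:
        """Pressure difference at time ``t`` (periodic, linear interpolation)."""
        tp = float(t) % self.period
        return float(np.interp(tp, self.times, self.pressure_gradient,
                               period=self.period))


def make_pressure_waveform(
    peak_gradient_mmhg: float,
    period: float = 0.8,
    systole_fraction: float = 0.375,
    n_samples: int = 256,
) -> PressureWaveform:
    """Build the single-pulse transvalvular pressure-gradient waveform.

    The template is one half-sine systolic pulse over the first
    ``systole_fraction`` of the period followed by a zero-gradient
    diastole; it is identical for every case and only its amplitude is
    rescaled so the maximum equals ``peak_gradient_mmhg`` converted to Pa
    (1 mmHg = 133.322 Pa). With the default 0.8 s period and systolic
    fraction 0.375 the diastole lasts 500 ms.

    Parameters
    ----------
    peak_gradient_mmhg : float
        Echo-derived peak transvalvular pressure gradient, mmHg; >= 0.
    period : float
        Cardiac period, s.
    systole_fraction : float
        Fraction of the period occupied by the systolic pulse, in (0, 1).
    n_samples : int
        Number of uniform samples over one period; >= 16.
    """
    if peak_gradient_mmhg < 0:
        raise DomainError("peak gradient must be non-negative")
    if not 0.0 < systole_fraction < 1.0:
        raise DomainError("systole_fraction must lie in (0, 1)")
    if n_samples < 16:
        raise ResolutionError("need at least 16 samples per period")
    peak_pa = mmhg_to_pa(peak_gradient_mmhg)
    t = np.arange(n_samples) * (period / n_samples)
    p = np.zeros(n_samples)
    systole = t < systole_fraction * period
    p[systole] = peak_pa * np.sin(np.pi * t[systole] / (systole_fraction * period))
    return PressureWaveform(times=t, pressure_gradient=p, period=period,
                            peak_gradient=peak_pa)


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class PlaneSection:
    """A cross-section plane normal to the longitudinal (+x) axis."""

    x_index: int
    label: str


@dataclass
class GeometryMask:
    """Boolean occupancy geometry on a uniform lattice (True = solid).

    ``occupancy`` has shape (ny, nx): first axis transverse (y), second
    longitudinal (x). Rows 0 and ny-1 are channel walls. ``depth`` is the
    out-of-plane extent used to convert per-unit-depth 2D quantities into
    areas and volumes.
    """

    occupancy: np.ndarray
    lattice_spacing: float
    depth: float
    channel_width: float
    orifice_descriptor: dict = field(default_factory=dict)
    gap_channels: list = field(default_factory=list)
    occluder_span: Optional[tuple] = None  # (x0, x1) cell range, exclusive end

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    @property
    def n_across(self) -> int:
        """Number of interior (fluid-capable) rows across the channel."""
        return self.occupancy.shape[0] - 2

    @property
    def fluid(self) -> np.ndarray:
        return ~self.occupancy

    def open_width_at(self, x: int) -> float:
        """Open (fluid) transverse extent at column ``x``, in metres."""
        return float((~self.occupancy[:, x]).sum()) * self.lattice_spacing

    def validate(self) -> None:
        occ = self.occupancy
        if occ.dtype != bool or occ.ndim != 2:
            raise GeometryError("occupancy must be a 2D boolean array")
        if occ[1:-1, 0].any() or occ[1:-1, -1].any():
            raise GeometryError("inlet and outlet faces must be fully fluid")


def _rasterize_area_matched(
    inside, target_area: float, dx: float, ny: int, nz: int, distance
) -> np.ndarray:
    """Rasterize a shape on cell centres, then toggle boundary cells by
    signed distance until the cell-counted area matches ``target_area``
    to within half a cell area."""
    yy, zz = np.meshgrid(
        (np.arange(ny) + 0.5) * dx, (np.arange(nz) + 0.5) * dx, indexing="ij"
    )
    mask = inside(yy, zz)
    n_target = int(round(target_area / dx**2))
    d = distance(yy, zz)  # negative inside
    order = np.argsort(d, axis=None, kind="stable")
    flat = np.zeros(mask.size, dtype=bool)
    flat[order[:n_target]] = True
    return flat.reshape(mask.shape)


def aperture_raster(shape: str, open_area: float, dx: float) -> np.ndarray:
    """Rasterize an orifice aperture of the requested open area on the
    plate face at spacing ``dx``; the cell count matches the analytic
    request to within one cell area.

    Supported shapes: ``circular``, ``triangular`` (equilateral),
    ``slit`` (square). Returns a boolean array, True = open.
    """
    if open_area <= 0:
        raise DomainError("open_area must be positive")
    # characteristic across-dimension of the aperture
    if shape == "circular":
        across = 2.0 * np.sqrt(open_area / np.pi)
    elif shape == "triangular":
        # equilateral triangle of area A: side s = sqrt(4A/sqrt(3)); the
        # across-dimension is its inradius*2
        s = np.sqrt(4.0 * open_area / np.sqrt(3.0))
        across = s / np.sqrt(3.0)
    elif shape == "slit":
        across = np.sqrt(open_area)
    else:
        raise ConfigError(f"unknown aperture shape {shape!r}")
    if across < 8 * dx:
        raise ResolutionError(
            f"{shape} aperture of area {open_area:.3e} m^2 spans "
            f"{across / dx:.1f} cells across; need >= 8"
        )
    pad = 4
    n = int(np.ceil(across / dx)) * 2 + 2 * pad
    c = n * dx / 2.0

    if shape == "circular":
        r = np.sqrt(open_area / np.pi)
        dist = lambda y, z: np.hypot(y - c, z - c) - r
    elif shape == "slit":
        h = np.sqrt(open_area) / 2.0
        dist = lambda y, z: np.maximum(np.abs(y - c), np.abs(z - c)) - h
    else:  # equilateral triangle, centroid at centre, apex up
        s = np.sqrt(4.0 * open_area / np.sqrt(3.0))
        r_in = s / (2 * np.sqrt(3.0))

        def dist(y, z):
            # max over the three edge half-plane distances; outward edge
            # normals of an apex-up equilateral triangle centred at (c, c)
            u, v = y - c, z - c
            d1 = -v - r_in
            d2 = (u * (np.sqrt(3) / 2) + v * 0.5) - r_in
            d3 = (-u * (np.sqrt(3) / 2) + v * 0.5) - r_in
            return np.maximum(np.maximum(d1, d2), d3)

    inside = lambda y, z: dist(y, z) < 0.0
    return _rasterize_area_matched(inside, open_area, dx, n, n, dist)


def make_orifice_geometry(
    channel_width: float,
    orifice_open_area: float,
    shape: str = "slit",
    extension_factor: float = 3.0,
    lattice_spacing: float = 2.0e-4,
    depth: Optional[float] = None,
    occluder_thickness_cells: int = 3,
) -> GeometryMask:
    """Build the channel + perforated-occluder mask for a valve orifice.

    The channel (width ``channel_width``, walls on the first and last
    rows) carries fluid extensions of ``extension_factor`` channel widths
    upstream and downstream of a plate occluder at mid-channel. The plate
    is perforated by an aperture of the requested shape and open area;
    in the 2D flow plane the aperture reduces to a centred slit whose
    width is ``open_area / depth``. The aperture raster and its
    cell-counted area are recorded in ``orifice_descriptor``.

    Requesting the full cross-section (``channel_width * depth``) yields
    an unobstructed channel with no occluder.
    """
    dx = lattice_spacing
    if depth is None:
        depth = channel_width
    n_across = int(round(channel_width / dx))
    if n_across < 4:
        raise ResolutionError("channel width under-resolved")
    full_area = channel_width * depth
    if orifice_open_area > full_area * (1 + 1e-9):
        raise DomainError("orifice_open_area exceeds the channel cross-section")
    ext = int(round(extension_factor * n_across))
    thk = occluder_thickness_cells
    nx = 2 * ext + thk
    ny = n_across + 2
    occ = np.zeros((ny, nx), dtype=bool)
    occ[0, :] = True
    occ[-1, :] = True

    descriptor = {"shape": "none", "open_area": full_area, "centroid": None}
    if orifice_open_area >= full_area * (1 - 1e-9):
        mask = GeometryMask(occ, dx, depth, channel_width, descriptor, [],
                            occluder_span=None)
        mask.validate()
        return mask

    if shape == "none":
        raise ConfigError("shape 'none' requires the full cross-section area")
    raster = aperture_raster(shape, orifice_open_area, dx)
    counted_area = float(raster.sum()) * dx**2

    slit_width = orifice_open_area / depth
    slit_cells = int(round(slit_width / dx))
    if slit_cells < 8:
        raise ResolutionError(
            f"orifice slit spans {slit_width / dx:.1f} cells in the flow "
            "plane; need >= 8"
        )
    x0 = ext
    occ[:, x0:x0 + thk] = True
    y0 = 1 + (n_across - slit_cells) // 2
    occ[y0:y0 + slit_cells, x0:x0 + thk] = False

    descriptor = {
        "shape": shape,
        "open_area": counted_area,
        "requested_area": orifice_open_area,
        "centroid": (0.5 * ny * dx, (x0 + 0.5 * thk) * dx),
        "aperture_raster": raster,
        "slit_cells": slit_cells,
        "slit_open_area": slit_cells * dx * depth,
    }
    mask = GeometryMask(occ, dx, depth, channel_width, descriptor, [],
                        occluder_span=(x0, x0 + thk))
    mask.validate()
    return mask


def make_pvl_geometry(base: GeometryMask, gap_spec: Sequence[dict]) -> GeometryMask:
    """Seal the occluder of ``base`` and carve paravalvular gap channels.

    ``gap_spec`` is a list of ``{"location_tag": "commissural" |
    "leaflet_stent", "width": metres}``. Commissural gaps sit at the
    occluder periphery (adjacent to the channel walls, alternating
    top/bottom); leaflet_stent gaps sit at mid-edge positions spread over
    the plate interior. Gap widths must span at least 2 lattice cells.
    An empty ``gap_spec`` returns a fully sealed occluder. The total gap
    area is recorded in ``gap_channels`` metadata.
    """
    if base.occluder_span is None:
        raise GeometryError("base geometry has no occluder to seal")
    dx = base.lattice_spacing
    occ = base.occupancy.copy()
    x0, x1 = base.occluder_span
    occ[1:-1, x0:x1] = True  # seal

    ny = occ.shape[0]
    n_across = base.n_across
    gaps = []
    n_comm_placed = 0
    interior = [g for g in gap_spec if g["location_tag"] == "leaflet_stent"]
    n_int = len(interior)
    i_int = 0
    for g in gap_spec:
        tag = g["location_tag"]
        width = float(g["width"])
        cells = int(round(width / dx))
        if cells < 2:
            raise GeometryError(
                f"gap of width {width:.2e} m spans {width / dx:.1f} cells; need >= 2"
            )
        if cells > n_across:
            raise GeometryError("gap wider than the occluder footprint")
        if tag == "commissural":
            # periphery: alternate top and bottom wall corners
            if n_comm_placed % 2 == 0:
                y0 = 1 + (n_comm_placed // 2) * (cells + 2)
            else:
                y0 = ny - 1 - cells - (n_comm_placed // 2) * (cells + 2)
            n_comm_placed += 1
        elif tag == "leaflet_stent":
            # mid-edge: spread across the plate interior
            i_int += 1
            frac = i_int / (n_int + 1)
            y0 = 1 + int(round(frac * n_across)) - cells // 2
        else:
            raise ConfigError(f"unknown gap location_tag {tag!r}")
        if y0 < 1 or y0 + cells > ny - 1:
            raise GeometryError("gap placement falls outside the occluder footprint")
        occ[y0:y0 + cells, x0:x1] = False
        gaps.append({"location_tag": tag, "width": cells * dx,
                     "requested_width": width, "y0": y0, "cells": cells,
                     "area": cells * dx * base.depth})

    descriptor = {"shape": "none" if not gaps else "pvl_gaps",
                  "open_area": sum(g["area"] for g in gaps),
                  "centroid": ((x0 + x1) / 2 * dx, 0.5 * ny * dx)}
    mask = GeometryMask(occ, dx, base.depth, base.channel_width, descriptor,
                        gaps, occluder_span=(x0, x1))
    mask.validate()
    return mask


# ---------------------------------------------------------------------------
# scenario bundle


@dataclass
class ScenarioSpec:
    """Complete description of one synthetic valve case."""

    name: str
    geometry: GeometryMask
    fluid: FluidProperties
    particles: ParticleProperties
    waveform: Optional[PressureWaveform] = None
    constant_pressure_pair_mmhg: Optional[tuple] = None  # (upstream, downstream)
    measurement_planes: list = field(default_factory=list)
    rng_seed: int = 0
    gradient_scale: float = 1.0
    relaxation_time: float = 1.0

    def __post_init__(self) -> None:
        if self.waveform is None and self.constant_pressure_pair_mmhg is None:
            raise ConfigError("scenario needs a waveform or a constant pressure pair")
        nx = self.geometry.shape[1]
        for pl in self.measurement_planes:
            if not 0 < pl.x_index < nx - 1:
                raise GeometryError(f"plane {pl.label} lies outside the domain")
            if self.geometry.occupancy[1:-1, pl.x_index].all():
                raise GeometryError(f"plane {pl.label} lies entirely in solid")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        g = self.geometry
        occ_rows = ["".join("#" if s else "." for s in row) for row in g.occupancy]
        desc = {k: v for k, v in g.orifice_descriptor.items()
                if k != "aperture_raster"}
        if desc.get("centroid") is not None:
            desc["centroid"] = list(desc["centroid"])
        wf = None
        if self.waveform is not None:
            wf = {
                "times": [float(t) for t in self.waveform.times],
                "pressure_gradient": [float(p) for p in
                                      self.waveform.pressure_gradient],
                "period": self.waveform.period,
                "peak_gradient": self.waveform.peak_gradient,
            }
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "geometry": {
                "occupancy": occ_rows,
                "lattice_spacing": g.lattice_spacing,
                "depth": g.depth,
                "channel_width": g.channel_width,
                "orifice_descriptor": desc,
                "gap_channels": g.gap_channels,
                "occluder_span": list(g.occluder_span) if g.occluder_span else None,
            },
            "fluid": asdict(self.fluid),
            "particles": asdict(self.particles),
            "waveform": wf,
            "constant_pressure_pair_mmhg": (
                list(self.constant_pressure_pair_mmhg)
                if self.constant_pressure_pair_mmhg else None),
            "measurement_planes": [
                {"x_index": p.x_index, "label": p.label}
                for p in self.measurement_planes],
            "rng_seed": self.rng_seed,
            "gradient_scale": self.gradient_scale,
            "relaxation_time": self.relaxation_time,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ConfigError("unsupported scenario schema version")
        gd = d["geometry"]
        occ = np.array([[ch == "#" for ch in row] for row in gd["occupancy"]])
        geom = GeometryMask(
            occ, gd["lattice_spacing"], gd["depth"], gd["channel_width"],
            dict(gd["orifice_descriptor"]), list(gd["gap_channels"]),
            tuple(gd["occluder_span"]) if gd["occluder_span"] else None)
        wf = None
        if d["waveform"] is not None:
            w = d["waveform"]
            wf = PressureWaveform(np.array(w["times"]),
                                  np.array(w["pressure_gradient"]),
                                  w["period"], w["peak_gradient"])
        return cls(
            name=d["name"], geometry=geom,
            fluid=FluidProperties(**d["fluid"]),
            particles=ParticleProperties(**d["particles"]),
            waveform=wf,
            constant_pressure_pair_mmhg=(
                tuple(d["constant_pressure_pair_mmhg"])
                if d["constant_pressure_pair_mmhg"] else None),
            measurement_planes=[PlaneSection(p["x_index"], p["label"])
                                for p in d["measurement_planes"]],
            rng_seed=d["rng_seed"], gradient_scale=d["gradient_scale"],
            relaxation_time=d["relaxation_time"])


# ---------------------------------------------------------------------------
# presets

#: Reference annulus: a 24 mm valve, area pi (D/2)^2 = 4.52 cm^2. Orifice
#: open fractions of the analogue presets are clinical orifice areas
#: divided by this reference, preserving the CAS < FAS pre-implant and
#: CAS > FAS post-implant area orderings.
ANNULUS_AREA_CM2 = float(np.pi * 1.2**2)

_PRESET_NAMES = ("healthy", "CAS_pre", "FAS_pre", "CAS_post_pvl", "FAS_post_pvl")

# Desk-scale analogue channel: 10 mm wide, 0.2 mm lattice (50 cells across).
_CHANNEL_WIDTH = 10.0e-3
_DX = 2.0e-4
#: Dynamic-similarity factor applied to driving pressure differences so the
#: desk-scale laminar lattice stays in its stability envelope; identical for
#: every preset, so all cross-preset orderings are preserved.
_GRADIENT_SCALE = 1.0e-5


def _orifice_preset(area_cm2: float, peak_mmhg: float, name: str,
                    shape: str) -> dict:
    frac = area_cm2 / ANNULUS_AREA_CM2
    return {"open_fraction": frac, "peak_mmhg": peak_mmhg, "name": name,
            "shape": shape}


_PRE_PRESETS = {
    # healthy tricuspid analogue: EOA 3.38 cm^2, normal gradient ~10 mmHg
    "healthy": _orifice_preset(3.38, 10.0, "healthy", "circular"),
    # calcific stenosis: 0.71 cm^2 orifice, 99 mmHg Echo peak, round opening
    "CAS_pre": _orifice_preset(0.71, 99.0, "CAS_pre", "circular"),
    # fibrocalcific stenosis: 0.80 cm^2 orifice, 74 mmHg Echo peak
    "FAS_pre": _orifice_preset(0.80, 74.0, "FAS_pre", "triangular"),
}

_PVL_PRESETS = {
    # calcific: few wide leaks between native leaflets and the stent
    "CAS_post_pvl": {"gaps": [
        {"location_tag": "leaflet_stent", "width": 1.0e-3},
        {"location_tag": "leaflet_stent", "width": 1.0e-3},
    ]},
    # fibrocalcific: several narrow leaks at the commissures
    "FAS_post_pvl": {"gaps": [
        {"location_tag": "commissural", "width": 0.4e-3},
        {"location_tag": "commissural", "width": 0.4e-3},
        {"location_tag": "commissural", "width": 0.4e-3},
    ]},
}


def make_scenario(preset: str, rng_seed: int = 0) -> ScenarioSpec:
    """Build a deterministic ScenarioSpec for a named preset.

    Presets encode the comparative study design: ``CAS_pre`` (small round
    orifice, 99 mmHg peak gradient), ``FAS_pre`` (slightly larger
    triangular orifice, 74 mmHg), ``healthy`` (wide opening, normal
    gradient), and the post-implant diastolic leak configurations
    ``CAS_post_pvl`` (two wide leaflet-stent gaps) and ``FAS_post_pvl``
    (three narrow commissural gaps) driven by a constant 90/0 mmHg
    aortic/ventricular pressure pair.
    """
    if preset not in _PRESET_NAMES:
        raise ConfigError(f"unknown preset {preset!r}; choose from {_PRESET_NAMES}")
    fluid = FluidProperties()
    particles = ParticleProperties()
    w = _CHANNEL_WIDTH
    if preset in _PRE_PRESETS:
        p = _PRE_PRESETS[preset]
        # analogue orifice area: open fraction applied to the 2D channel
        # cross-section (width x depth)
        area = p["open_fraction"] * w * w
        geom = make_orifice_geometry(w, area, shape=p["shape"],
                                     lattice_spacing=_DX, depth=w)
        wf = make_pressure_waveform(p["peak_mmhg"])
        planes = _default_planes(geom)
        return ScenarioSpec(
            name=preset, geometry=geom, fluid=fluid, particles=particles,
            waveform=wf, measurement_planes=planes, rng_seed=int(rng_seed),
            gradient_scale=_GRADIENT_SCALE)
    p = _PVL_PRESETS[preset]
    base = make_orifice_geometry(w, 0.25 * w * w, shape="slit",
                                 lattice_spacing=_DX, depth=w)
    geom = make_pvl_geometry(base, p["gaps"])
    planes = _default_planes(geom)
    return ScenarioSpec(
        name=preset, geometry=geom, fluid=fluid, particles=particles,
        constant_pressure_pair_mmhg=(90.0, 0.0),
        measurement_planes=planes, rng_seed=int(rng_seed),
        gradient_scale=_GRADIENT_SCALE)


def _default_planes(geom: GeometryMask) -> list:
    """Sub-annular measurement planes one and two channel widths
    downstream of the occluder (labelled AA' and BB'), plus a jet plane
    through the orifice itself (the effective-jet cross-section; at
    creeping-flow scale a downstream plane would already see the spread
    jet rather than its core)."""
    if geom.occluder_span is None:
        mid = geom.shape[1] // 2
        return [PlaneSection(mid, "AA'"), PlaneSection(mid + geom.n_across, "BB'")]
    x0, x1 = geom.occluder_span
    n = geom.n_across
    return [
        PlaneSection((x0 + x1) // 2, "jet"),
        PlaneSection(min(x1 + n, geom.shape[1] - 2), "AA'"),
        PlaneSection(min(x1 + 2 * n, geom.shape[1] - 2), "BB'"),
    ]
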