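"""Flow-field summary metrics: plane flux, paravalvular leak volume,
effective orifice area, peak jet velocity and wall shear stress.

All quantities are computed in SI internally; clinical reporting units
(ml/beat, cm^2) appear in the MetricReport. 2D fields report
per-unit-depth fluxes converted with the geometry's out-of-plane depth
(default: the channel width); the conversion is always recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, GeometryError
from .lbm import FlowSeries, FlowSnapshot
from .scenario import GeometryMask, PlaneSection
from .units import M2_TO_CM2, M3_TO_ML

log = logging.getLogger(__name__)


def plane_flux(snapshot: FlowSnapshot, plane: PlaneSection,
               geometry: GeometryMask) -> float:
    """Signed volumetric flow through a cross-section plane, m^3/s.

    Integral summation of the longitudinal velocity component over the
    open cells of the plane: Q = sum u_x * cell_area, with cell_area =
    spacing * depth. Positive flux points downstream (+x); in leak
    configurations that is the regurgitant aorta-to-ventricle direction.
    """
    nx = geometry.shape[1]
    if not 0 <= plane.x_index < nx:
        raise GeometryError(f"plane {plane.label} outside the domain")
    open_cells = ~geometry.occupancy[:, plane.x_index]
    ux = snapshot.velocity[open_cells, plane.x_index, 0]
    cell_area = geometry.lattice_spacing * geometry.depth
    return float(ux.sum() * cell_area)


def pvl_volume(flow: FlowSeries, plane: PlaneSection,
               window: float = 0.5, steady: bool | str = "auto") -> float:
    """Paravalvular leak volume through a sub-annular plane, ml per beat.

    The flux of the longitudinal velocity component is integrated over a
    diastolic window of ``window`` seconds (default 500 ms). With
    ``steady=True`` (or a series that cannot resolve the window) the
    final steady flux is held over the whole window, the appropriate
    treatment for constant-pressure diastolic runs; otherwise the
    time-resolved flux is integrated with the trapezoid rule over the
    snapshots covering the window, which must exist. The magnitude is
    reported; the regurgitant direction is the sign convention of
    :func:`plane_flux`.
    """
    if window <= 0:
        raise DomainError("window must be positive")
    geom = flow.geometry
    times = flow.times
    in_window = times <= times[0] + window * (1 + 1e-9) if len(flow) else []
    if steady == "auto":
        steady = len(flow) < 2 or int(np.sum(in_window)) < 2
    if steady:
        q = plane_flux(flow[-1], plane, geom)
        return abs(q) * window * M3_TO_ML
    if times[-1] - times[0] < window * (1 - 1e-9):
        raise DomainError("flow series does not cover the integration window")
    q = np.array([plane_flux(s, plane, geom) for s, m in
                  zip(flow.snapshots, in_window) if m])
    t = times[in_window]
    return abs(float(np.trapezoid(q, t))) * M3_TO_ML


def effective_orifice_area(snapshot: FlowSnapshot, plane: PlaneSection,
                           geometry: GeometryMask,
                           method: str = "continuity") -> float:
    """Effective orifice area of the jet on a plane, cm^2.

    ``continuity`` (default): EOA = Q / v_peak with Q the forward plane
    flux and v_peak the maximum longitudinal velocity on the plane — the
    functional jet area, bounded above by the geometric open area.
    ``velocity_threshold``: the summed area of plane cells with
    longitudinal velocity above half the peak.
    """
    nx = geometry.shape[1]
    if not 0 <= plane.x_index < nx:
        raise GeometryError(f"plane {plane.label} outside the domain")
    open_cells = ~geometry.occupancy[:, plane.x_index]
    ux = snapshot.velocity[open_cells, plane.x_index, 0]
    v_peak = float(ux.max())
    if v_peak <= 0:
        raise DomainError("no forward flow at the plane; EOA undefined")
    cell_area = geometry.lattice_spacing * geometry.depth
    if method == "continuity":
        q = float(np.clip(ux, 0.0, None).sum() * cell_area)
        return q / v_peak * M2_TO_CM2
    if method == "velocity_threshold":
        return float((ux > 0.5 * v_peak).sum() * cell_area) * M2_TO_CM2
    raise DomainError(f"unknown EOA method {method!r}")


@dataclass
class WSSProfile:
    """Wall shear stress along a wall, indexed by arc length."""

    arc_length: np.ndarray   # m, along the wall
    wss: np.ndarray          # Pa
    wall: str                # "bottom" | "top"


def wall_shear_stress(snapshot: FlowSnapshot, geometry: GeometryMask,
                      viscosity: float, walls: tuple = ("bottom", "top"),
                      ) -> list:
    """Viscous wall shear stress profiles along the channel walls, Pa.

    WSS = mu * d(u_tangential)/dn evaluated with a one-sided
    second-order difference using the two fluid cells adjacent to the
    wall, with the no-slip plane half a cell beyond the first fluid cell
    (the bounce-back wall location). Wall columns without two fluid
    neighbours (occluder footprint) are skipped and logged.
    """
    geom = geometry
    dx = geom.lattice_spacing
    occ = geom.occupancy
    ny, nx = occ.shape
    profiles = []
    for wall in walls:
        if wall == "bottom":
            r0, r1 = 1, 2
        elif wall == "top":
            r0, r1 = ny - 2, ny - 3
        else:
            raise DomainError(f"unknown wall {wall!r}")
        xs, taus = [], []
        skipped = 0
        for x in range(nx):
            if occ[r0, x] or occ[r1, x]:
                skipped += 1
                continue
            u0 = snapshot.velocity[r0, x, 0]
            u1 = snapshot.velocity[r1, x, 0]
            # quadratic through (wall: -dx/2, 0), (0, u0), (dx, u1)
            dudn = (3.0 * u0 - u1 / 3.0) / dx
            xs.append((x + 0.5) * dx)
            taus.append(viscosity * dudn)
        if skipped:
            log.info("wall_shear_stress: skipped %d %s-wall columns without "
                     "two fluid neighbours", skipped, wall)
        profiles.append(WSSProfile(np.array(xs), np.array(taus), wall))
    return profiles


def peak_jet_velocity(flow: FlowSeries):
    """Maximum velocity magnitude over all snapshots and fluid cells.

    Returns ``(v_max [m/s], time [s], (y_index, x_index))``.
    """
    if len(flow) == 0:
        raise DomainError("empty flow series")
    best = (0.0, flow.times[0], (0, 0))
    for s in flow.snapshots:
        sp = s.speed()
        v = float(sp.max())
        if v >= best[0]:
            iy, ix = np.unravel_index(int(np.argmax(sp)), sp.shape)
            best = (v, s.time, (int(iy), int(ix)))
    return best


@dataclass
class MetricReport:
    """Summary metrics for one scenario run, reporting units."""

    scenario: str
    pvl_volume_ml_per_beat: Optional[float] = None
    eoa_cm2: Optional[float] = None
    eoa_method: str = "continuity"
    peak_jet_velocity_m_s: Optional[float] = None
    peak_jet_time_s: Optional[float] = None
    wss_max_pa: Optional[float] = None
    plane_fluxes_m3_s: dict = field(default_factory=dict)
    depth_m: Optional[float] = None
    config_hash: Optional[str] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compute_metrics(scenario, flow: FlowSeries,
                    config_hash: Optional[str] = None) -> MetricReport:
    """Standard metric bundle for a scenario: peak jet velocity always;
    EOA at the jet plane when forward flow exists; leak volume at the
    sub-annular AA' plane for constant-drive (diastolic) scenarios."""
    geom = flow.geometry
    planes = {p.label: p for p in scenario.measurement_planes}
    report = MetricReport(scenario=scenario.name, depth_m=geom.depth,
                          config_hash=config_hash)
    v, t, _loc = peak_jet_velocity(flow)
    report.peak_jet_velocity_m_s = v
    report.peak_jet_time_s = float(t)
    last = flow[-1]
    for label, plane in planes.items():
        report.plane_fluxes_m3_s[label] = plane_flux(last, plane, geom)
    jet = planes.get("jet") or planes.get("AA'")
    if jet is not None:
        try:
            report.eoa_cm2 = effective_orifice_area(last, jet, geom)
        except DomainError:
            report.eoa_cm2 = None
    if scenario.constant_pressure_pair_mmhg is not None:
        plane = planes.get("AA'") or jet
        if plane is not None:
            report.pvl_volume_ml_per_beat = pvl_volume(flow, plane, steady=True)
    profiles = wall_shear_stress(last, geom, scenario.fluid.dynamic_viscosity)
    if any(len(p.wss) for p in profiles):
        report.wss_max_pa = float(max(np.abs(p.wss).max()
                                      for p in profiles if len(p.wss)))
    return report
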