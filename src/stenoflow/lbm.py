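"""Laminar Newtonian lattice Boltzmann flow solver (D2Q9, BGK).

The solver advances particle-population distributions f_i(x, t) with the
single-relaxation-time (BGK) collision operator, half-way bounce-back at
solid cells, an optional uniform body force (Guo forcing), and
density-type (Zou-He) pressure boundaries on the inlet and outlet faces:
the downstream pressure is held at the reference value and a
time-dependent pressure difference is applied upstream. Flow is assumed
laminar and the fluid Newtonian.

Lattice-physical unit conversion follows the standard diffusive scaling:
with spacing dx and time step dt, velocities convert by dx/dt, the
lattice kinematic viscosity is c_s^2 (tau - 1/2), and pressure deviations
convert by rho_phys (dx/dt)^2. The collision operator is pluggable
through ``collide``; only BGK ships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .errors import DivergenceError, StabilityError
from .lattice import CS2, D2Q9, LatticeModel
from .scenario import FluidProperties, GeometryMask, ScenarioSpec
from .units import mmhg_to_pa

log = logging.getLogger(__name__)

#: Default lattice Mach number limit: beyond this the second-order
#: equilibrium expansion loses validity and compressibility error grows.
MACH_LIMIT = 0.17


# ---------------------------------------------------------------------------
# unit bookkeeping


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice resolution, time step and relaxation time, with the
    conversion factors between lattice and physical units.

    The relaxation time must exceed 1/2 (linear stability of BGK); the
    derived lattice viscosity c_s^2 (tau - 1/2) maps exactly to the
    physical kinematic viscosity under (spacing, time_step).
    """

    spacing: float
    time_step: float
    relaxation_time: float
    fluid: FluidProperties

    def __post_init__(self) -> None:
        if self.relaxation_time <= 0.5:
            raise StabilityError(
                f"relaxation_time {self.relaxation_time} <= 0.5 is unstable; refused"
            )
        if self.spacing <= 0 or self.time_step <= 0:
            raise StabilityError("spacing and time_step must be positive")

    @property
    def lattice_viscosity(self) -> float:
        return CS2 * (self.relaxation_time - 0.5)

    @property
    def velocity_factor(self) -> float:
        """Physical velocity per unit lattice velocity, m/s."""
        return self.spacing / self.time_step

    @property
    def pressure_factor(self) -> float:
        """Physical pressure per unit lattice density deviation, Pa."""
        return CS2 * self.fluid.fluid_density * self.velocity_factor**2

    @classmethod
    def from_physical(cls, spacing: float, relaxation_time: float,
                      fluid: FluidProperties) -> "LatticeSpec":
        """Choose the time step so the lattice viscosity at the given
        relaxation time reproduces the fluid's kinematic viscosity."""
        nu_lat = CS2 * (relaxation_time - 0.5)
        dt = nu_lat * spacing**2 / fluid.kinematic_viscosity
        return cls(spacing, dt, relaxation_time, fluid)

    @classmethod
    def from_time_step(cls, spacing: float, time_step: float,
                       fluid: FluidProperties) -> "LatticeSpec":
        """Derive the relaxation time from a prescribed time step."""
        nu_lat = fluid.kinematic_viscosity * time_step / spacing**2
        return cls(spacing, time_step, 0.5 + nu_lat / CS2, fluid)


# ---------------------------------------------------------------------------
# kernel operations (lattice units)


def equilibrium_distribution(density: np.ndarray, velocity: np.ndarray,
                             model: LatticeModel = D2Q9,
                             check_mach: bool = False) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium populations.

    ``density`` has shape (...,), ``velocity`` shape (..., d); returns
    populations of shape (q, ...). The zeroth moment equals ``density``
    and the first moment ``density * velocity`` identically.
    """
    rho = np.asarray(density, dtype=float)
    u = np.asarray(velocity, dtype=float)
    if check_mach and np.any(np.linalg.norm(u, axis=-1) > MACH_LIMIT):
        raise StabilityError("velocity exceeds the lattice Mach limit")
    usq = np.sum(u * u, axis=-1)
    feq = np.empty((model.q,) + rho.shape)
    for i in range(model.q):
        cu = np.tensordot(u, model.velocities[i].astype(float), axes=([-1], [0]))
        feq[i] = model.weights[i] * rho * (
            1.0 + cu / CS2 + 0.5 * cu**2 / CS2**2 - 0.5 * usq / CS2
        )
    return feq


def macroscopic_moments(populations: np.ndarray,
                        model: LatticeModel = D2Q9,
                        force: Optional[np.ndarray] = None):
    """Density and velocity from populations.

    density = sum_i f_i; velocity = (sum_i f_i c_i + F/2) / density,
    including the half-force shift when a body force is present.
    """
    f = np.asarray(populations, dtype=float)
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(f))[0]
        raise DivergenceError(f"non-finite population at index {tuple(bad)}")
    rho = f.sum(axis=0)
    if np.any(rho <= 0):
        bad = np.argwhere(rho <= 0)[0]
        raise DivergenceError(f"non-positive density at cell {tuple(bad)}")
    c = model.velocities.astype(float)
    mom = np.tensordot(f, c, axes=([0], [0]))  # (..., d)
    if force is not None:
        mom = mom + 0.5 * np.asarray(force, dtype=float)
    u = mom / rho[..., None]
    return rho, u


@dataclass
class PressureBC:
    """Zou-He density boundaries on the inlet (x=0) and outlet (x=nx-1)
    faces; densities in lattice units."""

    rho_in: float
    rho_out: float = 1.0


@dataclass
class LBMState:
    """Mutable solver state: populations, solid mask, relaxation time,
    optional uniform body force (lattice units), and step counter."""

    f: np.ndarray                     # (q, ny, nx)
    solid: np.ndarray                 # (ny, nx) bool
    relaxation_time: float
    force: Optional[np.ndarray] = None  # (d,) lattice force density
    model: LatticeModel = field(default=D2Q9)
    step_count: int = 0

    @classmethod
    def at_rest(cls, solid: np.ndarray, relaxation_time: float,
                force=None, model: LatticeModel = D2Q9) -> "LBMState":
        rho = np.ones(solid.shape)
        u = np.zeros(solid.shape + (model.ndim,))
        f = equilibrium_distribution(rho, u, model)
        return cls(f=f, solid=np.asarray(solid, bool),
                   relaxation_time=relaxation_time,
                   force=None if force is None else np.asarray(force, float),
                   model=model)

    def moments(self):
        rho, u = macroscopic_moments(self.f, self.model, self.force)
        u = u.copy()
        u[self.solid] = 0.0
        return rho, u

    def fluid_mass(self) -> float:
        return float(self.f.sum(axis=0)[~self.solid].sum())


def bgk_collide(state: LBMState) -> np.ndarray:
    """BGK collision with Guo forcing; returns post-collision populations."""
    model = state.model
    tau = state.relaxation_time
    rho, u = macroscopic_moments(state.f, model, state.force)
    feq = equilibrium_distribution(rho, u, model)
    f_post = state.f - (state.f - feq) / tau
    if state.force is not None:
        F = np.asarray(state.force, dtype=float)
        pref = 1.0 - 0.5 / tau
        for i in range(model.q):
            c = model.velocities[i].astype(float)
            cu = np.tensordot(u, c, axes=([-1], [0]))
            term = (c - u) / CS2 + cu[..., None] * c / CS2**2
            f_post[i] += pref * model.weights[i] * np.tensordot(
                term, F, axes=([-1], [0]))
    return f_post


def step(state: LBMState, bc: Optional[PressureBC] = None,
         collide: Callable[[LBMState], np.ndarray] = bgk_collide) -> LBMState:
    """One collide-stream cycle, in place.

    Collision (default BGK with Guo forcing), periodic streaming, half-way
    bounce-back at solid cells, then Zou-He pressure boundaries if ``bc``
    is given. The collision operator is pluggable.
    """
    model = state.model
    solid = state.solid
    f_post = collide(state)
    f_new = np.empty_like(f_post)
    for i in range(model.q):
        cx, cy = int(model.velocities[i][0]), int(model.velocities[i][1])
        f_new[i] = np.roll(f_post[i], shift=(cy, cx), axis=(0, 1))
    if solid.any():
        fluid = ~solid
        for i in range(model.q):
            cx, cy = int(model.velocities[i][0]), int(model.velocities[i][1])
            from_solid = np.roll(solid, shift=(cy, cx), axis=(0, 1)) & fluid
            f_new[i][from_solid] = f_post[model.opposite[i]][from_solid]
    state.f = f_new
    if bc is not None:
        _apply_pressure_bc(state, bc)
    state.step_count += 1
    return state


def _apply_pressure_bc(state: LBMState, bc: PressureBC) -> None:
    """Zou-He density boundaries on the open inlet/outlet columns.

    Direction indexing (cx, cy): 0:(0,0) 1:(1,0) 2:(0,1) 3:(-1,0)
    4:(0,-1) 5:(1,1) 6:(-1,1) 7:(-1,-1) 8:(1,-1).
    """
    f = state.f
    fluid_in = ~state.solid[:, 0]
    fluid_out = ~state.solid[:, -1]

    # inlet x = 0: unknown f1, f5, f8
    col = f[:, fluid_in, 0]
    rho = bc.rho_in
    ux = 1.0 - (col[0] + col[2] + col[4] + 2.0 * (col[3] + col[6] + col[7])) / rho
    f[1, fluid_in, 0] = col[3] + (2.0 / 3.0) * rho * ux
    f[5, fluid_in, 0] = col[7] - 0.5 * (col[2] - col[4]) + (1.0 / 6.0) * rho * ux
    f[8, fluid_in, 0] = col[6] + 0.5 * (col[2] - col[4]) + (1.0 / 6.0) * rho * ux

    # outlet x = nx-1: unknown f3, f6, f7
    col = f[:, fluid_out, -1]
    rho = bc.rho_out
    ux = -1.0 + (col[0] + col[2] + col[4] + 2.0 * (col[1] + col[5] + col[8])) / rho
    f[3, fluid_out, -1] = col[1] - (2.0 / 3.0) * rho * ux
    f[7, fluid_out, -1] = col[5] + 0.5 * (col[2] - col[4]) - (1.0 / 6.0) * rho * ux
    f[6, fluid_out, -1] = col[8] - 0.5 * (col[2] - col[4]) - (1.0 / 6.0) * rho * ux


# ---------------------------------------------------------------------------
# physical-unit time series


@dataclass
class FlowSnapshot:
    """Velocity/pressure fields at one instant, physical units.

    ``velocity`` has shape (ny, nx, 2) in m/s (zero on solid cells);
    ``pressure`` is the deviation from the outlet reference in Pa.
    """

    time: float
    velocity: np.ndarray
    pressure: np.ndarray

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=-1)


@dataclass
class FlowSeries:
    """Time-ordered flow snapshots with their lattice and geometry."""

    snapshots: List[FlowSnapshot]
    lattice_spec: LatticeSpec
    geometry: GeometryMask

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i) -> FlowSnapshot:
        return self.snapshots[i]

    def at_time(self, t: float) -> FlowSnapshot:
        """Snapshot with time closest to ``t``."""
        return self.snapshots[int(np.argmin(np.abs(self.times - t)))]


def _snapshot(state: LBMState, spec: LatticeSpec, t: float) -> FlowSnapshot:
    rho, u = state.moments()
    vel = u * spec.velocity_factor
    pres = (rho - 1.0) * spec.pressure_factor
    pres = np.where(state.solid, 0.0, pres)
    return FlowSnapshot(time=t, velocity=vel, pressure=pres)


def run_flow(
    scenario: ScenarioSpec,
    duration: Optional[float] = None,
    output_stride: int = 200,
    drive: str = "auto",
    warmup_periods: int = 1,
    steady_tol: Optional[float] = None,
    mach_limit: float = MACH_LIMIT,
    max_steps: Optional[int] = None,
) -> FlowSeries:
    """Simulate a scenario and return its flow series in physical units.

    Drive modes: ``"waveform"`` applies the scenario's time-dependent
    pressure difference upstream (outlet held at reference pressure) and
    discards ``warmup_periods`` cardiac periods as the start-up
    transient; ``"constant"`` applies the diastolic constant pressure
    pair; ``"peak_hold"`` holds the waveform's peak gradient steady
    (frozen systole-peak analysis); ``"auto"`` picks ``"constant"`` when
    the scenario defines a constant pair, else ``"waveform"``.

    If ``steady_tol`` is set, a constant-drive run stops early once the
    relative change of the maximum speed between output frames falls
    below it. Each output frame logs the maximum velocity, the lattice
    Mach number and the mass residual; exceeding ``mach_limit`` aborts
    with advice to refine the lattice.
    """
    geom = scenario.geometry
    fluid = scenario.fluid
    spec = LatticeSpec.from_physical(geom.lattice_spacing,
                                     scenario.relaxation_time, fluid)
    if drive == "auto":
        drive = ("constant" if scenario.constant_pressure_pair_mmhg is not None
                 else "waveform")
    if drive in ("waveform", "peak_hold") and scenario.waveform is None:
        raise StabilityError(f"drive {drive!r} needs a waveform")
    if drive == "constant" and scenario.constant_pressure_pair_mmhg is None:
        raise StabilityError("constant drive needs a constant pressure pair")

    if drive == "waveform":
        period = scenario.waveform.period
        if duration is None:
            duration = period
        if duration < period - 1e-12:
            raise StabilityError("pulsatile runs need duration >= one period")
        t_offset = warmup_periods * period

        def dp_phys(t: float) -> float:
            return scenario.waveform.at(t)
    elif drive == "peak_hold":
        t_offset = 0.0
        peak = scenario.waveform.peak_gradient

        def dp_phys(t: float) -> float:
            return peak
    else:
        t_offset = 0.0
        up, down = scenario.constant_pressure_pair_mmhg
        diff = mmhg_to_pa(up) - mmhg_to_pa(down)

        def dp_phys(t: float) -> float:
            return diff

    if duration is None:
        duration = 0.5  # default steady window
    dt = spec.time_step
    n_total = int(round((t_offset + duration) / dt))
    if max_steps is not None:
        n_total = min(n_total, max_steps)
    n_warm = int(round(t_offset / dt))

    scale = scenario.gradient_scale
    pf = spec.pressure_factor

    state = LBMState.at_rest(geom.occupancy, scenario.relaxation_time)
    mass0 = state.fluid_mass()
    snapshots: List[FlowSnapshot] = []
    prev_max = None
    for k in range(n_total + 1):
        t = k * dt
        if k > 0:
            # upstream density offset realizing the scaled pressure difference
            rho_in = 1.0 + dp_phys(t) * scale / pf
            step(state, PressureBC(rho_in=rho_in, rho_out=1.0))
        if k % output_stride == 0 or k == n_total:
            rho, u = state.moments()
            umax_lat = float(np.abs(u).max())
            if umax_lat > mach_limit:
                raise StabilityError(
                    f"lattice Mach {umax_lat:.3f} exceeds limit {mach_limit} "
                    f"at step {k}; refine the lattice or reduce the drive"
                )
            mass_res = state.fluid_mass() / mass0 - 1.0
            log.info("step %d t=%.4gs max|u|=%.3g m/s Mach=%.3g mass_res=%.2e",
                     k, t, umax_lat * spec.velocity_factor, umax_lat, mass_res)
            if k >= n_warm:
                snapshots.append(_snapshot(state, spec, t - t_offset))
            if steady_tol is not None and drive in ("constant", "peak_hold"):
                if prev_max is not None and umax_lat > 0:
                    if abs(umax_lat - prev_max) <= steady_tol * umax_lat:
                        break
                prev_max = umax_lat
    return FlowSeries(snapshots=snapshots, lattice_spec=spec, geometry=geom)
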