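"""Lagrangian platelet-surrogate transport through a flow series.

Particles are seeded uniformly over an inlet region near the upstream
(aortic) side with a prescribed initial longitudinal velocity, then
advected through the velocity field with either of two coupling modes:

* ``tracer`` — the particle moves with the interpolated fluid velocity
  (euler or rk4 position integration);
* ``stokes_drag`` — the particle carries its own velocity relaxing
  toward the local fluid velocity with the Stokes time
  tau_p = rho_p d^2 / (18 mu), integrated with an exponential
  (exact-relaxation) update that is unconditionally stable for the
  stiff tau_p of micron-scale platelets.

Wall encounters are pure elastic collisions (velocity reflected about
the wall normal, speed preserved); there are no particle-particle
interactions. Along each trajectory the multilinearly interpolated
velocity gradient feeds the shear stress tensor, the scalar stress and
the running stress accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigError, GeometryError
from .footprint import scalar_stress, shear_stress_tensor
from .lbm import FlowSeries, FlowSnapshot
from .scenario import GeometryMask, ParticleProperties

EXIT_IN_FLIGHT = "in_flight"
EXIT_OUTLET = "exited_outlet"
EXIT_MAX_TIME = "max_time"
EXIT_STUCK = "stuck"


@dataclass
class AdvectionConfig:
    """Settings for particle advection.

    ``time_step`` in seconds; ``integrator`` euler|rk4 for the position
    update (tracer mode); ``max_time`` caps a trajectory at one cardiac
    period by default (single passage); ``time_mode`` chooses a frozen
    snapshot (default, index ``frozen_index``) or the full series held
    piecewise-constant between frames.
    """

    time_step: float
    integrator: str = "rk4"
    interpolation: str = "linear"
    max_time: float = 0.8
    rng_seed: int = 0
    time_mode: str = "frozen"       # "frozen" | "series"
    frozen_index: int = -1
    record: str = "endpoint"        # "endpoint" | "full"

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.max_time <= 0:
            raise ConfigError("time_step and max_time must be positive")
        if self.integrator not in ("euler", "rk4"):
            raise ConfigError(f"unknown integrator {self.integrator!r}")
        if self.interpolation != "linear":
            raise ConfigError("only linear interpolation is available")
        if self.time_mode not in ("frozen", "series"):
            raise ConfigError(f"unknown time_mode {self.time_mode!r}")


@dataclass
class ParticleEnsemble:
    """State of n particles: positions/velocities in metres and m/s."""

    positions: np.ndarray           # (n, 2) [x, y]
    velocities: np.ndarray          # (n, 2)
    alive: np.ndarray               # (n,) bool
    exit_reason: np.ndarray         # (n,) str codes

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class ParticleTrajectory:
    """Time-stamped samples along one platelet path.

    Arrays are aligned on the sample axis; ``stress_tensor`` is the 3x3
    embedded viscous stress (Pa), ``scalar_stress`` the invariant sigma
    (Pa), ``running_sa`` the left-Riemann cumulative SA (Pa s).
    """

    times: np.ndarray
    positions: np.ndarray
    fluid_velocity: np.ndarray
    velocity_gradient: np.ndarray   # (n, 2, 2), 1/s
    stress_tensor: np.ndarray       # (n, 3, 3), Pa
    scalar_stress: np.ndarray       # (n,), Pa
    running_sa: np.ndarray          # (n,), Pa s
    integration_step: float
    exit_reason: str = EXIT_IN_FLIGHT

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def stress_accumulation(self) -> float:
        return float(self.running_sa[-1])


# ---------------------------------------------------------------------------
# seeding


def seed_particles(
    n: int,
    geometry: GeometryMask,
    inlet_region: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
    initial_longitudinal_velocity: float = 1.0,
    rng_seed: int = 0,
) -> ParticleEnsemble:
    """Seed ``n`` particles uniformly over an upstream inlet region.

    ``inlet_region`` is ``((x_lo, x_hi), (y_lo, y_hi))`` in metres; by
    default the upstream fluid extension (from two cells past the inlet
    face up to the occluder, full channel height). The region must be
    wholly fluid. Initial velocity is purely longitudinal.
    """
    if n < 1:
        raise ConfigError("need at least one particle")
    dx = geometry.lattice_spacing
    ny, nx = geometry.shape
    if inlet_region is None:
        x_hi = (geometry.occluder_span[0] if geometry.occluder_span
                else nx // 2) * dx
        inlet_region = ((2 * dx, x_hi - dx), (1.5 * dx, (ny - 1.5) * dx))
    (x_lo, x_hi), (y_lo, y_hi) = inlet_region
    # region must be wholly fluid
    ix = slice(int(np.floor(x_lo / dx)), int(np.ceil(x_hi / dx)))
    iy = slice(int(np.floor(y_lo / dx)), int(np.ceil(y_hi / dx)))
    if geometry.occupancy[iy, ix].any():
        raise GeometryError("inlet region intersects solid cells")
    rng = np.random.default_rng(rng_seed)
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(x_lo, x_hi, size=n)
    pos[:, 1] = rng.uniform(y_lo, y_hi, size=n)
    vel = np.zeros((n, 2))
    vel[:, 0] = initial_longitudinal_velocity
    return ParticleEnsemble(
        positions=pos, velocities=vel,
        alive=np.ones(n, dtype=bool),
        exit_reason=np.full(n, EXIT_IN_FLIGHT, dtype=object))


# ---------------------------------------------------------------------------
# interpolation


class FieldInterpolator:
    """Multilinear interpolation of a snapshot's velocity and of its
    central-difference velocity gradient, on cell-centred data."""

    def __init__(self, snapshot: FlowSnapshot, spacing: float):
        self.spacing = spacing
        self.u = snapshot.velocity                      # (ny, nx, 2)
        dx = spacing
        # G[a, b] = du_a / dx_b; axis 0 of the field is y, axis 1 is x
        dudy, dudx = np.gradient(self.u[..., 0], dx, dx)
        dvdy, dvdx = np.gradient(self.u[..., 1], dx, dx)
        self.grad = np.stack(
            [np.stack([dudx, dudy], axis=-1),
             np.stack([dvdx, dvdy], axis=-1)], axis=-2)  # (ny, nx, 2, 2)

    def _weights(self, positions: np.ndarray):
        dx = self.spacing
        ny, nx = self.u.shape[:2]
        fx = np.clip(positions[:, 0] / dx - 0.5, 0.0, nx - 1.000001)
        fy = np.clip(positions[:, 1] / dx - 0.5, 0.0, ny - 1.000001)
        ix, iy = fx.astype(np.intp), fy.astype(np.intp)
        tx, ty = fx - ix, fy - iy
        return ix, iy, tx, ty

    def _interp(self, field: np.ndarray, positions: np.ndarray) -> np.ndarray:
        ix, iy, tx, ty = self._weights(positions)
        tx = tx.reshape((-1,) + (1,) * (field.ndim - 2))
        ty = ty.reshape(tx.shape)
        f00 = field[iy, ix]
        f01 = field[iy, ix + 1]
        f10 = field[iy + 1, ix]
        f11 = field[iy + 1, ix + 1]
        return ((1 - ty) * ((1 - tx) * f00 + tx * f01)
                + ty * ((1 - tx) * f10 + tx * f11))

    def velocity(self, positions: np.ndarray) -> np.ndarray:
        return self._interp(self.u, positions)

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        return self._interp(self.grad, positions)


def interpolate_field(snapshot: FlowSnapshot, position: np.ndarray,
                      spacing: float):
    """Interpolated (fluid_velocity, velocity_gradient) at one or more
    positions; gradient is the central-difference grid gradient
    interpolated to the position."""
    interp = FieldInterpolator(snapshot, spacing)
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    u = interp.velocity(pos)
    g = interp.gradient(pos)
    if np.ndim(position) == 1:
        return u[0], g[0]
    return u, g


# ---------------------------------------------------------------------------
# advection


def _reflect(positions, velocities, proposed, solid, dx):
    """Elastic wall reflection: for particles whose proposed position is
    in a solid cell, reflect the offending coordinate(s) about the cell
    face and flip the matching velocity component. Returns the corrected
    positions, velocities, and a stuck mask."""
    ny, nx = solid.shape

    def in_solid(p):
        ix = np.clip((p[:, 0] / dx).astype(np.intp), 0, nx - 1)
        iy = np.clip((p[:, 1] / dx).astype(np.intp), 0, ny - 1)
        return solid[iy, ix]

    bad = in_solid(proposed)
    if not bad.any():
        return proposed, velocities, np.zeros(len(proposed), bool)
    new_p = proposed.copy()
    new_v = velocities.copy()
    idx = np.nonzero(bad)[0]
    for axis in (0, 1):
        # test whether moving only along this axis enters solid
        trial = positions[idx].copy()
        trial[:, axis] = proposed[idx, axis]
        offending = in_solid(trial)
        for j, k in enumerate(idx):
            if not offending[j]:
                continue
            old_c = positions[k, axis]
            new_c = proposed[k, axis]
            cell_old = int(old_c / dx)
            if new_c > old_c:
                face = (cell_old + 1) * dx
            else:
                face = cell_old * dx
            new_p[k, axis] = 2.0 * face - new_c
            new_v[k, axis] = -new_v[k, axis]
    stuck = in_solid(new_p)
    # leave stuck particles at their previous (fluid) position
    new_p[stuck] = positions[stuck]
    return new_p, new_v, stuck


def advect(
    particles: ParticleEnsemble,
    flow: FlowSeries,
    config: AdvectionConfig,
    particle_props: ParticleProperties,
) -> "AdvectionResult":
    """Advect an ensemble through the flow, recording stress histories.

    A trajectory ends when the particle crosses the outlet face or
    reaches ``config.max_time``. The particle CFL (max fluid speed x
    time_step / spacing) must stay below 1. In ``stokes_drag`` mode the
    particle velocity relaxes exponentially toward the fluid velocity
    with the Stokes time; with platelet-scale properties this is
    indistinguishable from tracer transport.
    """
    geom = flow.geometry
    dx = geom.lattice_spacing
    fluid_props = flow.lattice_spec.fluid
    umax = max(float(s.speed().max()) for s in flow.snapshots)
    cfl = umax * config.time_step / dx
    if cfl >= 1.0:
        raise ConfigError(
            f"particle CFL {cfl:.2f} >= 1; reduce time_step below "
            f"{dx / umax:.3e} s")

    if config.time_mode == "frozen":
        interps = [FieldInterpolator(flow.snapshots[config.frozen_index], dx)]
        frame_of = lambda t: 0
    else:
        interps = [FieldInterpolator(s, dx) for s in flow.snapshots]
        times = flow.times

        def frame_of(t):
            return int(np.searchsorted(times, t, side="right") - 1)

    dt = config.time_step
    n_steps = int(round(config.max_time / dt))
    tau_p = particle_props.relaxation_time(fluid_props)
    mu = fluid_props.dynamic_viscosity
    drag = particle_props.drag_mode == "stokes_drag"
    x_out = (geom.shape[1] - 1) * dx  # outlet face

    pos = particles.positions.copy()
    vel = particles.velocities.copy()
    alive = particles.alive.copy()
    reason = particles.exit_reason.copy()
    n = particles.n

    sa = np.zeros(n)
    end_time = np.zeros(n)
    full = config.record == "full"
    if full:
        hist: List[dict] = []

    def sigma_at(interp, p):
        g = interp.gradient(p)
        tau = shear_stress_tensor(g, mu)
        return g, tau, scalar_stress(tau)

    for k in range(n_steps):
        t = k * dt
        interp = interps[frame_of(t)]
        if not alive.any():
            break
        ia = np.nonzero(alive)[0]
        p = pos[ia]
        g, tau, sig = sigma_at(interp, p)
        # left-Riemann stress accumulation over [t, t+dt)
        sa[ia] += sig * dt
        if full:
            hist.append({"t": t, "idx": ia.copy(), "pos": p.copy(),
                         "u": interp.velocity(p), "grad": g, "tau": tau,
                         "sigma": sig})
        # position update
        if drag:
            u = interp.velocity(p)
            decay = np.exp(-dt / tau_p)
            v = vel[ia]
            disp = u * dt + (v - u) * tau_p * (1.0 - decay)
            new_v = u + (v - u) * decay
            proposed = p + disp
        else:
            if config.integrator == "euler":
                proposed = p + interp.velocity(p) * dt
            else:  # rk4
                k1 = interp.velocity(p)
                k2 = interp.velocity(p + 0.5 * dt * k1)
                k3 = interp.velocity(p + 0.5 * dt * k2)
                k4 = interp.velocity(p + dt * k3)
                proposed = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            new_v = interp.velocity(proposed)
        # inlet face treated as a wall (reflect); outlet face is an exit
        exited = proposed[:, 0] >= x_out
        proposed[:, 0] = np.maximum(proposed[:, 0], 0.0)
        corrected, new_v, stuck = _reflect(p, new_v, proposed,
                                           geom.occupancy, dx)
        pos[ia] = corrected
        vel[ia] = new_v
        t_next = (k + 1) * dt
        for local, kglob in enumerate(ia):
            if exited[local]:
                alive[kglob] = False
                reason[kglob] = EXIT_OUTLET
                end_time[kglob] = t_next
            elif stuck[local]:
                alive[kglob] = False
                reason[kglob] = EXIT_STUCK
                end_time[kglob] = t_next
    still = alive
    reason[still] = EXIT_MAX_TIME
    end_time[still] = n_steps * dt
    alive[:] = False

    trajectories = None
    if full:
        trajectories = _assemble_trajectories(n, hist, dt, reason)
    return AdvectionResult(
        sa=sa, exit_reason=reason, duration=end_time,
        final_positions=pos, final_velocities=vel,
        trajectories=trajectories, config=config)


def _assemble_trajectories(n, hist, dt, reason) -> List[ParticleTrajectory]:
    trajs = []
    for i in range(n):
        rows = [(h["t"], h["pos"][np.searchsorted(h["idx"], i)],
                 h["u"][np.searchsorted(h["idx"], i)],
                 h["grad"][np.searchsorted(h["idx"], i)],
                 h["tau"][np.searchsorted(h["idx"], i)],
                 h["sigma"][np.searchsorted(h["idx"], i)])
                for h in hist if i in h["idx"]]
        if not rows:
            continue
        t, p, u, g, tau, sig = (np.array([r[j] for r in rows])
                                for j in range(6))
        running = np.cumsum(sig * dt)  # left-Riemann over each step interval
        trajs.append(ParticleTrajectory(
            times=t, positions=p, fluid_velocity=u, velocity_gradient=g,
            stress_tensor=tau, scalar_stress=sig, running_sa=running,
            integration_step=dt, exit_reason=str(reason[i])))
    return trajs


@dataclass
class AdvectionResult:
    """Outcome of an advection run: per-particle endpoint SA (Pa s),
    exit reasons, trajectory durations, and optionally full trajectories."""

    sa: np.ndarray
    exit_reason: np.ndarray
    duration: np.ndarray
    final_positions: np.ndarray
    final_velocities: np.ndarray
    config: AdvectionConfig
    trajectories: Optional[List[ParticleTrajectory]] = None

    def counts_by_exit(self) -> dict:
        vals, counts = np.unique(self.exit_reason.astype(str),
                                 return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))
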