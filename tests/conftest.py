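"""Shared fixtures: lattice-unit Poiseuille runs and the comparative
scenario runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stenoflow.footprint import ActivationCriterion, analyze_population
from stenoflow.lattice import CS2
from stenoflow.lbm import LBMState, run_flow, step
from stenoflow.metrics import compute_metrics
from stenoflow.particles import AdvectionConfig, advect, seed_particles
from stenoflow.scenario import make_scenario

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def run_poiseuille(H: int, tau: float = 0.8, a: float = 1e-7,
                   settle_factor: float = 10.0):
    """Body-force-driven periodic channel with ``H`` fluid cells across,
    run to steady state; returns (velocity profile, analytic profile,
    state, force)."""
    nu = CS2 * (tau - 0.5)
    solid = np.zeros((H + 2, 4), dtype=bool)
    solid[0] = True
    solid[-1] = True
    state = LBMState.at_rest(solid, tau, force=np.array([a, 0.0]))
    n_steps = int(settle_factor * H**2 / nu / np.pi**2)
    for _ in range(n_steps):
        step(state)
    _, u = state.moments()
    ux = u[1:-1, 0, 0]
    y = np.arange(H) + 0.5
    analytic = a / (2 * nu) * y * (H - y)
    return ux, analytic, state, a


@pytest.fixture(scope="session")
def poiseuille_33():
    """The 33-cell cross-channel Poiseuille validation run."""
    return run_poiseuille(33)


@pytest.fixture(scope="session")
def poiseuille_errors():
    """Relative L2 profile errors at three resolution doublings."""
    errs = {}
    for H in (16, 32, 64):
        ux, analytic, _, _ = run_poiseuille(H)
        errs[H] = float(np.linalg.norm(ux - analytic)
                        / np.linalg.norm(analytic))
    return errs


def _run_case(preset: str, seed: int, n_particles: int):
    sc = make_scenario(preset, rng_seed=seed)
    drive = "constant" if sc.constant_pressure_pair_mmhg is not None else "peak_hold"
    flow = run_flow(sc, duration=10.0 if drive == "constant" else 8.0,
                    output_stride=1000, drive=drive)
    ens = seed_particles(n_particles, sc.geometry, rng_seed=seed)
    umax = max(float(s.speed().max()) for s in flow.snapshots)
    dt = min(0.2 * sc.geometry.lattice_spacing / umax, 0.08)
    res = advect(ens, flow, AdvectionConfig(time_step=dt, max_time=0.8),
                 sc.particles)
    crit = ActivationCriterion(3.5 * sc.gradient_scale)
    pop = analyze_population(res.sa, criterion=crit, rng_seed=seed)
    report = compute_metrics(sc, flow)
    return {"scenario": sc, "flow": flow, "advection": res,
            "population": pop, "metrics": report}


@pytest.fixture(scope="session")
def comparative_runs():
    """Steady analogue runs of the four comparative presets with a fixed
    seed: stenotic systole-peak jets (CAS_pre, FAS_pre) and diastolic
    leak configurations (CAS_post_pvl, FAS_post_pvl)."""
    return {p: _run_case(p, seed=7, n_particles=4000)
            for p in ("CAS_pre", "FAS_pre", "CAS_post_pvl", "FAS_post_pvl")}
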