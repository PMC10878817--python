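"""Configuration-driven orchestration: scenario -> flow -> particles ->
footprint -> metrics.

A RunConfig (schema-validated, unknown keys rejected) drives the full
chain and writes machine-readable outputs plus a RunRecord with a config
hash and a checksummed file inventory. One global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence`` so each stage can
be re-run in isolation with an identical stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io as sfio
from .errors import ConfigError, StenoflowError
from .footprint import ActivationCriterion, analyze_population
from .lbm import run_flow
from .metrics import compute_metrics
from .particles import AdvectionConfig, advect, seed_particles
from .scenario import ScenarioSpec, make_scenario

log = logging.getLogger(__name__)

_STAGES = ("scenario", "flow", "particles", "footprint", "metrics")


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration: float = 10.0
    output_stride: int = 500
    drive: str = "auto"
    steady_tol: Optional[float] = 1e-5
    warmup_periods: int = 1


class AdvectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_particles: int = 10000
    initial_longitudinal_velocity: float = 1.0
    time_step: Optional[float] = None  # default: CFL 0.2 against the flow
    integrator: str = "rk4"
    max_time: float = 0.8
    time_mode: str = "frozen"


class FootprintSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    #: Activation threshold in Pa s. ``None`` selects Hellum's 3.5 Pa s
    #: multiplied by the scenario's gradient_scale — the dynamic-similarity
    #: image of the physiological threshold at the scaled drive, since
    #: stresses scale linearly with the drive in the laminar regime.
    threshold: Optional[float] = None
    n_bins: int = 64
    bin_scale: str = "log"
    bootstrap_sizes: list = Field(default=[1000, 2500, 5000, 10000])
    n_replicates: int = 1000


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")
    preset: str
    rng_seed: int = 0
    outdir: str = "stenoflow_run"
    solver: SolverSettings = Field(default_factory=SolverSettings)
    advection: AdvectionSettings = Field(default_factory=AdvectionSettings)
    footprint: FootprintSettings = Field(default_factory=FootprintSettings)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the semantically meaningful fields (where outputs go
        and how verbosely we log do not change what is computed)."""
        d = self.model_dump(exclude={"outdir", "log_level"})
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config_hash: str
    software_version: str
    stage_seconds: dict
    inventory: dict              # filename -> sha256
    outdir: str
    results: dict

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds fanned out from the global seed."""
    ss = np.random.SeedSequence(global_seed)
    states = ss.generate_state(len(_STAGES), dtype=np.uint32)
    return {name: int(s) % (2**31) for name, s in zip(_STAGES, states)}


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute scenario -> flow -> particles -> footprint -> metrics.

    Writes the scenario spec, flow series, endpoint-SA population, SA
    PDF, footprint summary and metric report under ``config.outdir``. A
    failure in any stage leaves earlier outputs intact and drops a
    ``FAILED_<stage>.json`` marker before re-raising.
    """
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.rng_seed)
    chash = config.config_hash()
    walls: dict = {}
    results: dict = {}
    stage = "scenario"
    try:
        t0 = time.perf_counter()
        scenario = make_scenario(config.preset, rng_seed=seeds["scenario"])
        (outdir / "scenario.json").write_text(scenario.to_json())
        walls[stage] = time.perf_counter() - t0

        stage = "flow"
        t0 = time.perf_counter()
        s = config.solver
        flow = run_flow(scenario, duration=s.duration,
                        output_stride=s.output_stride, drive=s.drive,
                        steady_tol=s.steady_tol,
                        warmup_periods=s.warmup_periods)
        sfio.write_flow_series(outdir / "flow", flow, scenario)
        walls[stage] = time.perf_counter() - t0

        stage = "particles"
        t0 = time.perf_counter()
        a = config.advection
        ens = seed_particles(
            a.n_particles, scenario.geometry,
            initial_longitudinal_velocity=a.initial_longitudinal_velocity,
            rng_seed=seeds["particles"])
        dt = a.time_step
        if dt is None:
            umax = max(float(s_.speed().max()) for s_ in flow.snapshots)
            dt = 0.2 * scenario.geometry.lattice_spacing / max(umax, 1e-12)
            dt = min(dt, a.max_time / 10.0)
        adv_cfg = AdvectionConfig(
            time_step=dt, integrator=a.integrator, max_time=a.max_time,
            time_mode=a.time_mode, rng_seed=seeds["particles"])
        result = advect(ens, flow, adv_cfg, scenario.particles)
        sfio.write_sa_population(outdir / "sa_population.csv", result.sa,
                                 result.exit_reason)
        (outdir / "particles_manifest.json").write_text(json.dumps({
            "n_particles": a.n_particles,
            "time_step_s": dt,
            "seed": seeds["particles"],
            "counts_by_exit": result.counts_by_exit(),
        }, indent=1, sort_keys=True))
        walls[stage] = time.perf_counter() - t0

        stage = "footprint"
        t0 = time.perf_counter()
        fset = config.footprint
        thr = fset.threshold
        if thr is None:
            thr = 3.5 * scenario.gradient_scale
        crit = ActivationCriterion(threshold=thr)
        pop = analyze_population(
            result.sa, criterion=crit, n_bins=fset.n_bins,
            bin_scale=fset.bin_scale,
            bootstrap_sizes=fset.bootstrap_sizes,
            n_replicates=fset.n_replicates, rng_seed=seeds["footprint"])
        sfio.write_sa_pdf(outdir / "sa_pdf.csv", pop.pdf)
        summary = {
            "threshold_pa_s": thr,
            "activation_fraction": pop.activation_fraction,
            "zero_atom_mass": pop.pdf.zero_atom_mass,
            "pdf_mode_pa_s": None if pop.pdf.degenerate else pop.pdf.mode,
            "regions": None if pop.regions is None else {
                k: asdict(v) for k, v in pop.regions.items()},
            "bootstrap": None if pop.bootstrap is None else asdict(pop.bootstrap),
        }
        (outdir / "footprint_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        results["activation_fraction"] = pop.activation_fraction
        walls[stage] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        report = compute_metrics(scenario, flow, config_hash=chash)
        (outdir / "metrics.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True, default=str))
        results["metrics"] = report.to_dict()
        walls[stage] = time.perf_counter() - t0
    except StenoflowError as exc:
        (outdir / f"FAILED_{stage}.json").write_text(json.dumps(
            {"stage": stage, "error": str(exc)}, indent=1))
        raise

    inventory = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and not p.name.startswith("run_record"):
            inventory[str(p.relative_to(outdir))] = sfio.file_sha256(p)
    record = RunRecord(config_hash=chash, software_version=__version__,
                       stage_seconds=walls, inventory=inventory,
                       outdir=str(outdir), results=results)
    (outdir / "run_record.json").write_text(
        json.dumps(record.to_dict(), indent=1, sort_keys=True))
    return record


def compare_scenarios(config_a: RunConfig, config_b: RunConfig) -> dict:
    """Run two configurations and tabulate their metrics side by side.

    Refuses to compare runs on different lattice spacings or depth
    conventions. Flags the orderings of peak jet velocity, leak volume
    and activation fraction.
    """
    rec_a = run_pipeline(config_a)
    rec_b = run_pipeline(config_b)
    sc_a = make_scenario(config_a.preset)
    sc_b = make_scenario(config_b.preset)
    if not np.isclose(sc_a.geometry.lattice_spacing,
                      sc_b.geometry.lattice_spacing):
        raise ConfigError("comparison refused: lattice spacings differ")
    if not np.isclose(sc_a.geometry.depth, sc_b.geometry.depth):
        raise ConfigError("comparison refused: depth conventions differ")

    def row(rec):
        m = rec.results["metrics"]
        return {
            "eoa_cm2": m.get("eoa_cm2"),
            "peak_jet_velocity_m_s": m.get("peak_jet_velocity_m_s"),
            "pvl_volume_ml_per_beat": m.get("pvl_volume_ml_per_beat"),
            "activation_fraction": rec.results.get("activation_fraction"),
        }

    a, b = row(rec_a), row(rec_b)
    orderings = {}
    for key in a:
        if a[key] is not None and b[key] is not None:
            orderings[key] = (
                f"{config_a.preset} > {config_b.preset}" if a[key] > b[key]
                else f"{config_a.preset} < {config_b.preset}"
                if a[key] < b[key] else "equal")
    comparison = {
        config_a.preset: a, config_b.preset: b,
        "orderings": orderings,
        "config_hashes": [rec_a.config_hash, rec_b.config_hash],
    }
    out = Path(config_a.outdir).parent / "comparison.json"
    out.write_text(json.dumps(comparison, indent=1, sort_keys=True))
    return comparison
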