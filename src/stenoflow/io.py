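"""Writers and readers for run artifacts.

Flow series are written as one legacy-VTK ASCII structured-points file
per snapshot (for inspection in ParaView) plus a compressed ``.npz``
per snapshot (for programmatic reload) and a JSON index manifest
recording times, files, lattice spacing and physical units. Particle,
footprint and metric outputs are plain CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .lbm import FlowSeries, FlowSnapshot, LatticeSpec
from .scenario import FluidProperties, GeometryMask, ScenarioSpec


def write_vtk_structured_points(path, scalars: dict, vectors: dict,
                                spacing: float) -> None:
    """Write 2D cell-centred fields as a legacy-VTK ASCII structured-points
    dataset (one z-layer); field arrays are (ny, nx) or (ny, nx, 2)."""
    any_field = next(iter(scalars.values())) if scalars else next(
        iter(vectors.values()))
    ny, nx = any_field.shape[:2]
    lines = [
        "# vtk DataFile Version 3.0",
        "stenoflow snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
    for name, arr in vectors.items():
        lines.append(f"VECTORS {name} double")
        vec3 = np.concatenate([arr, np.zeros(arr.shape[:2] + (1,))], axis=-1)
        lines.extend(
            " ".join(f"{c:.9g}" for c in np.ravel(row)) for row in vec3)
    Path(path).write_text("\n".join(lines) + "\n")


def write_flow_series(directory, flow: FlowSeries,
                      scenario: Optional[ScenarioSpec] = None) -> dict:
    """Write a flow series (VTK + npz per snapshot, JSON manifest).

    Returns the manifest dict; files land under ``directory``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, snap in enumerate(flow.snapshots):
        vtk = d / f"snapshot_{k:05d}.vtk"
        npz = d / f"snapshot_{k:05d}.npz"
        write_vtk_structured_points(
            vtk, scalars={"pressure": snap.pressure}, vectors={
                "velocity": snap.velocity},
            spacing=flow.lattice_spec.spacing)
        np.savez_compressed(npz, time=snap.time, velocity=snap.velocity,
                            pressure=snap.pressure)
        entries.append({"time": float(snap.time), "vtk": vtk.name,
                        "npz": npz.name})
    spec = flow.lattice_spec
    manifest = {
        "format": "stenoflow-flow-series",
        "version": 1,
        "units": {"velocity": "m/s", "pressure": "Pa", "time": "s",
                  "spacing": "m"},
        "lattice_spec": {
            "spacing": spec.spacing,
            "time_step": spec.time_step,
            "relaxation_time": spec.relaxation_time,
            "dynamic_viscosity": spec.fluid.dynamic_viscosity,
            "fluid_density": spec.fluid.fluid_density,
        },
        "snapshots": entries,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                sort_keys=True))
    if scenario is not None:
        (d / "scenario.json").write_text(scenario.to_json())
    return manifest


def read_flow_series(directory) -> FlowSeries:
    """Reload a flow series written by :func:`write_flow_series`.

    Requires ``scenario.json`` beside the manifest for the geometry.
    """
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    scenario = ScenarioSpec.from_dict(
        json.loads((d / "scenario.json").read_text()))
    ls = manifest["lattice_spec"]
    spec = LatticeSpec(
        spacing=ls["spacing"], time_step=ls["time_step"],
        relaxation_time=ls["relaxation_time"],
        fluid=FluidProperties(ls["dynamic_viscosity"], ls["fluid_density"]))
    snaps = []
    for e in manifest["snapshots"]:
        z = np.load(d / e["npz"])
        snaps.append(FlowSnapshot(time=float(z["time"]),
                                  velocity=z["velocity"],
                                  pressure=z["pressure"]))
    return FlowSeries(snapshots=snaps, lattice_spec=spec,
                      geometry=scenario.geometry)


def write_sa_population(path, sa: np.ndarray, exit_reason) -> None:
    """Endpoint SA per particle as CSV (particle_id, SA [Pa s], exit_reason)."""
    df = pd.DataFrame({
        "particle_id": np.arange(len(sa)),
        "sa_pa_s": sa,
        "exit_reason": np.asarray(exit_reason, dtype=str),
    })
    df.to_csv(path, index=False)


def write_sa_pdf(path, pdf) -> None:
    """SA probability density as CSV (bin_left, bin_right, density)."""
    df = pd.DataFrame({
        "bin_left_pa_s": pdf.bin_edges[:-1],
        "bin_right_pa_s": pdf.bin_edges[1:],
        "density_per_pa_s": pdf.density,
    })
    df.to_csv(path, index=False)


def write_trajectories(path, trajectories) -> None:
    """Long-format trajectory CSV: one row per (particle, sample)."""
    rows = []
    for pid, tr in enumerate(trajectories):
        for k in range(len(tr.times)):
            g = tr.velocity_gradient[k]
            rows.append({
                "particle_id": pid, "t_s": tr.times[k],
                "x_m": tr.positions[k, 0], "y_m": tr.positions[k, 1],
                "ux_m_s": tr.fluid_velocity[k, 0],
                "uy_m_s": tr.fluid_velocity[k, 1],
                "dudx_1_s": g[0, 0], "dudy_1_s": g[0, 1],
                "dvdx_1_s": g[1, 0], "dvdy_1_s": g[1, 1],
                "sigma_pa": tr.scalar_stress[k],
                "sa_pa_s": tr.running_sa[k],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
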