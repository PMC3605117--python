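"""Orchestration of the three-step forward procedure.

Step 1: monodomain solve for v_m on the myometrium.
Step 2: quasi-static volume-conductor solve for the potentials.
Step 3: total currents and Biot–Savart magnetic field at the sensors.
Followed by metric extraction.  Every stage writes its artifacts into the
run directory and the manifest records the configuration hash, package
versions and wall times, so identical configurations reproduce identical
outputs.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__, io, metrics
from .biomagnetics import SensorArray, magnetic_field, mmg_projection, total_current
from .conductivity import TensorField
from .config import RunConfig, save_config
from .fhn import PacemakerSpec
from .fibers import spherical_fiber_direction
from .geometry import Compartment, build_spherical_geometry
from .meshing import four_compartment_mesh, interval_mesh, spherical_shell_mesh
from .monodomain import FieldSeries, assemble_operators, run_monodomain
from .volume_conductor import VolumeConductorSystem

__all__ = ["PipelineResult", "run_pipeline", "calibrate", "build_mesh", "build_tensor_field"]


@dataclass
class PipelineResult:
    outdir: Path
    mesh: object
    v_series: FieldSeries
    phi_series: FieldSeries | None
    mmg: np.ndarray | None  # (T, sensors)
    metrics: dict
    manifest: dict


def build_mesh(config: RunConfig):
    geometry = build_spherical_geometry(config.geometry)
    if config.mesh_dimension == 1:
        mesh = interval_mesh(config.cable_length, config.cable_h)
    elif config.mesh_kind == "shell":
        mesh = spherical_shell_mesh(
            config.geometry.r_myo_inner,
            config.geometry.r_myo_outer,
            config.mesh_subdiv,
            config.mesh_layers[2],
        )
    else:
        mesh = four_compartment_mesh(geometry, config.mesh_subdiv, config.mesh_layers)
    return geometry, mesh


def build_tensor_field(config: RunConfig, sigma_l: float, sigma_t: float) -> TensorField:
    alpha = np.deg2rad(config.fiber_alpha_deg)
    return TensorField(
        lambda r: spherical_fiber_direction(r, alpha), sigma_l, sigma_t
    )


def _build_pacemakers(config: RunConfig) -> list[PacemakerSpec]:
    out = []
    for pm in config.pacemakers:
        if config.mesh_dimension == 1:
            out.append(
                PacemakerSpec.interval(
                    nu=pm.get("nu", 2.0),
                    t_on=pm.get("t_on", 0.0),
                    t_off=pm.get("t_off", 0.1),
                    x_max=pm.get("x_max", 0.05 * config.cable_length),
                )
            )
        else:
            out.append(
                PacemakerSpec.fundus_cap(
                    nu=pm.get("nu", 2.0),
                    t_on=pm.get("t_on", 0.0),
                    t_off=pm.get("t_off", 0.1),
                    r_min=pm.get("r_min", config.geometry.r_myo_inner),
                    r_max=pm.get("r_max", config.geometry.r_myo_outer),
                    z_min=pm.get("z_min", 0.15),
                )
            )
    return out


def _build_sensors(config: RunConfig) -> SensorArray | None:
    s = config.sensors
    if not s:
        return None
    if "file" in s:
        return SensorArray.from_csv(s["file"])
    if s.get("kind") == "cap":
        cfg = config.geometry
        return SensorArray.spherical_cap(
            center=cfg.abdomen_offset,
            radius=cfg.r_abdomen * 1.02,
            n=s.get("n", 37),
            axis=s.get("axis", (1.0, 0.0, 0.0)),
            half_angle_deg=s.get("half_angle_deg", 60.0),
        )
    raise ValueError(f"unknown sensor spec {s!r}")


def run_pipeline(config: RunConfig, with_potentials: bool = True) -> PipelineResult:
    """Execute simulate -> potentials -> fields -> metrics, writing a run
    directory.  Fully deterministic for a fixed configuration."""
    rng_seed = int(config.seed)
    np.random.seed(rng_seed % 2**31)  # no stage draws randomness; recorded anyway
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "uterosim",
        "version": __version__,
        "python": platform.python_version(),
        "config_digest": config.digest(),
        "seed": rng_seed,
        "stages": {},
    }
    save_config(config, outdir / "config.yaml")
    stage_t0 = time.perf_counter()

    cm = config.conductivity_model()
    geometry, mesh = build_mesh(config)
    manifest["stages"]["mesh"] = {
        "nodes": mesh.num_nodes,
        "cells": mesh.num_cells,
        "wall_s": round(time.perf_counter() - stage_t0, 3),
    }

    # --- step 1: monodomain -------------------------------------------
    t0 = time.perf_counter()
    pacemakers = _build_pacemakers(config)
    if config.mesh_dimension == 1:
        m_mesh, m_nodes = mesh, np.arange(mesh.num_nodes)
        cond = cm.sigma_el
        tensor = None
    else:
        m_mesh, m_nodes = (
            mesh.submesh(Compartment.M, with_nodes=True)
            if config.mesh_kind == "full"
            else (mesh, np.arange(mesh.num_nodes))
        )
        tensor = build_tensor_field(config, cm.sigma_el, cm.sigma_et)
        cond = tensor
    ops = assemble_operators(
        m_mesh, cond, cm.varsigma, config.ionic, config.solver.mass_lumping
    )
    v_series, w_series = run_monodomain(
        m_mesh, ops, config.ionic, pacemakers, config.solver
    )
    io.save_field_series(v_series, outdir / "v_m.npz")
    manifest["stages"]["monodomain"] = {
        "steps": int(round(config.solver.t_end / config.solver.dt)),
        "wall_s": round(time.perf_counter() - t0, 3),
    }

    # --- metrics on v_m -----------------------------------------------
    t0 = time.perf_counter()
    times, pct = metrics.contracting_fraction(
        v_series, m_mesh, config.contract_threshold, config.ionic.v_mr
    )
    np.savetxt(
        outdir / "contracting_fraction.csv",
        np.column_stack([times, pct]),
        delimiter=",",
        header="t,contracting_pct",
        comments="",
    )
    if config.mesh_dimension == 1:
        probe_pt = [0.5 * config.cable_length]
    else:
        r_mid = config.geometry.r_myo_outer - 0.5 * config.geometry.wall_thickness
        probe_pt = [r_mid, 0.0, 0.0]  # equator, mid-wall
    trace = v_series.probe(probe_pt)
    wf = metrics.waveform_metrics(v_series.times, trace, config.ionic.v_mr)
    run_metrics: dict = {
        "probe_point": list(np.atleast_1d(probe_pt).astype(float)),
        "waveform": None
        if wf is None
        else {
            "peak_vm_mV": wf.peak_vm * 1e3,
            "plateau_mean_mV": wf.plateau_mean * 1e3,
            "duration_s": wf.duration_s,
        },
        "contracting_peak_pct": float(pct.max()),
    }
    manifest["stages"]["metrics"] = {"wall_s": round(time.perf_counter() - t0, 3)}

    # --- steps 2 & 3: potentials, currents, magnetic field -------------
    phi_series = None
    mmg = None
    if config.mesh_dimension == 3 and config.mesh_kind == "full" and with_potentials:
        t0 = time.perf_counter()
        stride = max(1, int(config.potential_stride))
        idx = np.arange(len(v_series.times) - 1, -1, -stride)[::-1]
        if idx[0] != 0:
            idx = np.concatenate([[0], idx])
        vfull = np.zeros((len(idx), mesh.num_nodes))
        for row, i in enumerate(idx):
            vfull[row, m_nodes] = v_series.values[i]
        sub = FieldSeries(mesh, v_series.times[idx], vfull, "v_m", "V")
        sys_ = VolumeConductorSystem(mesh, cm, tensor, config.geometry.lambda_vernix)
        phis = np.empty_like(vfull)
        for row in range(len(idx)):
            phis[row] = sys_.solve_vm(vfull[row]).phi
        phi_series = FieldSeries(mesh, sub.times, phis, "phi", "V")
        io.save_field_series(phi_series, outdir / "phi.npz")
        manifest["stages"]["potentials"] = {
            "snapshots": len(idx),
            "wall_s": round(time.perf_counter() - t0, 3),
        }

        sensors = _build_sensors(config)
        if sensors is not None:
            t0 = time.perf_counter()
            mmg = np.empty((len(idx), len(sensors)))
            for row in range(len(idx)):
                J = total_current(
                    mesh,
                    vfull[row],
                    phis[row],
                    tensor,
                    cm,
                    config.geometry.lambda_vernix,
                )
                B = magnetic_field(mesh, J, sensors.positions)
                mmg[row] = mmg_projection(B, sensors)
            sensors.to_csv(outdir / "sensors.csv")
            arr = np.column_stack([sub.times, mmg])
            header = "t," + ",".join(f"s{int(i)}" for i in sensors.ids)
            np.savetxt(
                outdir / "mmg.csv", arr, delimiter=",", header=header, comments=""
            )
            run_metrics["mmg_peak_T"] = float(np.abs(mmg).max())
            manifest["stages"]["fields"] = {
                "sensors": len(sensors),
                "wall_s": round(time.perf_counter() - t0, 3),
            }

    with open(outdir / "metrics.json", "w") as f:
        json.dump(run_metrics, f, indent=1)
    manifest["total_wall_s"] = round(time.perf_counter() - stage_t0, 3)
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return PipelineResult(outdir, mesh, v_series, phi_series, mmg, run_metrics, manifest)


def calibrate(config: RunConfig, verbose: bool = True) -> dict:
    """Run the conductivity design chain and report intermediate values.

    The anisotropy ratio is derived from the configured propagation speed;
    if the speed is outside the admissible range a CalibrationError
    propagates, naming the admissible eps1 interval.
    """
    from .conductivity import (
        anisotropy_ratio,
        archie_extracellular,
        grid_conductivities,
    )
    from .fhn import nullcline_fixed_points

    se = archie_extracellular(config.sigma_M, config.p, config.m)
    sel, set_ = grid_conductivities(se, config.myocyte)
    roots = nullcline_fixed_points(config.ionic)
    report = {
        "sigma_e_tilde": se,
        "sigma_el": sel,
        "sigma_et": set_,
        "fixed_point_roots_V": list(roots),
        "a_m": config.ionic.a_m,
    }
    if config.varsigma == "auto":
        vs = anisotropy_ratio(config.speed_c, config.ionic, sel, roots)
        report["varsigma"] = vs
        report["varsigma_source"] = f"calibrated to c = {config.speed_c} m/s"
    else:
        report["varsigma"] = float(config.varsigma)
        report["varsigma_source"] = "configured"
    if verbose:
        for k, v in report.items():
            print(f"{k}: {v}")
    return report
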