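"""YAML run configuration: parsing, validation and round-trip.

A run configuration mirrors the parameter tables of the model: geometry,
ionic constants, myocyte dimensions and Archie's-law inputs, compartment
conductivities and anisotropy ratio, pacemakers, mesh and solver controls.
All values are SI; a few convenience suffixed keys (``*_deg``) accept
degrees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .conductivity import ConductivityModel, design_conductivities
from .params import (
    CompartmentConductivities,
    GeometryConfig,
    IonicParams,
    MyocyteGeometry,
    SolverConfig,
)

__all__ = ["RunConfig", "load_config", "save_config", "default_config_dict"]


@dataclass
class RunConfig:
    geometry: GeometryConfig = dc_field(default_factory=GeometryConfig)
    ionic: IonicParams = dc_field(default_factory=IonicParams)
    myocyte: MyocyteGeometry = dc_field(default_factory=MyocyteGeometry)
    sigma_M: float = 0.5
    p: float = 0.6
    m: float = 4.0 / 3.0
    varsigma: float | str = 0.8  # or "auto" to calibrate from speed_c
    speed_c: float = 0.0115
    compartments: CompartmentConductivities = dc_field(
        default_factory=CompartmentConductivities
    )
    fiber_alpha_deg: float = 45.0
    mesh_dimension: int = 3
    mesh_kind: str = "full"
    mesh_subdiv: int = 2
    mesh_layers: tuple = (3, 2, 2, 2)
    cable_length: float = 0.2
    cable_h: float = 5.0e-4
    pacemakers: list = dc_field(
        default_factory=lambda: [
            {
                "nu": 2.0,
                "t_on": 0.0,
                "t_off": 0.1,
                "r_min": 0.15,
                "r_max": 0.16,
                "z_min": 0.15,
            }
        ]
    )
    solver: SolverConfig = dc_field(
        default_factory=lambda: SolverConfig(dt=0.01, t_end=100.0, output_stride=50)
    )
    potential_stride: int = 10
    sensors: dict = dc_field(
        default_factory=lambda: {"kind": "cap", "n": 37, "half_angle_deg": 60.0}
    )
    contract_threshold: float = -0.04
    outdir: str = "runs/out"
    seed: int = 0

    def conductivity_model(self) -> ConductivityModel:
        vs = None if self.varsigma == "auto" else float(self.varsigma)
        return design_conductivities(
            geom=self.myocyte,
            sigma_M=self.sigma_M,
            p=self.p,
            m=self.m,
            varsigma=vs,
            c=self.speed_c,
            params=self.ionic,
            compartments=self.compartments,
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, (tuple, list)):
                return [enc(v) for v in x]
            if isinstance(x, dict):
                return {k: enc(v) for k, v in x.items()}
            return x

        return {
            "geometry": enc(self.geometry),
            "ionic": enc(self.ionic),
            "myocyte": enc(self.myocyte),
            "conductivity": {
                "sigma_M": self.sigma_M,
                "p": self.p,
                "m": self.m,
                "varsigma": self.varsigma,
                "speed_c": self.speed_c,
                **enc(self.compartments),
            },
            "fiber_alpha_deg": self.fiber_alpha_deg,
            "mesh": {
                "dimension": self.mesh_dimension,
                "kind": self.mesh_kind,
                "subdiv": self.mesh_subdiv,
                "layers": list(self.mesh_layers),
                "cable_length": self.cable_length,
                "cable_h": self.cable_h,
            },
            "pacemakers": enc(self.pacemakers),
            "solver": enc(self.solver),
            "potential_stride": self.potential_stride,
            "sensors": enc(self.sensors),
            "contract_threshold": self.contract_threshold,
            "outdir": self.outdir,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d or {})
        cond = dict(d.get("conductivity", {}))
        meshd = dict(d.get("mesh", {}))
        comp_keys = {k: cond[k] for k in ("G_A", "G_U", "G_F") if k in cond}
        geo = dict(d.get("geometry", {}))
        if "abdomen_offset" in geo:
            geo["abdomen_offset"] = tuple(geo["abdomen_offset"])
        kw: dict[str, Any] = dict(
            geometry=GeometryConfig(**geo),
            ionic=IonicParams(**d.get("ionic", {})),
            myocyte=MyocyteGeometry(**d.get("myocyte", {})),
            sigma_M=cond.get("sigma_M", 0.5),
            p=cond.get("p", 0.6),
            m=cond.get("m", 4.0 / 3.0),
            varsigma=cond.get("varsigma", 0.8),
            speed_c=cond.get("speed_c", 0.0115),
            compartments=CompartmentConductivities(**comp_keys),
            fiber_alpha_deg=d.get("fiber_alpha_deg", 45.0),
            mesh_dimension=meshd.get("dimension", 3),
            mesh_kind=meshd.get("kind", "full"),
            mesh_subdiv=meshd.get("subdiv", 2),
            mesh_layers=tuple(meshd.get("layers", (3, 2, 2, 2))),
            cable_length=meshd.get("cable_length", 0.2),
            cable_h=meshd.get("cable_h", 5.0e-4),
            solver=SolverConfig(**d.get("solver", {})),
            potential_stride=d.get("potential_stride", 10),
            contract_threshold=d.get("contract_threshold", -0.04),
            outdir=d.get("outdir", "runs/out"),
            seed=d.get("seed", 0),
        )
        if "pacemakers" in d:
            kw["pacemakers"] = d["pacemakers"]
        if "sensors" in d:
            kw["sensors"] = d["sensors"]
        return RunConfig(**kw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config_dict() -> dict:
    return RunConfig().to_dict()


def load_config(path) -> RunConfig:
    with open(path) as f:
        return RunConfig.from_dict(yaml.safe_load(f))


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
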