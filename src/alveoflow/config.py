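"""Run configuration: YAML-serializable defaults for the whole workbench.

The defaults reproduce the study's standard settings end to end: the
diameter-based alveolus, 17 pores of Kohn, the square pillar lattice, one
20-µm arteriole opposite one 20-µm venule, 2.3 mm/s inlet velocity,
1,127 Pa outlet pressure, blood density 1,050 kg/m³ and Newtonian 2 cP
viscosity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidGeometryError
from .geometry import ConnectivityConfig, MorphoParams
from .sheetflow import BoundaryConditions, FluidModel


@dataclass
class RunConfig:
    morphology: MorphoParams = field(default_factory=MorphoParams)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    fluid: FluidModel = field(default_factory=FluidModel)
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    target_edge_length: float = 4.0       # µm
    lattice_type: str = "square"
    friction_factor_mode: str = "calibrated"
    vessel_stub_length: float = 100.0     # µm
    seed: int = 11
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        # tuples -> lists for clean YAML round-trips
        return _tuples_to_lists(out)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidGeometryError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, typ in (("morphology", MorphoParams),
                          ("connectivity", ConnectivityConfig),
                          ("fluid", FluidModel), ("bc", BoundaryConditions)):
            if name in data:
                sub = data.pop(name)
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in sub.items()}
                kwargs[name] = typ(**sub)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj
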