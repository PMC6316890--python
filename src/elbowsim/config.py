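"""Study configuration: schema-validated structured text (YAML or JSON).

A study config collects everything one run of the deficiency analysis
needs — geometry parameters (or mesh paths), contact constants, ligament
overrides, drive, solver settings, the scenario list, the output
directory and the seed.  Unknown keys are rejected with the offending key
named, so typos fail loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .contact import ContactParameters
from .geometry import GeometryConfig
from .ligament import SCENARIOS
from .simulate import ExternalLoad, MotionDrive, SimulationConfig

__all__ = ["StudyConfig", "load_config", "config_hash"]


def _from_dict(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed keys: {sorted(allowed)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class StudyConfig:
    """Complete, serialisable description of one deficiency study."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    contact_uh: ContactParameters = field(default_factory=lambda: ContactParameters(kc=126.0))
    contact_rh: ContactParameters = field(default_factory=lambda: ContactParameters(kc=105.0))
    drive: MotionDrive = field(default_factory=MotionDrive)
    loads: ExternalLoad = field(default_factory=ExternalLoad)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stiffness: dict = field(default_factory=dict)      # per-complex ligament k overrides
    pretension: dict = field(default_factory=dict)     # per-complex reference pretension
    scenarios: tuple = ("intact", "MCL_AB_deficient", "MCL_PB_deficient", "both_MCL_deficient")
    out_dir: str = "results"
    seed: int = 1

    def validate(self) -> "StudyConfig":
        self.geometry.validate()
        self.contact_uh.validate()
        self.contact_rh.validate()
        self.sim.validate()
        self.loads.validate()
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}; valid: {sorted(SCENARIOS)}")
        for key in list(self.stiffness) + list(self.pretension):
            if key not in ("MCL_AB", "MCL_PB", "LUCL", "RCL", "annular"):
                raise ValueError(f"unknown ligament complex {key!r} in overrides")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        sub = {
            "geometry": GeometryConfig,
            "contact_uh": ContactParameters,
            "contact_rh": ContactParameters,
            "drive": MotionDrive,
            "loads": ExternalLoad,
            "sim": SimulationConfig,
        }
        parsed = {}
        for key, klass in sub.items():
            if key in data:
                parsed[key] = _from_dict(klass, data.pop(key), f"config.{key}")
        if "scenarios" in data:
            parsed["scenarios"] = tuple(data.pop("scenarios"))
        cfg = _from_dict(cls, {**data, **parsed}, "config")
        return cfg.validate()

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["scenarios"] = list(self.scenarios)
        return out

    def with_seed(self, seed: int) -> "StudyConfig":
        geom = dataclasses.replace(self.geometry, seed=seed)
        return dataclasses.replace(self, geometry=geom, seed=seed)


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML or JSON study configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if data is None:
        data = {}
    return StudyConfig.from_dict(data)


def config_hash(config: StudyConfig) -> str:
    """Short stable digest recorded into every output file set."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
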