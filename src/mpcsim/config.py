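"""Run configuration: one YAML document drives the whole pipeline.

Every parameter block mirrors a module's dataclass; defaults are the
package's study conditions.  A single global seed fans out to per-stage
seeds through ``numpy.random.SeedSequence`` spawning (documented order:
generation, course, voxelize, iodine, quantify, zonate).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import numpy as np
import yaml

from .flow import BoundarySpec, FluidSpec, WallSpec
from .geometry import DEFAULT_ENVELOPE, EnvelopeSpec, GenerationConfig
from .minerals import DepositionParams, SwitchRule
from .phantom import PRESETS, Calibration, ScanPreset, TissueDensities

__all__ = ["RunConfig", "ConfigError", "stage_seeds", "STAGES"]

STAGES = ("generation", "course", "voxelize", "iodine", "quantify", "zonate")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationBlock:
    dt: float = 1.0  # hours
    n_steps: int = 900
    stop_after_interstitial: Optional[float] = 72.0  # hours


@dataclass(frozen=True)
class QuantBlock:
    delta: float = 4000.0  # region-growing tolerance, grayscale units
    density_threshold: float = 300.0  # auto-seed threshold, mg/cc
    use_watershed: bool = False


@dataclass(frozen=True)
class ZonationBlock:
    threshold: Optional[float] = None  # grayscale; None = automatic
    k_max: int = 3
    min_samples: int = 20
    peak_weight_floor: float = 0.05


@dataclass(frozen=True)
class ToleranceBlock:
    """Pass/fail tolerances of the recovery report (relative errors)."""

    vf_rel: float = 0.05
    md_rel: float = 0.02
    diameter_rel: float = 0.10
    tubule_fraction_rel: float = 0.25


@dataclass
class RunConfig:
    envelope: EnvelopeSpec = field(default_factory=lambda: DEFAULT_ENVELOPE)
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    fluid: FluidSpec = field(default_factory=FluidSpec)
    boundary: BoundarySpec = field(default_factory=BoundarySpec)
    wall: WallSpec = field(default_factory=WallSpec)
    mineral: DepositionParams = field(default_factory=DepositionParams)
    switch: SwitchRule = field(default_factory=SwitchRule)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    scan_preset: str = "10X"
    scan_overrides: Dict[str, float] = field(default_factory=dict)
    densities: TissueDensities = field(default_factory=TissueDensities)
    calibration: Calibration = field(default_factory=Calibration)
    quantification: QuantBlock = field(default_factory=QuantBlock)
    zonation: ZonationBlock = field(default_factory=ZonationBlock)
    tolerances: ToleranceBlock = field(default_factory=ToleranceBlock)
    seed: int = 0

    def preset(self) -> ScanPreset:
        if self.scan_preset not in PRESETS:
            raise ConfigError(f"unknown scan preset {self.scan_preset!r}; "
                              f"choose from {sorted(PRESETS)}")
        base = PRESETS[self.scan_preset]
        if self.scan_overrides:
            return dataclasses.replace(base, **self.scan_overrides)
        return base

    # -- serialization ----------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        defaults = cls()

        def build(tp, block, name):
            if block is None:
                return getattr(defaults, name)
            if not isinstance(block, dict):
                raise ConfigError(f"block for {tp.__name__} must be a mapping")
            fields = {f.name for f in dataclasses.fields(tp)}
            unknown = set(block) - fields
            if unknown:
                raise ConfigError(f"unknown keys {sorted(unknown)} in "
                                  f"{tp.__name__} block")
            kwargs = dict(block)
            # YAML round-trips tuples as lists
            for f in dataclasses.fields(tp):
                if f.name in kwargs and isinstance(kwargs[f.name], list):
                    kwargs[f.name] = tuple(kwargs[f.name])
            try:
                return tp(**kwargs)
            except (TypeError, ValueError) as e:
                raise ConfigError(f"invalid {tp.__name__} block: {e}") from e

        known = {
            "envelope": EnvelopeSpec,
            "generation": GenerationConfig,
            "fluid": FluidSpec,
            "boundary": BoundarySpec,
            "wall": WallSpec,
            "mineral": DepositionParams,
            "switch": SwitchRule,
            "simulation": SimulationBlock,
            "densities": TissueDensities,
            "calibration": Calibration,
            "quantification": QuantBlock,
            "zonation": ZonationBlock,
            "tolerances": ToleranceBlock,
        }
        unknown = set(d) - set(known) - {"scan_preset", "scan_overrides", "seed"}
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: Dict[str, Any] = {
            name: build(tp, d.get(name), name) for name, tp in known.items()
        }
        kwargs["scan_preset"] = d.get("scan_preset", "10X")
        kwargs["scan_overrides"] = d.get("scan_overrides", {}) or {}
        kwargs["seed"] = int(d.get("seed", 0))
        cfg = cls(**kwargs)
        cfg.preset()  # validates the preset name
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seeds(seed: int) -> Dict[str, int]:
    """Deterministic per-stage seeds spawned from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }
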