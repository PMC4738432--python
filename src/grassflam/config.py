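"""Run configuration: paths, seed, fit options, fire-model environment, MCMC.

Loaded from YAML (or JSON — YAML is a superset) and hashed so every pipeline
run can record exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RothermelEnv:
    """Environmental and non-measured fuel parameters for spread prediction.

    The moisture of extinction, mineral contents and particle density are not
    plant measurements; defaults are the standard values used with the
    single-fuel-class surface fire model.
    """

    wind_m_s: float = 0.0
    slope_fraction: float = 0.0
    moisture_of_extinction: float = 0.25
    total_mineral_content: float = 0.0555
    effective_mineral_content: float = 0.010
    particle_density_kg_m3: float = 512.6


@dataclass
class BoltzmannOptions:
    r2_threshold: float = 0.95     # lack-of-fit exclusion
    rate_window_s: float = 3.0     # half-window around inflection for max rate
    n_starts: int = 5


@dataclass
class McmcOptions:
    iterations: int = 50_000
    burnin: int = 1_000
    thin: int = 50
    prior_nu: float = 0.002
    prior_v: float = 1.0           # prior scale matrix = prior_nu * prior_v * I


@dataclass
class RunConfig:
    bundle_dir: str = "bundle"
    out_dir: str = "out"
    seed: int = 0
    density_mode: str = "log-linear"    # or "log-log"
    mass_change_def: str = "burned"     # intrinsic-combustibility x: "burned" (A1-A2) or "initial"
    spread_state: str = "fresh"         # which clump state feeds spread prediction
    boltzmann: BoltzmannOptions = field(default_factory=BoltzmannOptions)
    rothermel: RothermelEnv = field(default_factory=RothermelEnv)
    mcmc: McmcOptions = field(default_factory=McmcOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("boltzmann", BoltzmannOptions), ("rothermel", RothermelEnv), ("mcmc", McmcOptions)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
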