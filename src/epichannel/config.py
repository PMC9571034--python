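"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .diagnosis import DEFAULT_VARIANCE_THRESHOLD
from .model import NetworkConfig
from .preprocessing import DenoiseConfig
from .simulate import SimulationConfig


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, reproducibly.

    The network defaults here are the desk-scale settings used for
    synthetic studies (32 hidden units, 12 subjects per group); the
    clinical-scale architecture (200 hidden units) remains the
    :class:`~epichannel.model.NetworkConfig` default and can be requested
    explicitly.
    """

    seed: int = 0
    n_subjects_per_group: int = 12
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    window_s: float = 1.0
    overlap_fraction: float = 0.5
    alpha: float = 0.05
    low_thr: float = 0.20
    high_thr: float = 0.80
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(hidden_units=32)
    )
    n_splits: int = 10
    test_fraction: float = 0.2
    diagnosis_threshold: float = DEFAULT_VARIANCE_THRESHOLD

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "denoise" in kwargs:
            kwargs["denoise"] = DenoiseConfig(**kwargs["denoise"])
        if "network" in kwargs:
            kwargs["network"] = NetworkConfig(**kwargs["network"])
        return cls(**kwargs)
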