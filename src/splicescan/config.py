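"""Run-level configuration: one YAML document covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml

from .cnn_model import ModelSpec, TrainConfig
from .mining import MiningConfig
from .simulator import SimConfig


@dataclass(frozen=True)
class ScanConfig:
    step: int = 1
    min_score: float = 0.0
    min_filter_score: float = 0.5
    nms_radius: int = 0  # 0 disables non-maximum suppression


@dataclass(frozen=True)
class DatasetConfig:
    L: int = 400
    n_per_class: int = 10000
    rebalance_ratio: int = 10
    test_frac: float = 0.10
    val_frac_of_train: float = 0.20
    max_n_fraction: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    data: DatasetConfig = field(default_factory=DatasetConfig)
    model: Optional[ModelSpec] = None  # None: ModelSpec(L=data.L)
    train: TrainConfig = field(default_factory=TrainConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)

    def resolved_model(self) -> ModelSpec:
        return self.model if self.model is not None else ModelSpec(L=self.data.L)

    def to_yaml(self, path=None) -> str:
        data = {
            "seed": self.seed,
            "sim": yaml.safe_load(self.sim.to_yaml()),
            "data": asdict(self.data),
            "model": None if self.model is None else asdict(self.model),
            "train": asdict(self.train),
            "mining": _mining_to_dict(self.mining),
            "scan": asdict(self.scan),
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" not in text and len(text) < 4096:
                with open(text) as handle:
                    data = yaml.safe_load(handle)
            else:
                data = yaml.safe_load(text)
        kwargs = {"seed": data.get("seed", 0)}
        if "sim" in data:
            kwargs["sim"] = SimConfig.from_yaml(yaml.safe_dump(data["sim"]))
        if "data" in data:
            kwargs["data"] = DatasetConfig(**data["data"])
        if data.get("model") is not None:
            kwargs["model"] = ModelSpec(**data["model"])
        if "train" in data:
            kwargs["train"] = TrainConfig(**data["train"])
        if "mining" in data:
            mining = dict(data["mining"])
            if "train" in mining:
                mining["train"] = TrainConfig(**mining["train"])
            kwargs["mining"] = MiningConfig(**mining)
        if "scan" in data:
            kwargs["scan"] = ScanConfig(**data["scan"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _mining_to_dict(mining: MiningConfig) -> dict:
    out = {f.name: getattr(mining, f.name) for f in fields(mining)}
    out["train"] = asdict(mining.train)
    return out


def provenance_record(config, seed: int, command: str) -> dict:
    from . import __version__

    if isinstance(config, RunConfig):
        digest = config.config_hash()
    else:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
    return {
        "command": command,
        "seed": seed,
        "config_hash": digest,
        "splicescan_version": __version__,
    }
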