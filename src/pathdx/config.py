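"""YAML-backed pipeline configuration.

Sections mirror the pipeline stages::

    encoder:   name, dimension, vocab_size, seed, separator
    weighting: enabled, type_multipliers (TUI -> factor)
    sgin:      layers, include_in_neighbors
    ranker:    kind (multiattn|triattn), heads, hidden, aggregate, top_n, max_hops
    training:  epochs, lr, batch_size, margin, negatives_per_anchor,
               label_mode, val_fraction, seed
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .training import TrainConfig


@dataclass
class EncoderConfig:
    name: str = "toy"          # "toy" or "sapbert"
    dimension: int = 16
    vocab_size: int = 512
    seed: int = 0
    separator: str = "[SEP]"


@dataclass
class WeightingConfig:
    enabled: bool = False
    type_multipliers: dict[str, float] = field(default_factory=dict)


@dataclass
class SginConfig:
    layers: int = 2
    include_in_neighbors: bool = False


@dataclass
class RankerConfig:
    kind: str = "triattn"
    heads: int = 4
    hidden: int | None = None
    aggregate: str = "sum"
    top_n: int = 4
    max_hops: int = 2


@dataclass
class PipelineConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    weighting: WeightingConfig = field(default_factory=WeightingConfig)
    sgin: SginConfig = field(default_factory=SginConfig)
    ranker: RankerConfig = field(default_factory=RankerConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, payload in raw.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            for key, value in (payload or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(target, key, value)
        # keep the training hop settings in sync with the ranker section
        cfg.training.top_n = cfg.ranker.top_n
        cfg.training.max_hops = cfg.ranker.max_hops
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def make_encoder(cfg: EncoderConfig):
    """Instantiate the configured text encoder."""
    if cfg.name == "toy":
        from .synth import ToyEncoder

        return ToyEncoder(vocab_size=cfg.vocab_size, dimension=cfg.dimension,
                          seed=cfg.seed)
    if cfg.name == "sapbert":
        from .encoding import SapBertEncoder

        return SapBertEncoder()
    raise ValueError(f"unknown encoder {cfg.name!r}")
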