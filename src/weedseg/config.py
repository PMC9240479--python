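"""Run configuration: YAML file -> validated nested config with defaults.

Unknown keys are rejected by name; ablation presets expand to the
``use_se`` / ``enable_fusion`` flag pairs:

========================  =======  =============
preset                    use_se   enable_fusion
========================  =======  =============
``unet``                  off      off
``unet_se``               on       off
``unet_structure``        off      on
``unet_se_structure``     on       on
========================  =======  =============

One global ``seed`` governs scene generation, the dataset split,
augmentation, and weight initialization through derived sub-seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .augment import AugmentPolicy
from .training import TrainConfig


class ConfigError(ValueError):
    pass


PRESETS = {
    "unet": (False, False),
    "unet_se": (True, False),
    "unet_structure": (False, True),
    "unet_se_structure": (True, True),
}


@dataclass
class ModelConfig:
    backbone: str = "resnet34"
    use_se: bool = True
    enable_fusion: bool = True
    se_reduction: int = 16
    fusion_channels: int = 16
    input_size: int = 512

    def __post_init__(self):
        if self.backbone != "resnet34":
            raise ConfigError(f"unsupported backbone: {self.backbone!r}")


@dataclass
class ExtractConfig:
    dilate_size: int = 5
    dilate_shape: str = "square"
    min_area: int = 64


@dataclass
class DataConfig:
    root: str = "data"
    split: tuple = (6.0 / 7.0, 2.0 / 21.0, 1.0 / 21.0)


@dataclass
class RunConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    extract: ExtractConfig = field(default_factory=ExtractConfig)

    def sub_seed(self, stage: str) -> int:
        """Derive a stage-specific seed (< 2**31) from the global seed."""
        import zlib
        h = np.random.default_rng([self.seed, zlib.crc32(stage.encode())])
        return int(h.integers(0, 2 ** 31 - 1))


def _build(cls, block: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{where}': {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in block:
            val = block[f.name]
            if f.name in ("split", "crop_range", "rotation_range", "blur_kernels") \
                    and isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in '{where}': {exc}") from exc


def parse_config(doc: dict | None) -> RunConfig:
    """Validate a parsed YAML document into a RunConfig."""
    doc = dict(doc or {})
    preset = doc.pop("preset", None)
    known_blocks = {"seed", "data", "model", "train", "augment", "extract"}
    unknown = set(doc) - known_blocks
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    model_block = dict(doc.get("model") or {})
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        use_se, fusion = PRESETS[preset]
        model_block.setdefault("use_se", use_se)
        model_block.setdefault("enable_fusion", fusion)
    cfg = RunConfig(
        seed=int(doc.get("seed", 0)),
        data=_build(DataConfig, dict(doc.get("data") or {}), "data"),
        model=_build(ModelConfig, model_block, "model"),
        train=_build(TrainConfig, dict(doc.get("train") or {}), "train"),
        augment=_build(AugmentPolicy, dict(doc.get("augment") or {}), "augment"),
        extract=_build(ExtractConfig, dict(doc.get("extract") or {}), "extract"),
    )
    return cfg


def load_config(path) -> RunConfig:
    """Read and validate a YAML run-configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config file must contain a mapping")
    return parse_config(doc)
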