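"""YAML configuration loading for the command-line workflows.

A config file may carry four blocks, all optional:

.. code-block:: yaml

    generator:            # synthetic scene generation
      n: 360
      canvas_size: 64
      marginal_scale: 2.5
      pair_strength: 0.75
    backbone:             # network profile
      profile: desk       # or "full", or explicit fields
    train:                # TrainConfig fields
      epochs: 6
      lambda_pair: 0.4
    holdout_pairs: [[0, 6], [1, 4], [2, 7], [3, 5]]
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .model import TrainConfig

__all__ = ["load_config", "backbone_from_config", "train_config_from_config"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def backbone_from_config(cfg: dict) -> BackboneConfig:
    block = dict(cfg.get("backbone", {}))
    profile = block.pop("profile", "desk")
    base = BackboneConfig.full() if profile == "full" else BackboneConfig.desk()
    if not block:
        return base
    fields = {k: getattr(base, k) for k in (
        "profile", "stage_channels", "embed_dim", "n_heads", "n_layers",
        "canvas", "ff_mult", "avgpool_smoothing",
    )}
    fields.update(block)
    if isinstance(fields["stage_channels"], list):
        fields["stage_channels"] = tuple(fields["stage_channels"])
    return BackboneConfig(**fields)


def train_config_from_config(cfg: dict, seed: int | None = None) -> TrainConfig:
    block = dict(cfg.get("train", {}))
    if seed is not None:
        block["seed"] = seed
    return TrainConfig(**block)
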