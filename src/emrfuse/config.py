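"""Configuration dataclasses and named size profiles.

Two profiles are shipped:

* ``paper`` — the full-size configuration (12 transformer layers,
  300-dimensional static-note embedding), sized for a GPU workstation;
* ``desk`` — a reduced configuration (2 transformer layers, model width
  64) that trains on a single CPU core; used by the test-bench
  experiments.

Both keep the 300-dimensional static-note document embedding and the
30-day horizon with 3-day windows (10 subsequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

MODALITIES = ("static_tabular", "static_notes", "temporal_tabular", "temporal_notes")

#: Modality subsets of the dataset-ablation experiments: each subset keeps
#: exactly two of the four modalities.
SUBSETS: dict[str, tuple[str, ...]] = {
    "full": MODALITIES,
    "only_static": ("static_tabular", "static_notes"),
    "only_time_series": ("temporal_tabular", "temporal_notes"),
    "only_tabular": ("static_tabular", "temporal_tabular"),
    "only_notes": ("static_notes", "temporal_notes"),
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the gated multimodal fusion model."""

    d_model: int = 64           # width of temporal representations and Z
    d_note: int = 300           # static-note document embedding dimension
    transformer_layers: int = 2
    transformer_heads: int = 2
    d_ff: int = 128
    memory_len: int | None = None   # None -> tokens-per-window budget
    window_token_budget: int = 18   # max note tokens per 3-day window
    static_token_budget: int = 32   # max static-note tokens
    modality_subset: str = "full"
    primary_static: str = "static_notes"      # or "static_tabular"
    primary_temporal: str = "temporal_notes"  # or "temporal_tabular"
    backtracking: bool = True
    gate_mode: str = "vector"   # or "scalar"

    def __post_init__(self):
        if self.modality_subset not in SUBSETS:
            raise ValueError(f"unknown modality subset '{self.modality_subset}'")
        if self.primary_static not in ("static_notes", "static_tabular"):
            raise ValueError(f"invalid primary_static '{self.primary_static}'")
        if self.primary_temporal not in ("temporal_notes", "temporal_tabular"):
            raise ValueError(f"invalid primary_temporal '{self.primary_temporal}'")
        if self.gate_mode not in ("vector", "scalar"):
            raise ValueError(f"invalid gate_mode '{self.gate_mode}'")

    @property
    def modalities(self) -> tuple[str, ...]:
        return SUBSETS[self.modality_subset]


def model_profile(name: str, **overrides) -> ModelConfig:
    """Named size profiles; ``overrides`` are applied on top."""
    if name == "paper":
        cfg = ModelConfig(d_model=64, d_note=300, transformer_layers=12,
                          transformer_heads=4, d_ff=256,
                          window_token_budget=128, static_token_budget=256)
    elif name == "desk":
        cfg = ModelConfig()
    else:
        raise ValueError(f"unknown profile '{name}' (expected 'paper' or 'desk')")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TrainConfig:
    """Optimisation and evaluation protocol.

    Defaults follow the full-scale protocol (Adam, learning rate 1e-4,
    batch size 64, up to 50 epochs, 8:1:1 stratified split, minimum
    validation loss checkpoint selection, metrics averaged over five
    runs).  Desk-scale experiment helpers override the learning rate and
    epoch count to fit a single CPU core.
    """

    lr: float = 1e-4
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 50
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    task: str = "mortality"           # or "long_stay"
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.task not in ("mortality", "long_stay"):
            raise ValueError(f"unknown task '{self.task}'")


def load_yaml_config(path: str | Path, cls):
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "ratios" in data:
        data["ratios"] = tuple(data["ratios"])
    if "seeds" in data:
        data["seeds"] = tuple(data["seeds"])
    return cls(**data)


def dump_yaml_config(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
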