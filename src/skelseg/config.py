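"""Structured run configuration shared by all CLI subcommands.

Every tunable default named across the pipeline lives here; a YAML file can
override any field, unknown keys are rejected by name, and the whole config
round-trips losslessly.  One global seed expands into per-stage seeds via a
documented derivation so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "derive_seed", "STAGE_OFFSETS"]

# Fixed per-stage offsets for seed derivation; stable across releases.
STAGE_OFFSETS = {
    "phantom": 1,
    "cohort_split": 2,
    "shuffle": 3,
    "orders": 4,
    "training": 5,
    "grid": 6,
}


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministically expand the global seed into a per-stage seed (< 2^31)."""
    try:
        offset = STAGE_OFFSETS[stage]
    except KeyError:
        raise ConfigError(f"unknown seed stage {stage!r}") from None
    return (base_seed * 1000003 + offset) % 2**31


@dataclass
class RunConfig:
    # volume_io
    orientation: str = "as-is"
    # stretcher removal
    binarize_hu: float = 98.0
    dilation_radius: int = 3
    gap: int = 5
    accessory_fraction: float = 0.5
    # preprocessing
    lower_hu: float = 0.0
    upper_hu: float = 300.0
    normalization_mode: str = "A"
    # dataset construction
    n_sets: int = 5
    n_orders: int = 10
    train_fraction: float = 0.85
    # model / training
    f_values: tuple[int, ...] = (2, 4, 8)
    e_values: tuple[int, ...] = (5, 10, 20)
    probability_cut: float = 0.5
    learning_rate: float = 3e-3
    batch_size: int = 4
    input_size: tuple[int, int] = (64, 64)
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("as-is", "rotate90", "rotate180", "rotate270", "flip-lr"):
            raise ConfigError(f"unknown orientation {self.orientation!r}")
        if self.lower_hu >= self.upper_hu:
            raise ConfigError("lower_hu must be < upper_hu")
        if self.normalization_mode not in ("A", "B"):
            raise ConfigError(f"normalization_mode must be 'A' or 'B', got {self.normalization_mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if not 0 <= self.probability_cut <= 1:
            raise ConfigError("probability_cut must be in [0, 1]")
        self.f_values = tuple(self.f_values)
        self.e_values = tuple(self.e_values)
        self.input_size = tuple(self.input_size)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path!r} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["f_values"] = list(self.f_values)
        payload["e_values"] = list(self.e_values)
        payload["input_size"] = list(self.input_size)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def digest(self) -> str:
        """Short stable hash of the full configuration, for run logs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
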