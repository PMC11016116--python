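"""Round-trippable run configuration.

A single flat mapping of every knob exposed by the optimizers, the
binarization and the CV protocol; serializable to YAML so a run can be
reproduced from its manifest alone. CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import ConfigurationError, OptimizerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # optimizer
    algorithm: str = "sma_fbi"
    NP: int = 30
    GEN: int = 300_000
    seed: int = 0
    repeats: int = 30
    gate_a2: bool = True
    vector_draws: bool = True
    z: float = 0.03
    log_base: float = 10.0
    greedy_inspectors: bool = False
    # continuous problem
    function: str = "sphere"
    dim: int = 10
    # gene selection
    alpha: float = 0.95
    beta: float = 0.05
    folds: int = 10
    knn_k: int = 5
    transfer: str = "v"  # "v" | "literal"
    gs_mode: str = "holdout"  # "holdout" | "cv"
    box: float = 4.0

    def optimizer_config(self, seed: int | None = None) -> OptimizerConfig:
        return OptimizerConfig(
            NP=self.NP,
            GEN=self.GEN,
            seed=self.seed if seed is None else seed,
            gate_a2=self.gate_a2,
            vector_draws=self.vector_draws,
            z=self.z,
            log_base=self.log_base,
            greedy_inspectors=self.greedy_inspectors,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a flat mapping")
        return cls.from_dict(raw)
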