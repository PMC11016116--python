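"""Shared population machinery for the optimizers.

Box bounds, candidate solutions, the evaluation budget (the stopping
criterion is a fixed number of objective assessments, not iterations),
global-best tracking, and convergence traces. Every optimizer in the
package is built on these primitives so that budget accounting and
reproducibility are handled in exactly one place.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "BoundsError",
    "ConfigurationError",
    "BudgetExhausted",
    "Bounds",
    "Candidate",
    "OptimizerConfig",
    "Budget",
    "BestTracker",
    "Trace",
    "RunResult",
    "initialize_population",
    "clip_to_bounds",
    "evaluate",
    "greedy_replace",
]


class ConfigurationError(ValueError):
    """Invalid optimizer configuration (group size, budget, flags)."""


class BoundsError(ValueError):
    """Degenerate or inconsistent search-space bounds."""


class BudgetExhausted(RuntimeError):
    """Raised by :class:`Budget` when the evaluation budget is spent.

    Orchestrators catch this to terminate a run cleanly mid-phase.
    """


@dataclass(frozen=True)
class Bounds:
    """Box constraints of a D-dimensional continuous search space."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.lb, dtype=float)
        ub = np.asarray(self.ub, dtype=float)
        if lb.ndim != 1 or ub.ndim != 1 or lb.shape != ub.shape:
            raise BoundsError("lb and ub must be 1-D arrays of equal length")
        if lb.size == 0:
            raise BoundsError("bounds must have at least one dimension")
        if not np.all(np.isfinite(lb)) or not np.all(np.isfinite(ub)):
            raise BoundsError("bounds must be finite")
        if not np.all(lb < ub):
            bad = int(np.argmin(ub - lb))
            raise BoundsError(
                f"lb must be strictly below ub in every dimension "
                f"(violated at dimension {bad}: lb={lb[bad]}, ub={ub[bad]})"
            )
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def D(self) -> int:
        return int(self.lb.size)

    @classmethod
    def cube(cls, lo: float, hi: float, D: int) -> "Bounds":
        """Symmetric box ``[lo, hi]^D``."""
        if D < 1:
            raise BoundsError("dimension count must be positive")
        return cls(np.full(D, float(lo)), np.full(D, float(hi)))


@dataclass
class Candidate:
    """A position in the search space with a cached objective value.

    ``value is None`` marks the candidate as not yet evaluated.
    """

    position: np.ndarray
    value: Optional[float] = None

    @property
    def evaluated(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class OptimizerConfig:
    """Run configuration shared by every optimizer.

    NP is the size of each group (the hybrid replicates the initial
    sample into up to three groups of NP). GEN is the total budget of
    objective evaluations. One RNG stream per run is seeded from
    ``seed``; all stochastic draws consume it in a fixed order.
    """

    NP: int = 30
    GEN: int = 300_000
    seed: int = 0
    minimize: bool = True
    gate_a2: bool = True  # apply step A2 only when Prob_i < uniform draw
    vector_draws: bool = True  # random multipliers drawn per dimension
    z: float = 0.03  # slime-mould restart probability
    log_base: float = 10.0  # logarithm base in the weight formula
    greedy_inspectors: bool = False  # inspector phase replaces unconditionally

    def __post_init__(self) -> None:
        if self.NP < 4:
            raise ConfigurationError(
                "NP must be at least 4 (investigation steps draw 3 distinct peers)"
            )
        if self.GEN < self.NP:
            raise ConfigurationError("GEN must allow at least one full initial evaluation")
        if not (0.0 <= self.z <= 1.0):
            raise ConfigurationError("z must lie in [0, 1]")
        if self.log_base <= 1.0:
            raise ConfigurationError("log_base must exceed 1")
        if not self.minimize:
            raise ConfigurationError("only minimization is supported")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Budget:
    """Counter of objective evaluations with per-phase tallies."""

    def __init__(self, limit: int):
        if limit < 1:
            raise ConfigurationError("evaluation budget must be positive")
        self.limit = int(limit)
        self.used = 0
        self.by_phase: dict[str, int] = {}

    @property
    def remaining(self) -> int:
        return self.limit - self.used

    def spend(self, phase: str = "eval") -> None:
        if self.used >= self.limit:
            raise BudgetExhausted(f"evaluation budget of {self.limit} exhausted")
        self.used += 1
        self.by_phase[phase] = self.by_phase.get(phase, 0) + 1


class BestTracker:
    """Global best (position, value) over everything ever evaluated."""

    def __init__(self) -> None:
        self.best_position: Optional[np.ndarray] = None
        self.best_value: float = math.inf

    def offer(self, position: np.ndarray, value: float) -> bool:
        """Offer an evaluated point; returns True when it improves the best."""
        if value < self.best_value:
            self.best_value = float(value)
            self.best_position = np.array(position, dtype=float, copy=True)
            return True
        return False


@dataclass
class Trace:
    """Evaluation-indexed convergence trace (evaluations_used, best_value)."""

    records: list = field(default_factory=list)

    def append(self, evaluations_used: int, best_value: float) -> None:
        if self.records:
            last_e, last_v = self.records[-1]
            if evaluations_used <= last_e:
                return  # no evaluations since last record
            if best_value > last_v:
                raise ValueError("best value must be non-increasing along a trace")
        self.records.append((int(evaluations_used), float(best_value)))

    @property
    def best_value(self) -> float:
        return min(v for _, v in self.records)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.records, columns=["evaluations", "best_value"]).to_csv(
            path, index=False
        )


@dataclass
class RunResult:
    """Outcome of a single optimizer run."""

    best_position: np.ndarray
    best_value: float
    trace: Trace
    seed: int
    config: dict
    evaluations: int
    eval_counts: dict
    iterations: int

    def to_dict(self) -> dict:
        return {
            "best_position": np.asarray(self.best_position, dtype=float).tolist(),
            "best_value": float(self.best_value),
            "trace": [[int(e), float(v)] for e, v in self.trace.records],
            "seed": int(self.seed),
            "config": self.config,
            "evaluations": int(self.evaluations),
            "eval_counts": dict(self.eval_counts),
            "iterations": int(self.iterations),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def initialize_population(bounds: Bounds, NP: int, rng: np.random.Generator) -> list:
    """Draw NP candidates uniformly inside the box; all unevaluated."""
    if NP < 4:
        raise ConfigurationError("NP must be at least 4")
    positions = rng.uniform(bounds.lb, bounds.ub, size=(NP, bounds.D))
    return [Candidate(positions[i].copy()) for i in range(NP)]


def clip_to_bounds(position: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Coordinate-wise clipping to the box. Idempotent."""
    position = np.asarray(position, dtype=float)
    if position.shape != (bounds.D,):
        raise ValueError(
            f"position has shape {position.shape}, expected ({bounds.D},)"
        )
    return np.clip(position, bounds.lb, bounds.ub)


def evaluate(
    candidate: Candidate,
    objective: Callable[[np.ndarray], float],
    budget: Budget,
    tracker: Optional[BestTracker] = None,
    phase: str = "eval",
) -> float:
    """Evaluate a candidate, spending one budget unit.

    Non-finite objective values are recorded as +inf so they can never
    become the global best.
    """
    budget.spend(phase)
    value = float(objective(candidate.position))
    if not math.isfinite(value):
        value = math.inf
    candidate.value = value
    if tracker is not None:
        tracker.offer(candidate.position, value)
    return value


def greedy_replace(current: Candidate, proposal: Candidate) -> Candidate:
    """Keep the candidate with the lower objective value; ties keep current."""
    if not current.evaluated or not proposal.evaluated:
        raise ValueError("greedy replacement requires both candidates evaluated")
    return proposal if proposal.value < current.value else current
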