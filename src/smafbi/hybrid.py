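"""Hybrid orchestrator: investigation and pursuit teams plus a
slime-mould "inspector" group sharing one global best and one budget.

The hybrid keeps the two forensic-investigation groups exactly as in the
base optimizer and adds a third group whose members update by the
slime-mould rule. All groups communicate only through the shared global
best position/fitness, so disabling the inspector phase reproduces the
base optimizer bit-for-bit, and running the inspector phase alone gives
the standalone slime-mould optimizer.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .core import (
    BestTracker,
    Bounds,
    Budget,
    BudgetExhausted,
    OptimizerConfig,
    RunResult,
    Trace,
)
from .fbi import investigation_phase, pursuit_phase
from .sma import inspector_phase

__all__ = ["run_sma_fbi", "run_fbi", "run_sma", "run_optimizer", "OPTIMIZERS"]

_FBI_PHASES = ("investigation", "pursuit")
_ALL_PHASES = ("investigation", "pursuit", "inspector")


def _run(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: OptimizerConfig,
    phases: Sequence[str],
) -> RunResult:
    rng = np.random.default_rng(config.seed)
    budget = Budget(config.GEN)
    tracker = BestTracker()
    trace = Trace()
    NP, D = config.NP, bounds.D

    # One initial sample, replicated into every enabled group.
    base = rng.uniform(bounds.lb, bounds.ub, size=(NP, D))
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if "investigation" in phases or "pursuit" in phases:
        groups["A"] = (base.copy(), np.full(NP, math.inf))
        groups["B"] = (base.copy(), np.full(NP, math.inf))
    if "inspector" in phases:
        groups["S"] = (base.copy(), np.full(NP, math.inf))

    iterations = 0
    try:
        for name, (pos, val) in groups.items():
            for i in range(NP):
                budget.spend("init")
                v = float(objective(pos[i]))
                if not math.isfinite(v):
                    v = math.inf
                val[i] = v
                tracker.offer(pos[i], v)
        trace.append(budget.used, tracker.best_value)
        while True:
            if "investigation" in phases:
                posA, valA = groups["A"]
                investigation_phase(
                    posA, valA, tracker, bounds, objective, budget, rng, config
                )
                trace.append(budget.used, tracker.best_value)
            if "pursuit" in phases:
                posB, valB = groups["B"]
                pursuit_phase(
                    posB, valB, tracker, bounds, objective, budget, rng, config
                )
                trace.append(budget.used, tracker.best_value)
            if "inspector" in phases:
                posS, valS = groups["S"]
                progress = budget.used / config.GEN
                inspector_phase(
                    posS,
                    valS,
                    tracker,
                    bounds,
                    objective,
                    budget,
                    rng,
                    config,
                    progress,
                )
                trace.append(budget.used, tracker.best_value)
            iterations += 1
    except BudgetExhausted:
        pass  # clean mid-phase truncation
    trace.append(budget.used, tracker.best_value)

    return RunResult(
        best_position=tracker.best_position,
        best_value=tracker.best_value,
        trace=trace,
        seed=config.seed,
        config={**config.to_dict(), "phases": list(phases)},
        evaluations=budget.used,
        eval_counts=dict(budget.by_phase),
        iterations=iterations,
    )


def run_sma_fbi(
    objective,
    bounds: Bounds,
    config: OptimizerConfig,
    *,
    inspector: bool = True,
) -> RunResult:
    """Run the hybrid optimizer (investigation -> pursuit -> inspector).

    ``inspector=False`` disables the third group entirely (ablation):
    the run then equals :func:`run_fbi` on the same seed and config.
    """
    return _run(objective, bounds, config, _ALL_PHASES if inspector else _FBI_PHASES)


def run_fbi(objective, bounds: Bounds, config: OptimizerConfig) -> RunResult:
    """Run the base forensic-investigation optimizer (two groups)."""
    return _run(objective, bounds, config, _FBI_PHASES)


def run_sma(objective, bounds: Bounds, config: OptimizerConfig) -> RunResult:
    """Run the standalone slime-mould optimizer (single group).

    DF is the best fitness seen so far within this run, as there is no
    other group to share with.
    """
    return _run(objective, bounds, config, ("inspector",))


OPTIMIZERS = {
    "sma_fbi": run_sma_fbi,
    "fbi": run_fbi,
    "sma": run_sma,
}


def run_optimizer(name: str, objective, bounds: Bounds, config: OptimizerConfig) -> RunResult:
    """Dispatch by registry name ('sma_fbi', 'fbi' or 'sma')."""
    try:
        fn = OPTIMIZERS[name]
    except KeyError:
        raise KeyError(
            f"unknown optimizer {name!r}; registered: {sorted(OPTIMIZERS)}"
        ) from None
    return fn(objective, bounds, config)
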