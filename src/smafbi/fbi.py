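"""Forensic-based investigation (FBI) search steps.

The optimizer mimics a criminal investigation: an investigation team
(group A) locates the broad region where the "suspect" (optimum) may be,
and a pursuit team (group B) closes in on the most likely location. The
objective value of a position plays the role of the likelihood that the
suspect is there; in this implementation lower objective values mean a
more likely location (minimization).

Step functions operate on a ``(NP, D)`` position matrix and return a
single clipped proposal vector; they draw their peer indices and random
multipliers from the run's RNG stream unless explicitly overridden
(deterministic overrides are the hook the unit oracles use).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    BestTracker,
    Bounds,
    Budget,
    ConfigurationError,
    OptimizerConfig,
    clip_to_bounds,
)

__all__ = [
    "step_a1",
    "selection_prob",
    "step_a2",
    "step_b1",
    "step_b2",
    "investigation_phase",
    "pursuit_phase",
]


def _draw_peers(rng: np.random.Generator, NP: int, exclude: int, count: int) -> tuple:
    """``count`` distinct indices drawn uniformly from {0..NP-1} \\ {exclude}."""
    if NP - 1 < count:
        raise ConfigurationError(
            f"group of size {NP} cannot supply {count} distinct peers"
        )
    drawn = rng.choice(NP - 1, size=count, replace=False)
    return tuple(int(j) if j < exclude else int(j) + 1 for j in drawn)


def _multiplier(rng: np.random.Generator, D: int, vector: bool) -> np.ndarray:
    """A random multiplier in [0,1], per dimension or a shared scalar."""
    if vector:
        return rng.random(D)
    return np.full(D, rng.random())


def step_a1(
    positions: np.ndarray,
    i: int,
    bounds: Bounds,
    rng: np.random.Generator,
    vector_draws: bool = True,
    peers: Optional[tuple] = None,
    r1: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Investigation step A1: move relative to the midpoint of two peers.

    Proposal: ``X_i + (r1 - 0.5)*2 * (X_i - (X_k + X_h)/2)`` where
    ``(r1 - 0.5)*2`` is a random value in [-1, 1].
    """
    NP, D = positions.shape
    if peers is None:
        peers = _draw_peers(rng, NP, i, 2)
    k, h = peers
    if r1 is None:
        r1 = _multiplier(rng, D, vector_draws)
    prop = positions[i] + (np.asarray(r1) - 0.5) * 2.0 * (
        positions[i] - (positions[k] + positions[h]) / 2.0
    )
    return clip_to_bounds(prop, bounds)


def selection_prob(values) -> np.ndarray:
    """Per-member selection probability from objective values.

    ``Prob_i = (p_worst - p_i) / (p_worst - p_best)`` with p_best the
    minimum and p_worst the maximum value (minimization): the best
    member scores 1, the worst 0. All-equal values yield all ones.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("selection_prob requires at least one value")
    finite = np.isfinite(values)
    if not finite.any():
        return np.ones_like(values)
    worst = values[finite].max()
    best = values[finite].min()
    if worst == best:
        # +inf markers (failed evaluations) still rank below the rest
        return np.where(finite, 1.0, 0.0)
    probs = (worst - np.where(finite, values, worst)) / (worst - best)
    return np.where(finite, probs, 0.0)


def step_a2(
    positions: np.ndarray,
    best_position: np.ndarray,
    i: int,
    bounds: Bounds,
    rng: np.random.Generator,
    vector_draws: bool = True,
    peers: Optional[tuple] = None,
    r2: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Investigation step A2: relocate around the best-known position.

    Proposal: ``X_best + X_d + r2 * (X_e - X_f)`` with three distinct
    peers d, e, f. The first two terms are summed literally; the sum can
    leave the box and is repaired by clipping.
    """
    NP, D = positions.shape
    if peers is None:
        peers = _draw_peers(rng, NP, i, 3)
    d, e, f = peers
    if r2 is None:
        r2 = _multiplier(rng, D, vector_draws)
    prop = np.asarray(best_position) + positions[d] + np.asarray(r2) * (
        positions[e] - positions[f]
    )
    return clip_to_bounds(prop, bounds)


def step_b1(
    positions: np.ndarray,
    best_position: np.ndarray,
    i: int,
    bounds: Bounds,
    rng: np.random.Generator,
    vector_draws: bool = True,
    r3: Optional[np.ndarray] = None,
    r4: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pursuit step B1: attraction toward the best-known position.

    Proposal: ``r3 * X_i + r4 * (X_best - X_i)``.
    """
    D = positions.shape[1]
    if r3 is None:
        r3 = _multiplier(rng, D, vector_draws)
    if r4 is None:
        r4 = _multiplier(rng, D, vector_draws)
    prop = np.asarray(r3) * positions[i] + np.asarray(r4) * (
        np.asarray(best_position) - positions[i]
    )
    return clip_to_bounds(prop, bounds)


def step_b2(
    positions: np.ndarray,
    values: np.ndarray,
    best_position: np.ndarray,
    i: int,
    bounds: Bounds,
    rng: np.random.Generator,
    vector_draws: bool = True,
    partner: Optional[int] = None,
    r_pair: Optional[tuple] = None,
) -> np.ndarray:
    """Pursuit step B2: peer interaction during the chase.

    With partner r: when the partner is better (lower value) the member
    moves from the partner's position, ``X_r + r5*(X_r - X_i) +
    r6*(X_best - X_r)``; otherwise from its own, ``X_i + r7*(X_i - X_r)
    + r8*(X_best - X_i)``.
    """
    NP, D = positions.shape
    if NP < 2:
        raise ConfigurationError("step B2 needs at least two pursuers")
    if partner is None:
        (partner,) = _draw_peers(rng, NP, i, 1)
    if r_pair is None:
        ra = _multiplier(rng, D, vector_draws)
        rb = _multiplier(rng, D, vector_draws)
    else:
        ra, rb = (np.asarray(r) for r in r_pair)
    best = np.asarray(best_position)
    if values[partner] < values[i]:
        prop = positions[partner] + ra * (positions[partner] - positions[i]) + rb * (
            best - positions[partner]
        )
    else:
        prop = positions[i] + ra * (positions[i] - positions[partner]) + rb * (
            best - positions[i]
        )
    return clip_to_bounds(prop, bounds)


def _spend_and_eval(position, objective, budget, tracker, phase):
    import math

    budget.spend(phase)
    value = float(objective(position))
    if not math.isfinite(value):
        value = math.inf
    tracker.offer(position, value)
    return value


def investigation_phase(
    positions: np.ndarray,
    values: np.ndarray,
    tracker: BestTracker,
    bounds: Bounds,
    objective,
    budget: Budget,
    rng: np.random.Generator,
    config: OptimizerConfig,
) -> None:
    """One investigation pass over team A: A1, probability gate, A2.

    Each accepted proposal immediately refreshes the shared global best
    (acceptance is greedy: a proposal replaces the member only when it
    strictly improves it). Mutates ``positions``/``values`` in place.
    """
    NP = positions.shape[0]
    for i in range(NP):
        prop = step_a1(positions, i, bounds, rng, config.vector_draws)
        v = _spend_and_eval(prop, objective, budget, tracker, "investigation")
        if v < values[i]:
            positions[i] = prop
            values[i] = v
    probs = selection_prob(values)
    for i in range(NP):
        if config.gate_a2 and not (probs[i] < rng.random()):
            continue  # only low-quality members relocate
        prop = step_a2(positions, tracker.best_position, i, bounds, rng, config.vector_draws)
        v = _spend_and_eval(prop, objective, budget, tracker, "investigation")
        if v < values[i]:
            positions[i] = prop
            values[i] = v


def pursuit_phase(
    positions: np.ndarray,
    values: np.ndarray,
    tracker: BestTracker,
    bounds: Bounds,
    objective,
    budget: Budget,
    rng: np.random.Generator,
    config: OptimizerConfig,
) -> None:
    """One pursuit pass over team B: B1 then B2, both greedy."""
    NP = positions.shape[0]
    for i in range(NP):
        prop = step_b1(positions, tracker.best_position, i, bounds, rng, config.vector_draws)
        v = _spend_and_eval(prop, objective, budget, tracker, "pursuit")
        if v < values[i]:
            positions[i] = prop
            values[i] = v
    for i in range(NP):
        prop = step_b2(
            positions, values, tracker.best_position, i, bounds, rng, config.vector_draws
        )
        v = _spend_and_eval(prop, objective, budget, tracker, "pursuit")
        if v < values[i]:
            positions[i] = prop
            values[i] = v
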