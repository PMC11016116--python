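"""Slime-mould search mechanism.

Models the foraging behaviour of Physarum: the mould approaches food
following odour gradients, wraps promising sources while keeping thin
exploratory branches elsewhere, and oscillates between the two via a
biological oscillator. Mathematically: fitness-ranked weights W steer
members toward good regions, the oscillators vb (range [-a, a], a
shrinking over the run) and vc (range shrinking linearly 1 -> 0) trade
exploration against contraction, and a small restart probability z
re-seeds members uniformly in the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import BestTracker, Bounds, Budget, OptimizerConfig, clip_to_bounds

__all__ = [
    "SmaCoefficients",
    "compute_p",
    "compute_a",
    "sample_vb",
    "sample_vc",
    "compute_weights",
    "sma_update",
    "inspector_phase",
]

DEFAULT_Z = 0.03  # restart probability of the original formulation

# arctanh(1) diverges; the oscillator amplitude argument is clamped just
# below 1 so a run's very first update has a finite (large) half-range.
_A_CLAMP = 1.0 - 1e-12
_P_CLAMP = float(np.nextafter(1.0, 0.0))


@dataclass
class SmaCoefficients:
    """Per-iteration slime-mould quantities for one group of NP members."""

    W: np.ndarray  # (NP, D) weight matrix
    p: np.ndarray  # (NP,) branch thresholds tanh|S(i) - DF|
    a: float  # vb oscillator half-range
    progress: float  # fraction of the evaluation budget consumed
    bF: float  # best fitness this iteration
    wF: float  # worst fitness this iteration
    DF: float  # best fitness over all iterations (shared global best)
    smell_order: np.ndarray  # fitness values sorted ascending
    smell_index: np.ndarray  # permutation: rank -> member index
    z: float = DEFAULT_Z


def compute_p(value: float, DF: float) -> float:
    """Branch threshold ``p = tanh|S(i) - DF|``, in [0, 1).

    tanh saturates to 1.0 in floating point for gaps beyond ~19; the
    result is clamped to the largest double below 1 to keep p < 1.
    """
    if not (math.isfinite(value) and math.isfinite(DF)):
        raise ValueError("p requires finite fitness values")
    return min(math.tanh(abs(value - DF)), _P_CLAMP)


def compute_a(progress: float) -> float:
    """Oscillator half-range ``a = arctanh(1 - progress)``.

    ``progress`` is the consumed fraction of the evaluation budget;
    a is monotone decreasing with a(1) = 0.
    """
    if not (0.0 <= progress <= 1.0):
        raise ValueError("progress must lie in [0, 1]")
    return math.atanh(min(1.0 - progress, _A_CLAMP))


def sample_vb(a: float, D: int, rng: np.random.Generator) -> np.ndarray:
    """Oscillator vb ~ uniform[-a, a] per dimension."""
    if a < 0:
        raise ValueError("a must be non-negative")
    if a == 0.0:
        return np.zeros(D)
    return rng.uniform(-a, a, size=D)


def sample_vc(progress: float, D: int, rng: np.random.Generator) -> np.ndarray:
    """Oscillator vc ~ uniform[-c, c] with c = 1 - progress.

    The half-range declines linearly from one to zero over the run, so
    vc oscillates within [-1, 1] and converges to 0.
    """
    if not (0.0 <= progress <= 1.0):
        raise ValueError("progress must lie in [0, 1]")
    c = 1.0 - progress
    if c == 0.0:
        return np.zeros(D)
    return rng.uniform(-c, c, size=D)


def compute_weights(
    values,
    D: int,
    rng: np.random.Generator,
    log_base: float = 10.0,
) -> SmaCoefficients:
    """Fitness-ranked weight matrix and the iteration's coefficients.

    Members ranked in the superior half (lowest fitness; top ceil(NP/2)
    ranks) receive ``1 + r*log((bF - S)/(bF - wF) + 1)`` per dimension,
    the rest ``1 - r*log(...)``, with r ~ uniform[0,1] drawn per member
    per dimension in rank order. Degenerate iterations (bF == wF) give a
    matrix of exact ones. Only W, ranks and bF/wF are filled here; the
    caller sets p, a, progress and DF.
    """
    values = np.asarray(values, dtype=float)
    NP = values.size
    if NP == 0:
        raise ValueError("weights require at least one fitness value")
    if not np.all(np.isfinite(values)):
        # +inf markers (failed evaluations) rank worst but break the log
        # term; substitute the worst finite value for weighting purposes.
        finite = values[np.isfinite(values)]
        fill = finite.max() if finite.size else 0.0
        values = np.where(np.isfinite(values), values, fill)
    smell_index = np.argsort(values, kind="stable")
    smell_order = values[smell_index]
    bF = float(smell_order[0])
    wF = float(smell_order[-1])
    W = np.ones((NP, D))
    if wF > bF:
        n_superior = math.ceil(NP / 2)
        log_div = math.log(log_base)
        for rank, member in enumerate(smell_index):
            r = rng.random(D)
            term = np.log((bF - smell_order[rank]) / (bF - wF) + 1.0) / log_div
            if rank < n_superior:
                W[member] = 1.0 + r * term
            else:
                W[member] = 1.0 - r * term
    return SmaCoefficients(
        W=W,
        p=np.empty(NP),
        a=0.0,
        progress=0.0,
        bF=bF,
        wF=wF,
        DF=bF,
        smell_order=smell_order,
        smell_index=smell_index,
    )


def sma_update(
    position: np.ndarray,
    p_i: float,
    W_i: np.ndarray,
    Xb: np.ndarray,
    XA: np.ndarray,
    XB: np.ndarray,
    a: float,
    progress: float,
    bounds: Bounds,
    rng: np.random.Generator,
    z: float = DEFAULT_Z,
    return_branch: bool = False,
):
    """Three-branch slime-mould position update; returns a clipped,
    unevaluated proposal.

    Draw order: ``rand`` first (restart gate), then — only when not
    restarting — ``r`` (exploration/contraction gate), then the branch's
    oscillator vector:

    * ``rand < z``      -> fresh uniform position in the box ("restart");
    * ``r < p_i``       -> ``Xb + vb*(W_i*XA - XB)`` ("approach");
    * otherwise         -> ``vc * position`` ("contract").
    """
    D = bounds.D
    if W_i.shape != (D,):
        raise ValueError("weight row does not match the search dimension")
    if rng.random() < z:
        prop = rng.uniform(bounds.lb, bounds.ub)
        branch = "restart"
    elif rng.random() < p_i:
        vb = sample_vb(a, D, rng)
        prop = np.asarray(Xb) + vb * (W_i * np.asarray(XA) - np.asarray(XB))
        branch = "approach"
    else:
        vc = sample_vc(progress, D, rng)
        prop = vc * np.asarray(position)
        branch = "contract"
    prop = clip_to_bounds(prop, bounds)
    if return_branch:
        return prop, branch
    return prop


def inspector_phase(
    positions: np.ndarray,
    values: np.ndarray,
    tracker: BestTracker,
    bounds: Bounds,
    objective,
    budget: Budget,
    rng: np.random.Generator,
    config: OptimizerConfig,
    progress: float,
) -> None:
    """One slime-mould pass over the inspector group.

    Coefficients are rebuilt from the group's current fitness ranking;
    DF and Xb are the run-global best (the groups exchange information
    only through the shared optimum). Replacement is unconditional by
    default, faithful to the original slime-mould update; greedy
    acceptance is available via ``config.greedy_inspectors``.
    """
    NP, D = positions.shape
    coeffs = compute_weights(values, D, rng, config.log_base)
    coeffs.a = compute_a(progress)
    coeffs.progress = progress
    coeffs.DF = tracker.best_value
    coeffs.z = config.z
    Xb = tracker.best_position
    for i in range(NP):
        p_i = compute_p(values[i] if math.isfinite(values[i]) else coeffs.wF, coeffs.DF)
        ia, ib = int(rng.integers(NP)), int(rng.integers(NP))
        prop = sma_update(
            positions[i],
            p_i,
            coeffs.W[i],
            Xb,
            positions[ia],
            positions[ib],
            coeffs.a,
            progress,
            bounds,
            rng,
            z=coeffs.z,
        )
        budget.spend("inspector")
        v = float(objective(prop))
        if not math.isfinite(v):
            v = math.inf
        tracker.offer(prop, v)
        if config.greedy_inspectors and v >= values[i]:
            continue
        positions[i] = prop
        values[i] = v
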