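"""Continuous test-function battery with shift/rotation wrappers.

A dimension-generic stand-in battery covering the four categories used
to profile metaheuristics — unimodal (exploitation), multimodal
(exploration), hybrid-like and composite-like (balance). Every base
function has its global minimum of 0 at the origin (Rosenbrock and Levy
are re-centred), so the shift/rotation wrapper ``f(R(x - s))`` moves the
optimum to ``s`` without changing its value. Users with the official
CEC2017 evaluators can register them through :func:`register_function`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .core import Bounds, ConfigurationError

__all__ = ["FunctionDef", "BATTERY", "make_function", "random_rotation", "register_function"]


@dataclass(frozen=True)
class FunctionDef:
    """A named objective with default bounds and known optimum."""

    name: str
    fn: Callable[[np.ndarray], float]
    default_range: tuple  # (lo, hi) per dimension
    category: str  # unimodal | multimodal | hybrid-like | composite-like
    optimum_value: float = 0.0
    optimum_position: Optional[np.ndarray] = None  # None -> origin

    def bounds(self, D: int) -> Bounds:
        lo, hi = self.default_range
        return Bounds.cube(lo, hi, D)

    def argmin(self, D: int) -> np.ndarray:
        if self.optimum_position is not None:
            return np.asarray(self.optimum_position, dtype=float)
        return np.zeros(D)


def _sphere(x):
    return float(np.sum(x * x))


def _schwefel_222(x):
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _zakharov(x):
    s = 0.5 * np.sum(np.arange(1, x.size + 1) * x)
    return float(np.sum(x * x) + s**2 + s**4)


def _rastrigin(x):
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _ackley(x):
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _griewank(x):
    idx = np.sqrt(np.arange(1, x.size + 1))
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / idx)) + 1.0)


def _rosenbrock0(x):
    # classic Rosenbrock evaluated at x+1 so the argmin sits at the origin
    y = x + 1.0
    return float(np.sum(100.0 * (y[1:] - y[:-1] ** 2) ** 2 + (y[:-1] - 1.0) ** 2))


def _levy0(x):
    # classic Levy evaluated at x+1 so the argmin sits at the origin
    y = x + 1.0
    w = 1.0 + (y - 1.0) / 4.0
    term1 = np.sin(np.pi * w[0]) ** 2
    term3 = (w[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * w[-1]) ** 2)
    mid = np.sum((w[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * w[:-1] + 1.0) ** 2))
    return float(term1 + mid + term3)


def _comp_sphere_rastrigin(x):
    return 0.5 * _sphere(x) + 0.5 * _rastrigin(x)


def _comp_ackley_griewank(x):
    return 0.5 * _ackley(x) + 0.5 * _griewank(x)


BATTERY: dict[str, FunctionDef] = {
    f.name: f
    for f in [
        FunctionDef("sphere", _sphere, (-100.0, 100.0), "unimodal"),
        FunctionDef("schwefel_222", _schwefel_222, (-10.0, 10.0), "unimodal"),
        FunctionDef("zakharov", _zakharov, (-10.0, 10.0), "unimodal"),
        FunctionDef("rastrigin", _rastrigin, (-5.12, 5.12), "multimodal"),
        FunctionDef("ackley", _ackley, (-32.768, 32.768), "multimodal"),
        FunctionDef("griewank", _griewank, (-600.0, 600.0), "multimodal"),
        FunctionDef("rosenbrock", _rosenbrock0, (-30.0, 30.0), "hybrid-like"),
        FunctionDef("levy", _levy0, (-10.0, 10.0), "hybrid-like"),
        FunctionDef(
            "comp_sphere_rastrigin", _comp_sphere_rastrigin, (-5.12, 5.12), "composite-like"
        ),
        FunctionDef(
            "comp_ackley_griewank", _comp_ackley_griewank, (-32.768, 32.768), "composite-like"
        ),
    ]
}


def register_function(fdef: FunctionDef) -> None:
    """Plugin hook: add an external evaluator to the battery."""
    BATTERY[fdef.name] = fdef


def random_rotation(D: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random orthogonal matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((D, D)))
    return q * np.sign(np.diag(r))


def make_function(
    name: str,
    D: int,
    shift: Optional[np.ndarray] = None,
    rotation: Optional[np.ndarray] = None,
) -> FunctionDef:
    """Instantiate a battery function, optionally shifted and rotated.

    The evaluator is ``f(R(x - s))``: the optimum moves to ``s`` and its
    value is unchanged.
    """
    try:
        base = BATTERY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown benchmark function {name!r}; available: {sorted(BATTERY)}"
        ) from None
    s = np.zeros(D) if shift is None else np.asarray(shift, dtype=float)
    if s.shape != (D,):
        raise ConfigurationError("shift vector must have length D")
    if rotation is None:
        R = None
    else:
        R = np.asarray(rotation, dtype=float)
        if R.shape != (D, D) or not np.allclose(R @ R.T, np.eye(D), atol=1e-9):
            raise ConfigurationError("rotation must be an orthogonal DxD matrix")
    inner = base.fn

    if R is None and shift is None:
        fn = inner
    elif R is None:
        fn = lambda x, _s=s: inner(np.asarray(x, dtype=float) - _s)
    else:
        fn = lambda x, _s=s, _R=R: inner(_R @ (np.asarray(x, dtype=float) - _s))

    return FunctionDef(
        name=base.name,
        fn=fn,
        default_range=base.default_range,
        category=base.category,
        optimum_value=base.optimum_value,
        optimum_position=s,
    )
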