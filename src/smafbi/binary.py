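"""Binary gene selection: BSMA_FBI and the wrapper fitness function.

Gene selection is cast as binary optimization: a feature mask over d
genes, scored by ``fitness = alpha * error + beta * l/d`` where ``error``
is the cross-validated misclassification rate of a k-nearest-neighbour
classifier restricted to the selected genes, ``l`` the subset size and
``alpha = 0.95``, ``beta = 0.05`` (classification error matters far more
than parsimony). The continuous hybrid optimizer searches a box in R^d
and each position is mapped to a mask through the V-shaped transfer
function ``T(x) = |tanh x|``: bit_j is set when a uniform draw falls
below T(position_j). This converts the optimizer without touching its
update rules.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .core import Bounds, ConfigurationError, OptimizerConfig
from .hybrid import run_sma_fbi

__all__ = [
    "FeatureMask",
    "FitnessWeights",
    "LabeledDataset",
    "CVPlan",
    "GSRun",
    "GSResult",
    "transfer_v",
    "binarize",
    "literal_threshold_binarize",
    "knn_error_cv",
    "subset_fitness",
    "run_bsma_fbi",
    "run_bfbi",
]

DEFAULT_BOX = 4.0  # |tanh(4)| ~ 0.9993: the transfer saturates at the box edge


@dataclass
class FeatureMask:
    """Binary inclusion vector over d features."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise ValueError("mask must be a 1-D bit vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.bits = bits.astype(np.int8)

    @property
    def l(self) -> int:
        return int(self.bits.sum())

    @property
    def d(self) -> int:
        return int(self.bits.size)

    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the error and subset-size terms; they sum to one."""

    alpha: float = 0.95
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ConfigurationError("alpha + beta must equal 1")


@dataclass
class LabeledDataset:
    """Samples x features expression matrix with class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: Optional[list] = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D samples x features matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("label vector length must equal the sample count")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("single-class data: need at least 2 classes")
        if counts.min() < 2:
            bad = classes[counts.argmin()]
            raise ValueError(
                f"class {bad!r} has fewer than 2 samples; cross-validation infeasible"
            )
        if self.feature_names is not None and len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must equal the feature count")
        self.X = X
        self.y = y

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation protocol for the wrapper fitness."""

    folds: int = 10
    stratified: bool = True
    repeat_runs: int = 10
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("need at least 2 folds")
        if self.repeat_runs < 1:
            raise ConfigurationError("need at least 1 run")


def transfer_v(x):
    """V-shaped transfer function ``T(x) = |tanh x|`` in [0, 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("transfer input must be finite")
    return np.abs(np.tanh(x))


def binarize(position: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """Map a continuous position to a feature mask via the V-transfer.

    ``bit_j = 1`` iff ``u_j < T(position_j)`` with u_j ~ uniform[0,1].
    An all-zero mask is repaired by setting one uniformly chosen bit, so
    the classifier contract (at least one feature) stays total.
    """
    t = transfer_v(position)
    bits = (rng.random(t.size) < t).astype(np.int8)
    if not bits.any():
        bits[rng.integers(t.size)] = 1
    return FeatureMask(bits)


def literal_threshold_binarize(position: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """The raw fixed-0.5-threshold rule (bit from a bare uniform draw).

    As printed it ignores the position entirely, degenerating the search
    to random masks; shipped only for auditability, not used by default.
    """
    position = np.asarray(position, dtype=float)
    bits = (rng.random(position.size) > 0.5).astype(np.int8)
    if not bits.any():
        bits[rng.integers(position.size)] = 1
    return FeatureMask(bits)


def knn_error_cv(
    data: LabeledDataset,
    mask: FeatureMask,
    plan: CVPlan,
    k: int = 5,
) -> float:
    """Mean stratified K-fold misclassification rate of KNN on the
    mask-selected features. Deterministic given ``plan.split_seed``."""
    if mask.l < 1:
        raise ValueError("mask must select at least one feature")
    if mask.d != data.n_features:
        raise ValueError("mask length must equal the feature count")
    _, counts = np.unique(data.y, return_counts=True)
    if plan.stratified and plan.folds > counts.min():
        classes = np.unique(data.y)
        bad = classes[counts.argmin()]
        raise ConfigurationError(
            f"{plan.folds}-fold stratified CV infeasible: class {bad!r} has only "
            f"{counts.min()} samples"
        )
    Xsel = data.X[:, mask.bits.astype(bool)]
    splitter = StratifiedKFold(
        n_splits=plan.folds, shuffle=True, random_state=plan.split_seed
    )
    errors = []
    for train_idx, test_idx in splitter.split(Xsel, data.y):
        clf = KNeighborsClassifier(n_neighbors=k, algorithm="brute")
        clf.fit(Xsel[train_idx], data.y[train_idx])
        pred = clf.predict(Xsel[test_idx])
        errors.append(float(np.mean(pred != data.y[test_idx])))
    return float(np.mean(errors))


def subset_fitness(error: float, l: int, d: int, w: FitnessWeights = FitnessWeights()) -> float:
    """Wrapper fitness ``alpha * error + beta * l/d``, in [0, 1]."""
    if not (0.0 <= error <= 1.0):
        raise ValueError("error rate must lie in [0, 1]")
    if d < 1 or not (0 <= l <= d):
        raise ValueError("subset size must satisfy 0 <= l <= d")
    return w.alpha * error + w.beta * (l / d)


class _MaskRecorder:
    """Tracks the best (fitness, mask, error) seen by the GS objective."""

    def __init__(self) -> None:
        self.best_fitness = math.inf
        self.best_mask: Optional[FeatureMask] = None
        self.best_error = math.nan

    def offer(self, fitness: float, mask: FeatureMask, error: float) -> None:
        if fitness < self.best_fitness:
            self.best_fitness = fitness
            self.best_mask = FeatureMask(mask.bits.copy())
            self.best_error = error


@dataclass
class GSRun:
    """One optimization run of the gene-selection wrapper."""

    seed: int
    best_mask: FeatureMask
    best_fitness: float
    cv_error: float
    reported_error: float
    n_selected: int
    wall_time: float
    trace: list  # (evaluations, best fitness) convergence records


@dataclass
class GSResult:
    """All runs of a gene-selection experiment plus cross-run statistics."""

    runs: list
    weights: FitnessWeights
    plan: CVPlan
    mode: str
    k: int

    def summary(self) -> dict:
        feats = np.array([r.n_selected for r in self.runs], dtype=float)
        errs = np.array([r.reported_error for r in self.runs], dtype=float)
        fits = np.array([r.best_fitness for r in self.runs], dtype=float)
        times = np.array([r.wall_time for r in self.runs], dtype=float)
        sd = lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0
        return {
            "runs": len(self.runs),
            "mean_features": float(feats.mean()),
            "std_features": sd(feats),
            "mean_error": float(errs.mean()),
            "std_error": sd(errs),
            "mean_fitness": float(fits.mean()),
            "std_fitness": sd(fits),
            "mean_time": float(times.mean()),
        }


def _make_objective(fit_data, plan, k, weights, bit_rng, recorder):
    d = fit_data.n_features
    cache: dict[bytes, float] = {}

    def objective(position: np.ndarray) -> float:
        mask = binarize(position, bit_rng)
        key = mask.bits.tobytes()
        error = cache.get(key)
        if error is None:
            error = knn_error_cv(fit_data, mask, plan, k)
            cache[key] = error
        fitness = subset_fitness(error, mask.l, d, weights)
        recorder.offer(fitness, mask, error)
        return fitness

    return objective


def run_bsma_fbi(
    data: LabeledDataset,
    plan: CVPlan = CVPlan(),
    config: Optional[OptimizerConfig] = None,
    weights: FitnessWeights = FitnessWeights(),
    k: int = 5,
    box: float = DEFAULT_BOX,
    mode: str = "holdout",
    test_size: float = 0.2,
    seed: int = 0,
    inspector: bool = True,
) -> GSResult:
    """Wrapper gene selection with the binarized hybrid optimizer.

    Runs the continuous optimizer ``plan.repeat_runs`` times with
    distinct seeds in the box ``[-box, box]^d``; each candidate position
    is binarized and scored by the KNN-CV fitness.

    ``mode``:

    * ``"holdout"`` (default): stratified ``1 - test_size`` / ``test_size``
      outer split; the optimizer's fitness is the K-fold CV error on the
      training portion and the reported error is the held-out error of
      the best mask.
    * ``"cv"``: fitness and reported error are both the K-fold CV error
      on all samples.
    """
    if mode not in ("holdout", "cv"):
        raise ConfigurationError("mode must be 'holdout' or 'cv'")
    d = data.n_features
    if config is None:
        config = OptimizerConfig(NP=20, GEN=100 * 20, seed=0)
    bounds = Bounds.cube(-box, box, d)
    runs = []
    for r in range(plan.repeat_runs):
        run_seed = (seed + r) % (2**31)
        if mode == "holdout":
            idx_train, idx_test = train_test_split(
                np.arange(data.n_samples),
                test_size=test_size,
                stratify=data.y,
                random_state=run_seed,
            )
            fit_data = LabeledDataset(data.X[idx_train], data.y[idx_train])
        else:
            idx_train = idx_test = None
            fit_data = data
        run_plan = CVPlan(
            folds=plan.folds,
            stratified=plan.stratified,
            repeat_runs=1,
            split_seed=run_seed,
        )
        recorder = _MaskRecorder()
        bit_rng = np.random.default_rng((run_seed + 997) % (2**31))
        objective = _make_objective(fit_data, run_plan, k, weights, bit_rng, recorder)
        run_config = OptimizerConfig(
            NP=config.NP,
            GEN=config.GEN,
            seed=run_seed,
            gate_a2=config.gate_a2,
            vector_draws=config.vector_draws,
            z=config.z,
            log_base=config.log_base,
            greedy_inspectors=config.greedy_inspectors,
        )
        t0 = time.perf_counter()
        result = run_sma_fbi(objective, bounds, run_config, inspector=inspector)
        wall = time.perf_counter() - t0
        mask = recorder.best_mask
        if mode == "holdout":
            clf = KNeighborsClassifier(n_neighbors=k, algorithm="brute")
            sel = mask.bits.astype(bool)
            clf.fit(data.X[np.ix_(idx_train, np.flatnonzero(sel))], data.y[idx_train])
            pred = clf.predict(data.X[np.ix_(idx_test, np.flatnonzero(sel))])
            reported = float(np.mean(pred != data.y[idx_test]))
        else:
            reported = recorder.best_error
        runs.append(
            GSRun(
                seed=run_seed,
                best_mask=mask,
                best_fitness=recorder.best_fitness,
                cv_error=recorder.best_error,
                reported_error=reported,
                n_selected=mask.l,
                wall_time=wall,
                trace=list(result.trace.records),
            )
        )
    return GSResult(runs=runs, weights=weights, plan=plan, mode=mode, k=k)


def run_bfbi(data: LabeledDataset, plan: CVPlan = CVPlan(), **kwargs) -> GSResult:
    """Ablation baseline: the binarized optimizer without the inspector
    group (BFBI). Identical to :func:`run_bsma_fbi` with the slime-mould
    phase disabled."""
    kwargs.pop("inspector", None)
    return run_bsma_fbi(data, plan, inspector=False, **kwargs)
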