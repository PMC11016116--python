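"""Synthetic high-dimensional, small-sample expression data.

Generates labeled matrices shaped like microarray gene-expression
studies — tens of samples, hundreds to thousands of features — with a
known planted set of class-informative genes, optional redundant genes
(noisy copies of informative ones) and pure-noise genes. The ground
truth makes wrapper-selection behaviour testable: recovery of the
informative set can be scored directly instead of relying on
classification accuracy alone.

The class-conditional model is Gaussian: each informative gene receives
per-class mean offsets spaced ``class_separation`` noise-standard-
deviations apart, all genes share i.i.d. Gaussian noise. This keeps
chance-level and wide-margin oracles analytic; batch effects,
missingness and realistic co-expression networks are deliberately not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .binary import FeatureMask, LabeledDataset
from .core import ConfigurationError

__all__ = ["SyntheticSpec", "generate_expression_dataset", "informative_recall"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic expression dataset."""

    n_samples: int = 60
    n_features: int = 200
    n_informative: int = 10
    n_redundant: int = 0
    n_classes: int = 2
    class_separation: float = 3.0  # mean shift between classes, in noise-SD units
    noise_sd: float = 1.0
    seed: int = 0
    redundant_corr: float = 0.9  # correlation of redundant genes with their parent
    log_intensity: bool = False  # offset to a log2-microarray-like scale

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ConfigurationError("feature counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ConfigurationError(
                "informative + redundant features exceed the feature count"
            )
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ConfigurationError("redundant features need informative parents")
        if self.n_samples < 2 * self.n_classes:
            raise ConfigurationError("need at least 2 samples per class")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not (0.0 < self.redundant_corr < 1.0):
            raise ConfigurationError("redundant_corr must lie in (0, 1)")


def generate_expression_dataset(spec: SyntheticSpec) -> Tuple[LabeledDataset, np.ndarray]:
    """Generate a dataset and the indices of its informative features.

    Returns ``(dataset, truth)`` where ``truth`` is the sorted array of
    column indices (after shuffling) holding the informative genes.
    Redundant genes are noisy linear copies of randomly chosen
    informative parents and are *not* part of the truth set.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, K = spec.n_samples, spec.n_features, spec.n_classes

    # Balanced class labels in random order.
    y = np.arange(n) % K
    rng.shuffle(y)

    X = rng.normal(0.0, spec.noise_sd, size=(n, d))

    # Informative block: per-gene class centers spaced class_separation
    # noise-SDs apart, class order randomized per gene so no gene is a
    # copy of another.
    shift = spec.class_separation * spec.noise_sd
    for f in range(spec.n_informative):
        centers = shift * rng.permutation(K)
        X[:, f] += centers[y]

    # Redundant block: correlated noisy copies of informative parents.
    rho = spec.redundant_corr
    for f in range(spec.n_informative, spec.n_informative + spec.n_redundant):
        parent = int(rng.integers(spec.n_informative))
        pcol = X[:, parent]
        psd = pcol.std()
        extra = psd * np.sqrt(1.0 / rho**2 - 1.0)
        X[:, f] = pcol + rng.normal(0.0, extra, size=n)

    perm = rng.permutation(d)
    X = X[:, perm]
    inv = np.empty(d, dtype=int)
    inv[perm] = np.arange(d)
    truth = np.sort(inv[: spec.n_informative])

    if spec.log_intensity:
        X = X + 8.0  # typical log2-intensity baseline of microarray chips

    names = [f"g{j:05d}" for j in range(d)]
    return LabeledDataset(X=X, y=y, feature_names=names), truth


def informative_recall(mask: FeatureMask, truth: np.ndarray) -> float:
    """Fraction of the planted informative genes present in a mask."""
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise ValueError("truth set must be non-empty")
    if mask.d <= truth.max():
        raise ValueError("mask shorter than the largest truth index")
    selected = set(mask.selected().tolist())
    hit = sum(1 for t in truth.tolist() if t in selected)
    return hit / truth.size
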