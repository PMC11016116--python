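"""Nonparametric comparison statistics for optimizer benchmarking.

Paired Wilcoxon signed-rank tests (significance 0.05 by convention in
this literature) decide per-function superiority/equality/inferiority,
and Friedman mean ranks summarize overall standing as the average ranked
value (ARV, lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "wilcoxon_signed_rank",
    "friedman_arv",
    "sign_summary",
    "ComparisonTable",
    "comparison_table",
]


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. With all differences zero the result
    is degenerate: statistic 0, p = 1. The exact null distribution is
    used for n <= 25 (when |differences| are untied); larger samples or
    tied ranks fall back to the normal approximation with tie
    correction.

    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not ties:
        res = sps.wilcoxon(d, method="exact", correction=False)
        return float(res.statistic), float(res.pvalue)
    if n <= 16:
        # tied magnitudes at small n: exact two-sided p by enumerating
        # all sign assignments of the mid-ranks
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        total = float(ranks.sum())
        observed = min(w_plus, total - w_plus)
        count = 0
        for bits in range(2**n):
            w = sum(r for j, r in enumerate(ranks) if bits >> j & 1)
            if min(w, total - w) <= observed + 1e-9:
                count += 1
        return min(w_plus, total - w_plus), count / 2**n
    res = sps.wilcoxon(d, method="approx", correction=False)
    return float(res.statistic), float(res.pvalue)


def friedman_arv(means: pd.DataFrame):
    """Friedman ranks and average ranked values from a means table.

    ``means`` has one row per algorithm and one column per benchmark
    function. Each column is ranked ascending (lower mean = better =
    rank 1), ties mid-ranked; the ARV of an algorithm is its mean rank
    across functions.

    Returns ``(ranks: DataFrame, arv: Series, chi_square: float)`` where
    chi_square is the Friedman statistic
    ``12/(N k (k+1)) * sum_j Rj^2 - 3 N (k+1)``.
    """
    if not isinstance(means, pd.DataFrame):
        means = pd.DataFrame(means)
    k, N = means.shape
    if k < 2 or N < 2:
        raise ValueError("need at least 2 algorithms and 2 functions")
    if means.isna().any().any():
        raise ValueError("means table must be complete (no missing cells)")
    ranks = pd.DataFrame(np.column_stack([sps.rankdata(means[c]) for c in means.columns]),
                         index=means.index, columns=means.columns)
    arv = ranks.mean(axis=1)
    Rj = ranks.sum(axis=1).to_numpy()
    chi_square = float(12.0 / (N * k * (k + 1)) * np.sum(Rj**2) - 3.0 * N * (k + 1))
    return ranks, arv, chi_square


def sign_summary(
    reference: dict[str, np.ndarray],
    competitor: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict[str, int]:
    """Per-function "+/=/-" tally of a reference algorithm vs one competitor.

    Both arguments map function name -> per-repeat final values (paired
    repeats). '+' means the reference is significantly better (lower
    mean, Wilcoxon p < alpha), '-' significantly worse, '=' no
    significant difference.
    """
    tally = {"+": 0, "=": 0, "-": 0}
    for fname, ref_vals in reference.items():
        comp_vals = competitor[fname]
        try:
            _, p = wilcoxon_signed_rank(ref_vals, comp_vals)
        except ValueError:
            p = 1.0
        if p < alpha:
            tally["+" if np.mean(ref_vals) < np.mean(comp_vals) else "-"] += 1
        else:
            tally["="] += 1
    return tally


@dataclass
class ComparisonTable:
    """Aggregate benchmark comparison across algorithms and functions."""

    avg: pd.DataFrame  # algorithms x functions mean final value
    std: pd.DataFrame  # algorithms x functions std of final values
    ranks: pd.DataFrame  # Friedman ranks per function
    arv: pd.Series  # average ranked value per algorithm
    chi_square: float
    signs: dict  # competitor -> {'+': .., '=': .., '-': ..} vs reference
    reference: str


def comparison_table(
    results: dict[str, dict[str, np.ndarray]],
    reference: str | None = None,
    alpha: float = 0.05,
) -> ComparisonTable:
    """Build the full comparison table from raw per-repeat results.

    ``results[algo][function]`` is the array of final best values over
    repeats (paired across algorithms). The reference algorithm (first
    key by default) is the one the +/=/- columns describe.
    """
    algos = list(results)
    if reference is None:
        reference = algos[0]
    functions = list(results[reference])
    avg = pd.DataFrame(
        {f: [float(np.mean(results[a][f])) for a in algos] for f in functions},
        index=algos,
    )
    std = pd.DataFrame(
        {f: [float(np.std(results[a][f], ddof=1)) for a in algos] for f in functions},
        index=algos,
    )
    ranks, arv, chi_square = friedman_arv(avg)
    signs = {
        a: sign_summary(results[reference], results[a], alpha)
        for a in algos
        if a != reference
    }
    return ComparisonTable(avg, std, ranks, arv, chi_square, signs, reference)
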