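"""Histogram-based thresholding objectives: Shannon entropy and multilevel Otsu.

Both criteria are pure functions of a :class:`~metathresh.histogram.Histogram`
and an ordered threshold vector, and both are *maximized*:

* Shannon entropy (SEF): the sum over the k+1 classes of the entropy of the
  within-class normalized intensity distribution,
  H = sum_c [ -sum_{i in c} p_c(i) ln p_c(i) ] with p_c(i) = h(i) / w_c and
  w_c the class probability mass.  Large H favours classes that are
  internally uniform.

* Multilevel Otsu (MLOT): the between-class variance
  sigma_B^2 = sum_j omega_j (mu_j - mu_T)^2, the probability-weighted squared
  deviation of the class mean intensities from the global mean.

Conventions: 0 * ln 0 == 0, and an empty class (omega_j == 0) contributes 0
to either objective — degenerate threshold vectors are evaluated, not
penalized, so the fitness landscape stays finite.

:func:`make_objective` returns a fast evaluator built on prefix sums
(O(k) per threshold vector), used both by the metaheuristics and by the
exhaustive :func:`brute_force_optimum` reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Literal

import numpy as np

from .histogram import Histogram, as_thresholds

ObjectiveName = Literal["sef", "otsu"]

OBJECTIVE_NAMES = ("sef", "otsu")

#: exhaustive-search budget: number of threshold combinations we are willing
#: to enumerate (covers k<=3 at 256 levels and any k at small L)
BRUTE_FORCE_BUDGET = 3_000_000

__all__ = [
    "OBJECTIVE_NAMES",
    "ClassStatistics",
    "class_statistics",
    "shannon_entropy",
    "otsu_between_class_variance",
    "total_variance",
    "make_objective",
    "brute_force_optimum",
]


@dataclass(frozen=True)
class ClassStatistics:
    """Per-class probability mass and mean intensity under a threshold vector.

    ``omega[j]`` is the cumulative probability of class j, ``mu[j]`` its mean
    intensity (0 by convention when the class is empty), and ``mu_total`` the
    global mean intensity.  The omegas sum to 1 and
    sum_j omega[j] * mu[j] == mu_total.
    """

    omega: np.ndarray
    mu: np.ndarray
    mu_total: float


def _bounds(thresholds: np.ndarray, levels: int) -> np.ndarray:
    """Upper class boundaries as indices into inclusive prefix sums."""
    return np.concatenate([thresholds, [levels - 1]])


def class_statistics(hist: Histogram, thresholds) -> ClassStatistics:
    """omega_j, mu_j and mu_T for the k+1 classes induced by ``thresholds``."""
    th = as_thresholds(thresholds, hist.levels)
    p = hist.normalized
    i = np.arange(hist.levels)
    cum_p = np.concatenate([[0.0], np.cumsum(p)])
    cum_ip = np.concatenate([[0.0], np.cumsum(i * p)])
    hi = _bounds(th, hist.levels) + 1
    lo = np.concatenate([[0], th + 1])
    omega = cum_p[hi] - cum_p[lo]
    mass = cum_ip[hi] - cum_ip[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(omega > 0, mass / np.where(omega > 0, omega, 1.0), 0.0)
    return ClassStatistics(omega=omega, mu=mu, mu_total=float(cum_ip[-1]))


def shannon_entropy(hist: Histogram, thresholds) -> float:
    """Summed within-class Shannon entropy of the thresholded histogram."""
    th = as_thresholds(thresholds, hist.levels)
    return make_objective(hist, "sef")(th)


def otsu_between_class_variance(hist: Histogram, thresholds) -> float:
    """Between-class variance sigma_B^2 of the thresholded histogram."""
    th = as_thresholds(thresholds, hist.levels)
    return make_objective(hist, "otsu")(th)


def total_variance(hist: Histogram) -> float:
    """Total intensity variance sigma_T^2 (upper bound on sigma_B^2)."""
    p = hist.normalized
    i = np.arange(hist.levels)
    mu_t = float(np.sum(i * p))
    return float(np.sum((i - mu_t) ** 2 * p))


def make_objective(hist: Histogram, name: str) -> Callable[[np.ndarray], float]:
    """Build a fast evaluator f(thresholds) -> fitness for ``name``.

    The returned callable expects a strictly increasing integer array in
    [1, levels-2] (it does not re-validate) and evaluates in O(k) using
    precomputed prefix sums over the histogram.
    """
    if name not in OBJECTIVE_NAMES:
        raise ValueError(f"unknown objective {name!r}; expected one of {OBJECTIVE_NAMES}")
    p = hist.normalized
    levels = hist.levels
    i = np.arange(levels)
    cum_p = np.concatenate([[0.0], np.cumsum(p)])

    if name == "otsu":
        cum_ip = np.concatenate([[0.0], np.cumsum(i * p)])
        mu_t = float(cum_ip[-1])

        def otsu(th: np.ndarray) -> float:
            hi = np.concatenate([th, [levels - 1]]) + 1
            lo = np.concatenate([[0], th + 1])
            omega = cum_p[hi] - cum_p[lo]
            mass = cum_ip[hi] - cum_ip[lo]
            nz = omega > 0
            mu = mass[nz] / omega[nz]
            return float(np.sum(omega[nz] * (mu - mu_t) ** 2))

        return otsu

    # SEF: per-class entropy ln(w_c) - (1/w_c) * sum_{i in c} p_i ln p_i,
    # exploiting 0 ln 0 == 0 for empty bins and empty classes.
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_plogp = np.concatenate([[0.0], np.cumsum(plogp)])

    def sef(th: np.ndarray) -> float:
        hi = np.concatenate([th, [levels - 1]]) + 1
        lo = np.concatenate([[0], th + 1])
        omega = cum_p[hi] - cum_p[lo]
        s = cum_plogp[hi] - cum_plogp[lo]
        nz = omega > 0
        return float(np.sum(np.log(omega[nz]) - s[nz] / omega[nz]))

    return sef


def brute_force_optimum(
    hist: Histogram, k: int, name: str, budget: int = BRUTE_FORCE_BUDGET
) -> tuple[np.ndarray, float]:
    """Exhaustive maximizer over all strictly increasing threshold vectors.

    Enumerates every k-combination of [1, levels-2] and returns the best
    (thresholds, fitness) pair; ties are broken by the lexicographically
    smallest threshold vector (combinations are generated in lexicographic
    order and only strict improvements are kept).

    Raises
    ------
    ResourceWarning
        If the number of combinations exceeds ``budget``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_positions = hist.levels - 2
    if k > n_positions:
        raise ValueError(f"k={k} exceeds the {n_positions} available threshold positions")
    n_comb = math.comb(n_positions, k)
    if n_comb > budget:
        raise ResourceWarning(
            f"exhaustive search over {n_comb} combinations exceeds budget {budget}"
        )
    f = make_objective(hist, name)
    best_th: tuple[int, ...] | None = None
    best_fit = -math.inf
    for combo in combinations(range(1, hist.levels - 1), k):
        fit = f(np.asarray(combo, dtype=np.int64))
        if fit > best_fit:
            best_fit = fit
            best_th = combo
    assert best_th is not None
    return np.asarray(best_th, dtype=np.int64), best_fit
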