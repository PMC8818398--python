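"""Population metaheuristics for integer threshold selection.

Three algorithms — cuckoo search (CS), the equilibrium optimizer (EO) and
harmony search (HS) — share one contract: maximize ``objective(thresholds)``
over strictly increasing integer vectors inside a box ``SearchSpace``.

Internally every algorithm works on *continuous* positions so that its update
equations (Levy flights, exponential decay schedules, bandwidth perturbation)
apply verbatim; a position is rounded, sorted and de-duplicated by
:func:`decode` only at fitness-evaluation time.  All randomness flows from a
single seeded ``numpy.random.Generator`` per run, so a given
(objective, space, config) triple is bitwise reproducible.

The per-run bookkeeping (``OptimizationResult``) records the best decoded
threshold vector, its fitness, the elitist best-so-far trace per iteration
(always non-decreasing), and the number of objective evaluations:
CS spends ``pop * (1 + ceil(pa * pop) / pop)`` evaluations per iteration plus
``pop`` at initialization, EO spends ``pop`` per iteration plus ``pop``, and
HS spends exactly 1 per improvisation plus ``pop``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "SearchSpace",
    "CuckooParams",
    "EquilibriumParams",
    "HarmonyParams",
    "OptimizerConfig",
    "OptimizationResult",
    "ALGORITHMS",
    "mantegna_sigma",
    "levy_step",
    "decode",
    "cuckoo_search",
    "equilibrium_optimizer",
    "harmony_search",
    "optimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds for a k-dimensional threshold vector."""

    dim: int
    lower: float = 1.0
    upper: float = 254.0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be strictly below upper bound")

    @classmethod
    def for_levels(cls, k: int, levels: int = 256) -> "SearchSpace":
        """Threshold search space [1, levels-2]^k for an L-level histogram."""
        return cls(dim=k, lower=1.0, upper=float(levels - 2))


@dataclass(frozen=True)
class CuckooParams:
    """Cuckoo-search knobs: abandon probability pa, step scale alpha, Levy exponent beta."""

    pa: float = 0.25
    alpha: float = 1.0
    beta: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError("pa must lie in [0, 1]")
        if not 0.0 < self.beta <= 2.0:
            raise ValueError("beta must lie in (0, 2]")


@dataclass(frozen=True)
class EquilibriumParams:
    """Equilibrium-optimizer knobs: a1/a2 schedule constants, generation probability GP, unit volume V."""

    a1: float = 2.0
    a2: float = 1.0
    gp: float = 0.5
    v: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gp <= 1.0:
            raise ValueError("gp must lie in [0, 1]")


@dataclass(frozen=True)
class HarmonyParams:
    """Harmony-search knobs: memory-consideration rate, pitch-adjust rate, bandwidth.

    ``bw=None`` means 1/20 of the search-space width, resolved at run time.
    """

    hmcr: float = 0.9
    par: float = 0.3
    bw: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hmcr <= 1.0:
            raise ValueError("hmcr must lie in [0, 1]")
        if not 0.0 <= self.par <= 1.0:
            raise ValueError("par must lie in [0, 1]")


ALGORITHMS = ("cs", "eo", "hs")


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str = "cs"
    population_size: int = 30
    max_iterations: int = 100
    seed: int = 0
    cs: CuckooParams = field(default_factory=CuckooParams)
    eo: EquilibriumParams = field(default_factory=EquilibriumParams)
    hs: HarmonyParams = field(default_factory=HarmonyParams)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (EO needs a 4-candidate pool)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def with_seed(self, seed: int) -> "OptimizerConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of one optimizer run.

    ``history[t]`` is the elitist best fitness after iteration t+1 (length
    ``max_iterations``, non-decreasing); ``best_fitness == history[-1]``.
    """

    best_thresholds: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int
    seed: int


def mantegna_sigma(beta: float) -> float:
    """Standard deviation sigma_u of the Gaussian numerator in Mantegna's Levy step.

    sigma_u = [ Gamma(1+b) sin(pi b / 2) / ( Gamma((1+b)/2) b 2^((b-1)/2) ) ]^(1/b)
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(beta: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Heavy-tailed Levy-stable step(s) via Mantegna's Gaussian-ratio method.

    u ~ N(0, sigma_u^2), v ~ N(0, 1), step = u / |v|^(1/beta).
    """
    sigma = mantegna_sigma(beta)
    u = rng.normal(0.0, sigma, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def decode(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Continuous position -> valid strictly increasing integer threshold vector.

    Clamps to the box, rounds to nearest integer, sorts ascending, then
    repairs duplicates by pushing collided values to the nearest free integer
    upward; if the top of the range is hit, remaining collisions are resolved
    downward.
    """
    lo, hi = int(round(space.lower)), int(round(space.upper))
    n_levels = hi - lo + 1
    if space.dim > n_levels:
        raise ValueError(
            f"cannot place {space.dim} distinct thresholds in {n_levels} integer levels"
        )
    th = np.sort(np.rint(np.clip(position, space.lower, space.upper)).astype(np.int64))
    for i in range(1, th.size):
        if th[i] <= th[i - 1]:
            th[i] = th[i - 1] + 1
    if th[-1] > hi:  # ran off the top; resolve remaining collisions downward
        th[-1] = hi
        for i in range(th.size - 2, -1, -1):
            if th[i] >= th[i + 1]:
                th[i] = th[i + 1] - 1
    return th


class _Evaluator:
    """Decode-on-evaluate wrapper tracking call count and the elitist best."""

    def __init__(self, objective: Callable[[np.ndarray], float], space: SearchSpace):
        self.objective = objective
        self.space = space
        self.calls = 0
        self.best_fitness = -math.inf
        self.best_thresholds: np.ndarray | None = None

    def __call__(self, position: np.ndarray) -> float:
        th = decode(position, self.space)
        fit = float(self.objective(th))
        self.calls += 1
        if not math.isfinite(fit):
            raise ArithmeticError(
                f"objective returned non-finite fitness {fit} at thresholds {th.tolist()}"
            )
        if fit > self.best_fitness:
            self.best_fitness = fit
            self.best_thresholds = th
        return fit


def _init_population(rng: np.random.Generator, n: int, space: SearchSpace) -> np.ndarray:
    return space.lower + rng.random((n, space.dim)) * (space.upper - space.lower)


def _result(ev: _Evaluator, history: list[float], seed: int) -> OptimizationResult:
    assert ev.best_thresholds is not None
    return OptimizationResult(
        best_thresholds=ev.best_thresholds,
        best_fitness=ev.best_fitness,
        history=np.asarray(history, dtype=np.float64),
        evaluations=ev.calls,
        seed=seed,
    )


def cuckoo_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Cuckoo search with Mantegna Levy flights.

    Each generation: (a) every nest proposes a trial egg by a Levy flight
    scaled by alpha along its offset from the current best nest, which
    greedily replaces a *randomly chosen* nest when fitter (the classic
    scheme); (b) a fraction ``pa`` of the worst nests is abandoned and
    re-drawn by a bounded random walk between two random nests.
    """
    p = config.cs
    rng = np.random.default_rng(config.seed)
    ev = _Evaluator(objective, space)
    n, k = config.population_size, space.dim

    pop = _init_population(rng, n, space)
    fit = np.array([ev(pop[i]) for i in range(n)])
    best_pos = pop[int(np.argmax(fit))].copy()

    history: list[float] = []
    n_abandon = int(round(p.pa * n))
    for _ in range(config.max_iterations):
        for i in range(n):
            step = p.alpha * levy_step(p.beta, rng, k) * (pop[i] - best_pos)
            trial = np.clip(pop[i] + step, space.lower, space.upper)
            j = int(rng.integers(n))
            f_trial = ev(trial)
            if f_trial > fit[j]:
                pop[j] = trial
                fit[j] = f_trial
        if n_abandon:
            for i in np.argsort(fit)[:n_abandon]:
                r1, r2 = rng.integers(n, size=2)
                walk = rng.random(k) * (pop[r1] - pop[r2])
                pop[i] = np.clip(pop[i] + walk, space.lower, space.upper)
                fit[i] = ev(pop[i])
        best_pos = pop[int(np.argmax(fit))].copy()
        history.append(ev.best_fitness)
    return _result(ev, history, config.seed)


def _pool_insert(
    pool_pos: np.ndarray, pool_fit: np.ndarray, pos: np.ndarray, f: float
) -> None:
    """Cascade-insert a candidate into the 4-slot equilibrium pool (best first)."""
    for slot in range(4):
        if f > pool_fit[slot]:
            pool_pos[slot + 1 :] = pool_pos[slot:3].copy()
            pool_fit[slot + 1 :] = pool_fit[slot:3].copy()
            pool_pos[slot] = pos
            pool_fit[slot] = f
            return


def equilibrium_optimizer(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Equilibrium optimizer with a 4-candidate pool plus their mean.

    Each particle is attracted to a pool member drawn uniformly from the
    five (4 best-so-far candidates and their component-wise average).  The
    exponential term F = a1 sign(r - 0.5) (e^{-lambda t} - 1) with the decay
    schedule t = (1 - Iter/Max)^{a2 Iter/Max} balances exploration against
    exploitation; the generation-rate term G = GCP (Ceq - lambda C) F adds a
    source contribution gated by GP.  Concentrations update as
    C <- Ceq + (C - Ceq) F + G / (lambda V) (1 - F).
    """
    p = config.eo
    rng = np.random.default_rng(config.seed)
    ev = _Evaluator(objective, space)
    n, k = config.population_size, space.dim

    pop = _init_population(rng, n, space)
    fit = np.array([ev(pop[i]) for i in range(n)])

    pool_pos = np.zeros((4, k))
    pool_fit = np.full(4, -math.inf)

    for i in range(n):
        _pool_insert(pool_pos, pool_fit, pop[i].copy(), float(fit[i]))

    history: list[float] = []
    max_iter = config.max_iterations
    for it in range(1, max_iter + 1):
        t = (1.0 - it / max_iter) ** (p.a2 * it / max_iter)
        pool_ave = pool_pos.mean(axis=0)
        for i in range(n):
            choice = int(rng.integers(5))
            ceq = pool_ave if choice == 4 else pool_pos[choice]
            lam = np.maximum(rng.random(k), 1e-12)
            r = rng.random(k)
            f_term = p.a1 * np.sign(r - 0.5) * (np.exp(-lam * t) - 1.0)
            r1, r2 = rng.random(2)
            gcp = 0.5 * r1 if r2 >= p.gp else 0.0
            g0 = gcp * (ceq - lam * pop[i])
            g = g0 * f_term
            c_new = ceq + (pop[i] - ceq) * f_term + (g / (lam * p.v)) * (1.0 - f_term)
            c_new = np.clip(c_new, space.lower, space.upper)
            f_new = ev(c_new)
            pop[i] = c_new
            fit[i] = f_new
            _pool_insert(pool_pos, pool_fit, c_new.copy(), f_new)
        history.append(ev.best_fitness)
    return _result(ev, history, config.seed)


def harmony_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Harmony search over the harmony-memory matrix of threshold vectors.

    Each improvisation builds a new harmony component-wise: with probability
    HMCR the component is copied from a uniformly random memory row and then,
    with probability PAR, pitch-adjusted by +/- rand * BW (fair-coin sign);
    otherwise it is redrawn uniformly in the bounds.  The new harmony
    replaces the worst memory row when fitter.
    """
    p = config.hs
    rng = np.random.default_rng(config.seed)
    ev = _Evaluator(objective, space)
    n, k = config.population_size, space.dim
    bw = p.bw if p.bw is not None else (space.upper - space.lower) / 20.0

    hm = _init_population(rng, n, space)
    fit = np.array([ev(hm[i]) for i in range(n)])

    history: list[float] = []
    for _ in range(config.max_iterations):
        x_new = np.empty(k)
        for c in range(k):
            if rng.random() < p.hmcr:
                x_new[c] = hm[int(rng.integers(n)), c]
                if rng.random() < p.par:
                    delta = rng.random() * bw
                    x_new[c] += delta if rng.random() < 0.5 else -delta
            else:
                x_new[c] = space.lower + rng.random() * (space.upper - space.lower)
        x_new = np.clip(x_new, space.lower, space.upper)
        f_new = ev(x_new)
        worst = int(np.argmin(fit))
        if f_new > fit[worst]:
            hm[worst] = x_new
            fit[worst] = f_new
        history.append(ev.best_fitness)
    return _result(ev, history, config.seed)


_DISPATCH = {
    "cs": cuckoo_search,
    "eo": equilibrium_optimizer,
    "hs": harmony_search,
}


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Run the algorithm named in ``config.algorithm`` under the shared contract."""
    return _DISPATCH[config.algorithm](objective, space, config)
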