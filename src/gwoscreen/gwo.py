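"""Grey Wolf Optimization over a bounded continuous box.

The pack is led by the three best wolves (alpha, beta, gamma); every wolf
moves toward a stochastic average of leader-relative positions, with a step
coefficient whose scale decays linearly over the run ("encircling" early,
"pouncing" late).  Two coefficient variants are supported:

* ``standard`` — the canonical rules: a = 2(1 - t/T), x = 2a*v1 - a so that
  x ∈ [-a, a], y = 2*v2.
* ``paper`` — a published variant in which the decay starts at 1/2,
  a = (1 - t/T)/2, and x = 2a*(v1 + v2) - a so that x ∈ [-a, 3a]; y = 2*v2.

Both collapse to the same (pure leader-attraction) update at a = 0.

The distance term for each leader L is E_L = |y * GW_L - GW_i| (elementwise,
with the moving wolf's own position standing in for the prey location), the
candidate is GW_L - x * E_L, and the new position is the arithmetic mean of
the three candidates, clipped to the box.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "GWOConfig",
    "WolfPack",
    "OptimizationResult",
    "GreyWolfOptimizer",
    "initialize_pack",
    "control_parameter",
    "encircle_coefficients",
    "pounce_update",
    "optimize",
    "write_trace_csv",
]

Objective = Callable[[np.ndarray], float]


@dataclass
class GWOConfig:
    """Search configuration.

    n_wolves : pack size (>= 3 so the three leader ranks exist)
    dim      : search-space dimension
    max_iters: number of pounce iterations T
    lower_bounds, upper_bounds : box, elementwise lower < upper
    variant  : "standard" or "paper" coefficient rules
    seed     : RNG seed for init and coefficient draws
    leader_combine : how the three leader candidates merge ("mean")
    """

    n_wolves: int
    dim: int
    max_iters: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    variant: str = "standard"
    seed: int = 0
    leader_combine: str = "mean"

    def __post_init__(self):
        self.lower_bounds = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        self.upper_bounds = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        if self.lower_bounds.size == 1 and self.dim > 1:
            self.lower_bounds = np.full(self.dim, self.lower_bounds[0])
        if self.upper_bounds.size == 1 and self.dim > 1:
            self.upper_bounds = np.full(self.dim, self.upper_bounds[0])
        if self.n_wolves < 3:
            raise ValueError("n_wolves must be >= 3 (alpha, beta, gamma leaders)")
        if self.dim < 1 or self.max_iters < 0:
            raise ValueError("dim must be >= 1 and max_iters >= 0")
        if self.lower_bounds.shape != (self.dim,) or self.upper_bounds.shape != (self.dim,):
            raise ValueError("bounds must have length dim")
        if not np.all(self.lower_bounds < self.upper_bounds):
            raise ValueError("lower_bounds must be < upper_bounds elementwise")
        if self.variant not in ("standard", "paper"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.leader_combine != "mean":
            raise ValueError("only leader_combine='mean' is supported")


@dataclass
class WolfPack:
    positions: np.ndarray          # (n_wolves, dim)
    fitness: np.ndarray            # (n_wolves,)
    iteration: int
    leaders: tuple[int, int, int]  # indices of alpha, beta, gamma
    rng: np.random.Generator


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    evaluations: int = 0
    trace: list[dict] = field(default_factory=list)


def _rank_leaders(fitness: np.ndarray) -> tuple[int, int, int]:
    order = np.argsort(fitness, kind="stable")  # lower index wins ties
    return int(order[0]), int(order[1]), int(order[2])


def initialize_pack(config: GWOConfig, objective: Objective) -> WolfPack:
    """Draw the pack uniformly inside the box and rank the leaders."""
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(config.lower_bounds, config.upper_bounds,
                            size=(config.n_wolves, config.dim))
    fitness = np.empty(config.n_wolves)
    for i in range(config.n_wolves):
        val = float(objective(positions[i]))
        if not np.isfinite(val):
            raise ValueError(
                f"objective returned non-finite value {val} at initial "
                f"position {positions[i]}"
            )
        fitness[i] = val
    return WolfPack(positions=positions, fitness=fitness, iteration=0,
                    leaders=_rank_leaders(fitness), rng=rng)


def control_parameter(iteration: int, config: GWOConfig) -> float:
    """Linearly decaying step scale a(t): 2(1-t/T) standard, (1-t/T)/2 paper."""
    T = config.max_iters
    if iteration < 0 or iteration > T:
        raise ValueError(f"iteration {iteration} outside [0, {T}]")
    frac = 1.0 - (iteration / T if T > 0 else 1.0)
    return 2.0 * frac if config.variant == "standard" else 0.5 * frac


def encircle_coefficients(m: float, rng: np.random.Generator, dim: int,
                          variant: str = "standard",
                          v1: Optional[np.ndarray] = None,
                          v2: Optional[np.ndarray] = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the stochastic step (x) and wobble (y) coefficient vectors.

    v1/v2 may be supplied explicitly (tests); otherwise they are drawn
    i.i.d. uniform on [0, 1] per dimension.
    """
    if m < 0:
        raise ValueError(f"control parameter m must be >= 0, got {m}")
    if v1 is None:
        v1 = rng.random(dim)
    if v2 is None:
        v2 = rng.random(dim)
    if variant == "paper":
        x = 2.0 * m * (v1 + v2) - m
    else:
        x = 2.0 * m * v1 - m
    y = 2.0 * v2
    return x, y


def pounce_update(pack: WolfPack, m: float, config: GWOConfig) -> np.ndarray:
    """One position update for every wolf; returns the new positions.

    Each wolf draws fresh coefficients per leader, computes the elementwise
    absolute distance E_L = |y_L * GW_L - GW_i| and candidate
    GW_L - x_L * E_L, averages the three candidates, and is clipped to the
    box.
    """
    n, d = pack.positions.shape
    a_idx, b_idx, g_idx = pack.leaders
    leaders = (pack.positions[a_idx], pack.positions[b_idx], pack.positions[g_idx])
    new_positions = np.empty_like(pack.positions)
    for i in range(n):
        p = pack.positions[i]
        candidates = np.empty((3, d))
        for L, gw_leader in enumerate(leaders):
            x, y = encircle_coefficients(m, pack.rng, d, config.variant)
            E = np.abs(y * gw_leader - p)
            candidates[L] = gw_leader - x * E
        new_positions[i] = candidates.mean(axis=0)
    np.clip(new_positions, config.lower_bounds, config.upper_bounds,
            out=new_positions)
    return new_positions


def optimize(objective: Objective, config: GWOConfig,
             callback: Optional[Callable[[int, "WolfPack"], None]] = None
             ) -> OptimizationResult:
    """Run the full search: init, then T rounds of pounce/evaluate/rank."""
    pack = initialize_pack(config, objective)
    evaluations = config.n_wolves
    best_idx = pack.leaders[0]
    best_pos = pack.positions[best_idx].copy()
    best_fit = float(pack.fitness[best_idx])
    history = [best_fit]
    trace = [{"iteration": 0, "best_fitness": best_fit,
              "mean_fitness": float(pack.fitness.mean()),
              "m": control_parameter(0, config)}]
    if callback is not None:
        callback(0, pack)
    for t in range(1, config.max_iters + 1):
        m = control_parameter(t, config)
        pack.positions = pounce_update(pack, m, config)
        for i in range(config.n_wolves):
            val = float(objective(pack.positions[i]))
            if np.isnan(val):
                warnings.warn(f"objective returned NaN at iteration {t}; "
                              "treating as +inf", RuntimeWarning)
                val = np.inf
            pack.fitness[i] = val
        evaluations += config.n_wolves
        pack.iteration = t
        pack.leaders = _rank_leaders(pack.fitness)
        cur_best = pack.leaders[0]
        if pack.fitness[cur_best] < best_fit:
            best_fit = float(pack.fitness[cur_best])
            best_pos = pack.positions[cur_best].copy()
        history.append(best_fit)
        finite = pack.fitness[np.isfinite(pack.fitness)]
        trace.append({"iteration": t, "best_fitness": best_fit,
                      "mean_fitness": float(finite.mean()) if finite.size else np.inf,
                      "m": m})
        if callback is not None:
            callback(t, pack)
    return OptimizationResult(best_position=best_pos, best_fitness=best_fit,
                              history=history, evaluations=evaluations,
                              trace=trace)


def write_trace_csv(result: OptimizationResult, path) -> None:
    """Dump the per-iteration trace (iteration, best, mean, m) as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["iteration", "best_fitness", "mean_fitness", "m"])
        writer.writeheader()
        writer.writerows(result.trace)


class GreyWolfOptimizer:
    """Object wrapper over :func:`optimize` holding a config.

    Example
    -------
    >>> opt = GreyWolfOptimizer(n_wolves=12, dim=2, max_iters=50,
    ...                         lower_bounds=-5, upper_bounds=5, seed=3)
    >>> res = opt.optimize(lambda z: float((z ** 2).sum()))
    >>> res.best_fitness < 1e-2
    True
    """

    def __init__(self, n_wolves: int, dim: int, max_iters: int,
                 lower_bounds, upper_bounds, variant: str = "standard",
                 seed: int = 0, leader_combine: str = "mean"):
        self.config = GWOConfig(
            n_wolves=n_wolves, dim=dim, max_iters=max_iters,
            lower_bounds=lower_bounds, upper_bounds=upper_bounds,
            variant=variant, seed=seed, leader_combine=leader_combine)

    def optimize(self, objective: Objective,
                 callback=None) -> OptimizationResult:
        return optimize(objective, self.config, callback=callback)
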