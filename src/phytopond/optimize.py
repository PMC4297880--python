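"""Search for operating points maximizing annual production.

Two searchers over the (D, tau, media multiplier) operating space: an
exhaustive grid scan (the authoritative reference, with ties broken toward
the resource-frugal corner: smaller D, then smaller tau) and a seeded
(mu + lambda) evolution strategy with Gaussian mutation for continuous
refinement. Objective evaluations are cached by operating point, so
identical points are never re-simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["OptimizerConfig", "GridResult", "EvolveResult", "grid_search", "evolve"]

_AXES = ("D", "tau", "multiplier")


@dataclass
class OptimizerConfig:
    """Settings for the evolutionary search.

    ``bounds`` maps axis name (any of "D", "tau", "multiplier") to (lo, hi);
    axes left out are held at their defaults in the objective closure.
    """

    objective: str = "AP"  # "AP" or "AXP" (label only; the callable decides)
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"D": (0.0, 1.0)}
    )
    population: int = 8  # mu
    offspring: int = 16  # lambda
    generations: int = 40
    sigma_fraction: float = 0.10  # mutation s.d. as a fraction of each range
    sigma_decay: float = 0.93  # per-generation shrink of the mutation scale
    seed: int = 0
    tolerance: float = 0.0  # early stop when generation gain falls below

    def __post_init__(self) -> None:
        if self.population < 1 or self.offspring < 1 or self.generations < 1:
            raise ValueError("population, offspring, generations must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if name not in _AXES:
                raise ValueError(f"unknown axis {name!r}")
            if not lo < hi:
                raise ValueError(f"empty bounds for {name}")


class _CachedObjective:
    """Memoizes the objective on rounded axis coordinates."""

    def __init__(self, fn: Callable[..., float]):
        self.fn = fn
        self.cache: dict[tuple, float] = {}
        self.calls = 0

    def __call__(self, **coords: float) -> float:
        key = tuple(sorted((k, round(v, 12)) for k, v in coords.items()))
        if key not in self.cache:
            self.calls += 1
            self.cache[key] = float(self.fn(**coords))
        return self.cache[key]


@dataclass
class GridResult:
    best: dict[str, float]
    best_value: float
    table: "object"  # pandas.DataFrame: one row per grid point
    all_washout: bool


def grid_search(
    objective_fn: Callable[..., float],
    grid: Mapping[str, Sequence[float]],
) -> GridResult:
    """Exhaustively evaluate ``objective_fn(**point)`` on the cartesian grid.

    Returns the argmax and the complete evaluation table. Ties (within 1e-12)
    are broken toward smaller D, then smaller tau. If every point yields a
    non-positive objective the ``all_washout`` flag is set.
    """
    import pandas as pd

    axes = list(grid.keys())
    if not axes or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty on every axis")
    cached = objective_fn if isinstance(objective_fn, _CachedObjective) else _CachedObjective(objective_fn)

    rows = []
    for combo in itertools.product(*(grid[a] for a in axes)):
        point = dict(zip(axes, combo))
        rows.append({**point, "objective": cached(**point)})
    table = pd.DataFrame(rows)

    best_val = table["objective"].max()
    contenders = table[table["objective"] >= best_val - 1e-12].copy()
    sort_cols = [c for c in ("D", "tau") if c in contenders.columns]
    if sort_cols:
        contenders = contenders.sort_values(sort_cols, kind="stable")
    best_row = contenders.iloc[0]
    best = {a: float(best_row[a]) for a in axes}
    return GridResult(best, float(best_row["objective"]), table, bool(best_val <= 0.0))


@dataclass
class EvolveResult:
    best: dict[str, float]
    best_value: float
    history: list[float]  # per-generation best
    evaluations: int
    seed: int


def evolve(objective_fn: Callable[..., float], cfg: OptimizerConfig) -> EvolveResult:
    """(mu + lambda) evolution strategy with Gaussian mutation and box clipping.

    Deterministic for a fixed seed; the final best is never below the best
    of its own initial population (elitist selection). ``history`` records
    the best objective after each generation.
    """
    rng = np.random.default_rng(cfg.seed)
    axes = list(cfg.bounds.keys())
    lo = np.array([cfg.bounds[a][0] for a in axes])
    hi = np.array([cfg.bounds[a][1] for a in axes])
    sigma = cfg.sigma_fraction * (hi - lo)
    cached = objective_fn if isinstance(objective_fn, _CachedObjective) else _CachedObjective(objective_fn)

    def fitness(x: np.ndarray) -> float:
        return cached(**dict(zip(axes, (float(v) for v in x))))

    pop = rng.uniform(lo, hi, size=(cfg.population, len(axes)))
    fit = np.array([fitness(x) for x in pop])
    history: list[float] = []

    for _ in range(cfg.generations):
        parents = pop[rng.integers(0, cfg.population, size=cfg.offspring)]
        children = np.clip(parents + rng.normal(0.0, 1.0, parents.shape) * sigma, lo, hi)
        cfit = np.array([fitness(x) for x in children])
        allx = np.vstack([pop, children])
        allf = np.concatenate([fit, cfit])
        order = np.argsort(-allf, kind="stable")[: cfg.population]
        pop, fit = allx[order], allf[order]
        sigma = sigma * cfg.sigma_decay
        history.append(float(fit[0]))
        if cfg.tolerance > 0 and len(history) >= 2 and history[-1] - history[-2] < cfg.tolerance:
            break

    best = dict(zip(axes, (float(v) for v in pop[0])))
    return EvolveResult(best, float(fit[0]), history, cached.calls, cfg.seed)
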