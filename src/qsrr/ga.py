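"""Binary genetic algorithm for descriptor-subset selection with RMSECV fitness.

Each chromosome is a 0/1 mask over the descriptor columns. Fitness is the
leave-one-out RMSECV of a SIMPLS model on the selected submatrix, with the
latent-variable count optimized inside the evaluation over 2..rank(X_subset).
Masks selecting fewer than two descriptors receive an infinite penalty (the
LV lower bound of 2 requires at least two columns) and are never repaired.

Evolution follows the classical elitist scheme: tournament selection,
single-point crossover applied to a configurable fraction of the non-elite
offspring, per-bit uniform mutation of the cloned remainder, two elites copied
unchanged. A run stops after ``max_generations`` or once the best RMSECV has
not changed (at 1e-12) for ``stall_limit`` consecutive generations. All
randomness flows from a single integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pls import loo_predictions

__all__ = [
    "GAConfig",
    "GARunResult",
    "FitnessEvaluator",
    "evolve",
    "grid_search_hyperparameters",
    "default_grid",
]

PENALTY = float("inf")
_STALL_TOL = 1e-12


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    crossover_fraction: float = 0.8
    mutation_rate: float = 0.2
    elite_count: int = 2
    max_generations: int = 100
    stall_limit: int = 10
    tournament_size: int = 2
    lv_min: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be < population_size")
        if self.tournament_size < 1 or self.lv_min < 1:
            raise ValueError("tournament_size and lv_min must be >= 1")


@dataclass
class GARunResult:
    best_mask: np.ndarray
    best_rmsecv: float
    n_lv: int
    generations_run: int
    seed: int
    history: list[float] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "best_mask": self.best_mask.astype(int).tolist(),
            "best_rmsecv": self.best_rmsecv,
            "n_lv": self.n_lv,
            "generations_run": self.generations_run,
            "seed": self.seed,
            "history": self.history,
        }


class FitnessEvaluator:
    """Memoized RMSECV fitness over descriptor masks for a fixed (X, y).

    Evaluations are deterministic per mask, so the cache may be shared across
    GA runs on the same data without changing any result.
    """

    def __init__(self, X, y, lv_min: int = 2, lv_policy: str = "min") -> None:
        self.X = np.asarray(
            X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float
        )
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per element of y")
        self.lv_min = lv_min
        self.lv_policy = lv_policy
        self._cache: dict[bytes, tuple[float, int]] = {}
        self.n_model_evaluations = 0

    def detail(self, mask) -> tuple[float, int]:
        """(RMSECV, chosen n_LV) for a mask; infinite penalty below 2 bits."""
        mask = np.asarray(mask, dtype=np.uint8)
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        if int(mask.sum()) < 2:
            result = (PENALTY, 0)
        else:
            result = self._evaluate(mask)
            self.n_model_evaluations += 1
        self._cache[key] = result
        return result

    def _evaluate(self, mask: np.ndarray) -> tuple[float, int]:
        Xsub = self.X[:, mask.astype(bool)]
        # generic upper bound on rank(X_subset); per-fold deficiency is
        # handled inside the batched LOO by cross-product exhaustion
        cap = min(Xsub.shape[1], Xsub.shape[0] - 2)
        lv_lo = min(self.lv_min, cap)
        candidates = list(range(lv_lo, cap + 1))
        preds = loo_predictions(Xsub, self.y, candidates)
        rms = np.sqrt(np.mean((preds - self.y[:, None]) ** 2, axis=0))
        k = int(np.argmin(rms))
        return float(rms[k]), candidates[k]

    def __call__(self, mask) -> float:
        return self.detail(mask)[0]


def _tournament(rng, fits: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, fits.size, size=k)
    return int(contenders[np.argmin(fits[contenders])])


def evolve(X, y, config: GAConfig, fitness: FitnessEvaluator | None = None) -> GARunResult:
    """Run one GA and return the best mask found, reproducibly from the seed."""
    if fitness is None:
        fitness = FitnessEvaluator(X, y, lv_min=config.lv_min)
    p = fitness.X.shape[1]
    m = fitness.X.shape[0]
    if p < 2 or m < 3:
        raise ValueError("need at least 2 descriptors and 3 analytes")

    rng = np.random.default_rng(config.seed)
    pop = rng.integers(0, 2, size=(config.population_size, p), dtype=np.uint8)

    history: list[float] = []
    best_fit = PENALTY
    best_mask = pop[0].copy()
    stall = 0
    generations = 0
    while True:
        fits = np.array([fitness(ind) for ind in pop])
        order = np.argsort(fits, kind="stable")
        gen_best = float(fits[order[0]])
        if gen_best < best_fit - _STALL_TOL:
            best_fit = gen_best
            best_mask = pop[order[0]].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if generations >= config.max_generations or stall >= config.stall_limit:
            break
        generations += 1

        elites = pop[order[: config.elite_count]].copy()
        n_children = config.population_size - config.elite_count
        n_cross = int(round(config.crossover_fraction * n_children))
        children = np.empty((n_children, p), dtype=np.uint8)
        for c in range(n_cross):
            p1 = _tournament(rng, fits, config.tournament_size)
            p2 = _tournament(rng, fits, config.tournament_size)
            cut = int(rng.integers(1, p))
            children[c, :cut] = pop[p1, :cut]
            children[c, cut:] = pop[p2, cut:]
        for c in range(n_cross, n_children):
            w = _tournament(rng, fits, config.tournament_size)
            child = pop[w].copy()
            flips = rng.random(p) < config.mutation_rate
            child[flips] ^= 1
            children[c] = child
        pop = np.vstack([elites, children])

    rmsecv, n_lv = fitness.detail(best_mask)
    return GARunResult(
        best_mask=best_mask.astype(int),
        best_rmsecv=rmsecv,
        n_lv=n_lv,
        generations_run=generations,
        seed=config.seed,
        history=history,
    )


def default_grid() -> dict[str, list]:
    """Hyper-parameter grid: population 10..20 step 10, rates 0.1..0.8 step 0.1."""
    rates = [round(0.1 * k, 1) for k in range(1, 9)]
    return {
        "population_size": [10, 20],
        "crossover_fraction": rates,
        "mutation_rate": rates,
    }


def grid_search_hyperparameters(
    X,
    y,
    grid: dict[str, list] | None = None,
    base_config: GAConfig | None = None,
    master_seed: int = 0,
) -> tuple[GAConfig, pd.DataFrame]:
    """Evaluate every grid cell by a full GA run; return the argmin config.

    Cells share a memoized fitness cache (same data); each cell's run gets a
    deterministic child seed derived from ``master_seed``. The full table of
    (population_size, crossover_fraction, mutation_rate, best_rmsecv, n_lv)
    is returned alongside the winning config.
    """
    if grid is None:
        grid = default_grid()
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    base = base_config or GAConfig()
    keys = list(grid)
    cells = list(itertools.product(*(grid[k] for k in keys)))
    seeds = np.random.SeedSequence(master_seed).generate_state(len(cells))

    fitness = FitnessEvaluator(X, y, lv_min=base.lv_min)
    rows = []
    best_cfg, best_val = None, PENALTY
    for cell, seed in zip(cells, seeds):
        cfg = replace(base, **dict(zip(keys, cell)), seed=int(seed))
        run = evolve(X, y, cfg, fitness=fitness)
        rows.append({**dict(zip(keys, cell)), "best_rmsecv": run.best_rmsecv,
                     "n_lv": run.n_lv, "seed": int(seed)})
        if run.best_rmsecv < best_val:
            best_val, best_cfg = run.best_rmsecv, cfg
    return best_cfg, pd.DataFrame(rows)
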