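"""Repeated GA-PLS runs, occurrence tally, and the consensus model.

A single GA run is stochastic: different seeds select different descriptor
subsets of near-equal RMSECV. Repeating the run many times (1000 in routine
use) and recording how often each descriptor is selected separates stable
signal carriers from passengers. The consensus subset keeps the descriptors
whose occurrence exceeds the mean occurrence (strict inequality); the final
model is a fresh SIMPLS fit on that subset with the latent-variable count
re-optimized by leave-one-out CV.

Child seeds are spawned from the master seed with ``numpy.random.SeedSequence``
so any run is individually reproducible by its index, and results are
identical whether runs execute serially or concurrently (merged by index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ga import FitnessEvaluator, GAConfig, GARunResult, evolve
from .pls import CVResult, PLSModel, autoscale, loo_cv_curve, rmse, select_n_lvs, simpls_fit

__all__ = [
    "child_seeds",
    "run_repeats",
    "consensus_select",
    "fit_consensus",
    "build_consensus",
    "ConsensusModel",
]


def child_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run child seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n_runs)]


def run_repeats(
    X,
    y,
    config: GAConfig,
    n_runs: int = 1000,
    master_seed: int = 0,
    fitness: FitnessEvaluator | None = None,
) -> tuple[list[GARunResult], np.ndarray]:
    """``n_runs`` independent GA runs; returns results and occurrence (%).

    ``occurrence[j]`` is the percentage of runs whose best mask selects
    descriptor ``j``. All runs count, including those that exhausted
    ``max_generations`` without stalling.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if fitness is None:
        fitness = FitnessEvaluator(X, y, lv_min=config.lv_min)
    results = []
    for seed in child_seeds(master_seed, n_runs):
        results.append(evolve(X, y, replace(config, seed=seed), fitness=fitness))
    masks = np.array([r.best_mask for r in results])
    occurrence = 100.0 * masks.mean(axis=0)
    return results, occurrence


def consensus_select(occurrence) -> np.ndarray:
    """Mask of descriptors whose occurrence strictly exceeds the mean occurrence."""
    occ = np.asarray(occurrence, dtype=float)
    mask = (occ > occ.mean()).astype(int)
    if mask.sum() == 0:
        raise ValueError(
            "all occurrences equal the mean; no consensus subset exists - "
            "inspect the occurrence vector and the GA runs"
        )
    return mask


@dataclass
class ConsensusModel:
    """Consensus descriptor subset with its final fitted PLS model."""

    n_runs: int
    occurrence: pd.Series  # % of runs selecting each descriptor
    consensus_mask: np.ndarray
    selected_names: list[str]
    pls: PLSModel
    n_lv: int
    rmsecv_ln: float
    rmsecv_minutes: float
    cv: CVResult = field(repr=False)
    X_train: pd.DataFrame = field(repr=False)
    y_train: pd.Series = field(repr=False)

    @property
    def mean_occurrence(self) -> float:
        return float(self.occurrence.mean())

    @property
    def coefficients(self) -> pd.Series:
        """Autoscaled-scale PLS coefficients of the selected descriptors."""
        return pd.Series(self.pls.coef_scaled, index=self.selected_names)

    def predict(self, X, scale: str = "ln") -> np.ndarray:
        """Predict from a full descriptor matrix (selection applied internally)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_names]
        else:
            X = np.asarray(X, dtype=float)[:, self.consensus_mask.astype(bool)]
        return self.pls.predict(X, scale=scale)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "occurrence": self.occurrence.round(6).to_dict(),
            "mean_occurrence": self.mean_occurrence,
            "consensus_mask": self.consensus_mask.astype(int).tolist(),
            "selected_names": self.selected_names,
            "n_lv": self.n_lv,
            "rmsecv_ln": self.rmsecv_ln,
            "rmsecv_minutes": self.rmsecv_minutes,
            "pls": self.pls.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_consensus(
    X: pd.DataFrame,
    y,
    consensus_mask,
    occurrence=None,
    n_runs: int = 0,
    lv_min: int = 2,
    lv_policy: str = "min",
) -> ConsensusModel:
    """Fit the final SIMPLS model on the consensus descriptor subset.

    The LV count is re-optimized by LOO-CV on the submatrix (``lv_policy``
    "min" or "knee"), then a single model is fitted on all supplied rows
    (the training set).
    """
    mask = np.asarray(consensus_mask, dtype=int)
    if mask.sum() < 2:
        raise ValueError("consensus mask must select at least 2 descriptors")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    names = list(X.columns)
    selected = [n for n, b in zip(names, mask) if b]
    y = pd.Series(np.asarray(y, dtype=float).ravel(), index=X.index, name="ln_t_R")

    Xsub = X[selected]
    cv = loo_cv_curve(Xsub, y, lv_min=lv_min)
    n_lv = select_n_lvs(cv, policy=lv_policy)
    k = cv.lv_candidates.index(n_lv)

    Xs, ys, params = autoscale(Xsub, y)
    model = simpls_fit(Xs, ys, n_lv, scaling=params)
    if occurrence is None:
        occurrence = 100.0 * mask.astype(float)
    occ = pd.Series(np.asarray(occurrence, dtype=float), index=names)
    return ConsensusModel(
        n_runs=n_runs,
        occurrence=occ,
        consensus_mask=mask,
        selected_names=selected,
        pls=model,
        n_lv=n_lv,
        rmsecv_ln=float(cv.rmsecv_ln[k]),
        rmsecv_minutes=float(cv.rmsecv_minutes[k]),
        cv=cv,
        X_train=Xsub.copy(),
        y_train=y.copy(),
    )


def build_consensus(
    X: pd.DataFrame,
    y,
    config: GAConfig | None = None,
    n_runs: int = 1000,
    master_seed: int = 0,
    lv_policy: str = "min",
) -> tuple[ConsensusModel, list[GARunResult]]:
    """Convenience pipeline: repeats -> occurrence -> selection -> final fit."""
    config = config or GAConfig()
    results, occurrence = run_repeats(X, y, config, n_runs, master_seed)
    mask = consensus_select(occurrence)
    model = fit_consensus(
        X, y, mask, occurrence=occurrence, n_runs=n_runs, lv_min=config.lv_min,
        lv_policy=lv_policy,
    )
    return model, results
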