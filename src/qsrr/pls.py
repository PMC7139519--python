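"""Autoscaling, SIMPLS partial least squares, LOO cross-validation, LV selection.

The single-response SIMPLS algorithm (de Jong) deflates the X'y cross-product
directly. Score vectors are normalized to unit length (t't = 1) and are
mutually orthogonal; at full rank the SIMPLS predictions coincide with
ordinary least squares on the autoscaled data.

Cross-validation is leave-one-out: each analyte is predicted from a model
trained on the remaining ones, with autoscaling re-estimated inside each fold
so the held-out row never leaks into the scaling. RMSECV is reported both in
ln units and on the back-transformed minute scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScalingParams",
    "PLSModel",
    "CVResult",
    "autoscale",
    "simpls_fit",
    "pls_predict",
    "loo_cv_curve",
    "select_n_lvs",
    "rmse",
    "average_rmse",
]


@dataclass
class ScalingParams:
    """Column means and sample (n-1) standard deviations for X and y."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    feature_names: list[str] | None = None

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_std

    def unscale_x(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.x_std + self.x_mean

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * self.y_std + self.y_mean


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def autoscale(X, y=None) -> tuple[np.ndarray, np.ndarray | None, ScalingParams]:
    """Center to mean 0 and scale to unit sample SD; errors name the offender."""
    Xa, names = _as_matrix(X)
    if Xa.ndim != 2:
        raise ValueError("X must be 2-D")
    x_mean = Xa.mean(axis=0)
    x_std = Xa.std(axis=0, ddof=1)
    for j, s in enumerate(x_std):
        if not np.isfinite(s) or s == 0:
            label = names[j] if names else f"column {j}"
            raise ValueError(f"zero-variance descriptor: {label}")
    Xs = (Xa - x_mean) / x_std

    ys = None
    y_mean, y_std = 0.0, 1.0
    if y is not None:
        ya = np.asarray(y, dtype=float).ravel()
        y_mean = float(ya.mean())
        y_std = float(ya.std(ddof=1))
        if not np.isfinite(y_std) or y_std == 0:
            raise ValueError("zero-variance response")
        ys = (ya - y_mean) / y_std
    params = ScalingParams(x_mean, x_std, y_mean, y_std, names)
    return Xs, ys, params


@dataclass
class PLSModel:
    """Fitted SIMPLS model with loadings, scores and dual-scale coefficients."""

    n_lv: int
    r_weights: np.ndarray  # p x A, applied to Xs to give scores T
    weights: np.ndarray  # p x A, unit-norm columns (w'w = 1)
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A,
    scores: np.ndarray  # m x A, orthonormal columns
    u_scores: np.ndarray  # m x A
    coef_scaled: np.ndarray  # p, coefficients on the autoscaled scale
    coef_original: np.ndarray  # p, coefficients in original units
    intercept_original: float
    explained_x: np.ndarray  # % X variance per LV
    explained_y: np.ndarray  # % Y variance per LV
    scaling: ScalingParams
    feature_names: list[str] | None = None

    def predict(self, X_new, scale: str = "ln") -> np.ndarray:
        return pls_predict(self, X_new, scale=scale)

    def to_dict(self) -> dict:
        return {
            "n_lv": self.n_lv,
            "feature_names": self.feature_names,
            "coef_scaled": self.coef_scaled.tolist(),
            "coef_original": self.coef_original.tolist(),
            "intercept_original": self.intercept_original,
            "explained_x": self.explained_x.tolist(),
            "explained_y": self.explained_y.tolist(),
            "scaling": {
                "x_mean": self.scaling.x_mean.tolist(),
                "x_std": self.scaling.x_std.tolist(),
                "y_mean": self.scaling.y_mean,
                "y_std": self.scaling.y_std,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _simpls_core(Xs: np.ndarray, ys: np.ndarray, n_lv: int):
    """de Jong SIMPLS for a single response on autoscaled data."""
    m, p = Xs.shape
    R = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    V = np.zeros((p, n_lv))
    T = np.zeros((m, n_lv))
    U = np.zeros((m, n_lv))
    q = np.zeros(n_lv)

    s = Xs.T @ ys
    for a in range(n_lv):
        r = s.copy()
        t = Xs @ r
        norm_t = np.linalg.norm(t)
        if norm_t <= 1e-12 * max(1.0, np.linalg.norm(Xs)):
            # cross-product exhausted (e.g. y orthogonal to X): remaining
            # components carry no covariance; freeze coefficients here
            R, P, V, T, U = R[:, :a], P[:, :a], V[:, :a], T[:, :a], U[:, :a]
            q = q[:a]
            break
        t /= norm_t
        r /= norm_t
        p_load = Xs.T @ t
        q_a = float(ys @ t)
        u = ys * q_a
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
            u -= T[:, :a] @ (T[:, :a].T @ u)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a], P[:, a], V[:, a], T[:, a], U[:, a], q[a] = r, p_load, v, t, u, q_a
    return R, P, T, U, q


def simpls_fit(Xs, ys, n_lv: int, scaling: ScalingParams | None = None) -> PLSModel:
    """Fit SIMPLS with ``n_lv`` latent variables on autoscaled (Xs, ys).

    ``scaling`` carries the autoscale parameters so predictions can be
    returned in original units; when omitted, identity scaling is assumed.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    m, p = Xs.shape
    rank = np.linalg.matrix_rank(Xs)
    if not 1 <= n_lv <= rank:
        raise ValueError(f"n_lv must be in [1, rank(X)={rank}], got {n_lv}")

    R, P, T, U, q = _simpls_core(Xs, ys, n_lv)
    coef_scaled = R @ q

    if scaling is None:
        scaling = ScalingParams(
            np.zeros(p), np.ones(p), 0.0, 1.0, feature_names=None
        )
    coef_original = scaling.y_std * coef_scaled / scaling.x_std
    intercept = scaling.y_mean - float(coef_original @ scaling.x_mean)

    ss_x = float(np.sum(Xs * Xs))
    ss_y = float(ys @ ys)
    explained_x = 100.0 * np.sum(P * P, axis=0) / ss_x
    explained_y = 100.0 * q * q / ss_y

    norms = np.linalg.norm(R, axis=0)
    return PLSModel(
        n_lv=n_lv,
        r_weights=R,
        weights=R / norms,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        u_scores=U,
        coef_scaled=coef_scaled,
        coef_original=coef_original,
        intercept_original=intercept,
        explained_x=explained_x,
        explained_y=explained_y,
        scaling=scaling,
        feature_names=scaling.feature_names,
    )


def pls_predict(model: PLSModel, X_new, scale: str = "ln") -> np.ndarray:
    """Predict ln-retention (``scale="ln"``) or minutes (``scale="minutes"``).

    Applies the training ScalingParams; never re-estimates scaling from
    ``X_new``.
    """
    Xa, names = _as_matrix(X_new)
    if Xa.ndim == 1:
        Xa = Xa[None, :]
    p = model.scaling.x_mean.size
    if Xa.shape[1] != p:
        raise ValueError(f"expected {p} descriptor columns, got {Xa.shape[1]}")
    if names and model.feature_names and names != model.feature_names:
        raise ValueError("descriptor columns do not match the training matrix")
    Xs = model.scaling.scale_x(Xa)
    y_ln = model.scaling.unscale_y(Xs @ model.coef_scaled)
    if scale == "ln":
        return y_ln
    if scale == "minutes":
        return np.exp(y_ln)
    raise ValueError(f"unknown scale {scale!r}")


@dataclass
class CVResult:
    """LOO RMSECV per candidate LV count, on ln and minute scales."""

    lv_candidates: list[int]
    rmsecv_ln: np.ndarray
    rmsecv_minutes: np.ndarray
    predictions_ln: np.ndarray = field(repr=False)  # m x n_candidates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_lv": self.lv_candidates,
                "rmsecv_ln": self.rmsecv_ln,
                "rmsecv_min": self.rmsecv_minutes,
            }
        )


def loo_predictions(X, y, lv_candidates: list[int]) -> np.ndarray:
    """LOO-CV predictions (ln scale), one column per candidate LV count.

    Autoscaling is re-estimated inside each fold; candidates exceeding a
    fold's rank are capped at that rank (the SIMPLS deflation exhausts the
    cross-product there, freezing the coefficients). All folds run as one
    batched SIMPLS so the routine stays fast inside GA fitness loops.
    A descriptor that is constant within some fold contributes nothing to
    that fold's model rather than aborting the run.
    """
    Xa, _ = _as_matrix(X)
    ya = np.asarray(y, dtype=float).ravel()
    m, p = Xa.shape
    if m < 3:
        raise ValueError("need at least 3 analytes for LOO-CV")
    n = m - 1
    a_max = min(max(lv_candidates), p, n - 1)
    a_max = max(a_max, 1)

    idx = np.arange(m)
    keep = np.stack([np.delete(idx, i) for i in range(m)])  # (m, n)
    Xf = Xa[keep]  # (m, n, p)
    yf = ya[keep]  # (m, n)

    x_mean = Xf.mean(axis=1, keepdims=True)
    x_sd = Xf.std(axis=1, ddof=1, keepdims=True)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Z = (Xf - x_mean) / x_sd
    y_mean = yf.mean(axis=1)
    y_sd = yf.std(axis=1, ddof=1)
    y_sd = np.where(y_sd > 0, y_sd, 1.0)
    zy = (yf - y_mean[:, None]) / y_sd[:, None]
    x_held = (Xa - x_mean[:, 0, :]) / x_sd[:, 0, :]  # (m, p) scaled held-out rows

    eps = 1e-10
    s = np.einsum("fnp,fn->fp", Z, zy)
    V = np.zeros((m, p, a_max))
    coef = np.zeros((m, p))
    preds_all = np.empty((m, a_max))
    for a in range(a_max):
        r = s.copy()
        t = np.einsum("fnp,fp->fn", Z, r)
        norm_t = np.linalg.norm(t, axis=1)
        alive = norm_t > eps
        safe = np.where(alive, norm_t, 1.0)[:, None]
        t = np.where(alive[:, None], t / safe, 0.0)
        r = np.where(alive[:, None], r / safe, 0.0)
        p_load = np.einsum("fnp,fn->fp", Z, t)
        q = np.einsum("fn,fn->f", zy, t)
        v = p_load.copy()
        if a > 0:
            proj = np.einsum("fpa,fp->fa", V[:, :, :a], p_load)
            v -= np.einsum("fpa,fa->fp", V[:, :, :a], proj)
        norm_v = np.linalg.norm(v, axis=1)
        safe_v = np.where(norm_v > eps, norm_v, 1.0)[:, None]
        v = np.where((norm_v > eps)[:, None], v / safe_v, 0.0)
        s = s - v * np.einsum("fp,fp->f", v, s)[:, None]
        V[:, :, a] = v
        coef += r * q[:, None]
        preds_all[:, a] = y_mean + y_sd * np.einsum("fp,fp->f", x_held, coef)

    preds = np.empty((m, len(lv_candidates)))
    for k, a in enumerate(lv_candidates):
        preds[:, k] = preds_all[:, min(a, a_max) - 1]
    return preds


def loo_cv_curve(X, y, max_lv: int | None = None, lv_min: int = 1) -> CVResult:
    """RMSECV over candidate LV counts ``lv_min..max_lv`` by leave-one-out CV."""
    Xa, _ = _as_matrix(X)
    ya = np.asarray(y, dtype=float).ravel()
    rank = int(np.linalg.matrix_rank(Xa - Xa.mean(axis=0)))
    if max_lv is None:
        max_lv = rank
    max_lv = min(max_lv, rank)
    lv_min = max(1, min(lv_min, max_lv))
    candidates = list(range(lv_min, max_lv + 1))
    preds = loo_predictions(Xa, ya, candidates)
    rmse_ln = np.sqrt(np.mean((preds - ya[:, None]) ** 2, axis=0))
    rmse_min = np.sqrt(np.mean((np.exp(preds) - np.exp(ya)[:, None]) ** 2, axis=0))
    return CVResult(candidates, rmse_ln, rmse_min, preds)


def select_n_lvs(cv: CVResult, policy: str = "knee", tol: float = 0.02) -> int:
    """Pick the LV count from an RMSECV curve.

    ``"knee"`` (default): walk the curve and stop at the first LV whose gain
    from adding the next LV, relative to the first candidate's RMSECV, falls
    below ``tol``. ``"min"``: argmin RMSECV (ties toward fewer LVs).
    """
    if not cv.lv_candidates:
        raise ValueError("empty CV curve")
    r = np.asarray(cv.rmsecv_ln, dtype=float)
    if policy == "min":
        return cv.lv_candidates[int(np.argmin(r))]
    if policy != "knee":
        raise ValueError(f"unknown policy {policy!r}")
    base = r[0] if r[0] > 0 else 1.0
    for k in range(len(r) - 1):
        if (r[k] - r[k + 1]) / base < tol:
            return cv.lv_candidates[k]
    return cv.lv_candidates[-1]


def rmse(pred, obs) -> float:
    """Root mean square error."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size == 0 or pred.shape != obs.shape:
        raise ValueError("pred and obs must be non-empty and of equal length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def average_rmse(rmse_train: float, rmse_validation: float) -> float:
    """Arithmetic mean of the training-set and validation-set RMSEs."""
    return 0.5 * (rmse_train + rmse_validation)
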