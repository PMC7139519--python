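"""External validation, CV-ANOVA significance, and applicability-domain diagnostics.

CV-ANOVA partitions the total sum of squares of the training response into a
fit part and the cross-validated predictive residual part; the F ratio of
their mean squares measures whether the cross-validated model predicts better
than the response mean. The applicability domain is the Williams plot:
leverage (distance from the descriptor-space centroid through the hat matrix)
against standardized residuals, bounded by the critical leverage
h* = 3(n + 1)/m and a +/-3 SD residual band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusModel
from .pls import average_rmse, rmse

__all__ = [
    "AnovaTable",
    "cv_anova",
    "external_validate",
    "leverages",
    "critical_leverage",
    "ADResult",
    "applicability_domain",
]

_ANOVA_TOL = 1e-9


@dataclass
class AnovaTable:
    """Total/Fit/Residual decomposition with F statistic and p-value.

    Internal identities (SS and df additivity, MS = SS/df, F = MS ratio) are
    asserted on construction; ``check`` revalidates at any tolerance, e.g.
    for tables transcribed at print precision.
    """

    ss_total: float
    df_total: int
    ss_fit: float
    df_fit: int
    ss_residual: float
    df_residual: int
    F: float
    p_value: float
    df_policy: str = "lv2"

    def __post_init__(self) -> None:
        self.check(tol=_ANOVA_TOL)

    @property
    def ms_total(self) -> float:
        return self.ss_total / self.df_total

    @property
    def ms_fit(self) -> float:
        return self.ss_fit / self.df_fit

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    def check(self, tol: float = _ANOVA_TOL) -> None:
        """Assert SS additivity, df additivity and the F = MS ratio to ``tol``."""
        if abs(self.ss_total - (self.ss_fit + self.ss_residual)) > tol * max(
            1.0, abs(self.ss_total)
        ):
            raise ValueError("SS_Total != SS_Fit + SS_Residual")
        if self.df_total != self.df_fit + self.df_residual:
            raise ValueError("df_Total != df_Fit + df_Residual")
        if np.isfinite(self.F) and self.ss_residual > 0:
            if abs(self.F - self.ms_fit / self.ms_residual) > tol * max(1.0, self.F):
                raise ValueError("F != MS_Fit / MS_Residual")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Source": ["Total", "Fit", "Residual"],
                "SS": [self.ss_total, self.ss_fit, self.ss_residual],
                "df": [self.df_total, self.df_fit, self.df_residual],
                "MS": [self.ms_total, self.ms_fit, self.ms_residual],
                "F": [self.F, np.nan, np.nan],
                "Prob>F": [self.p_value, np.nan, np.nan],
            }
        )


def cv_anova(
    y_true,
    y_loocv_pred,
    n_lv: int | None = None,
    df_policy="lv2",
    n_descriptors: int | None = None,
) -> AnovaTable:
    """CV-ANOVA table from training responses and their LOO-CV predictions.

    ``df_policy`` sets the Fit degrees of freedom: ``"lv2"`` (default) uses
    2 * n_LV, ``"n_descriptors"`` uses the descriptor count, or pass an
    explicit integer. The policy used is recorded on the table.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    yhat = np.asarray(y_loocv_pred, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("y_true and y_loocv_pred must be equal-length, m >= 3")
    m = y.size

    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_residual = float(np.sum((y - yhat) ** 2))
    ss_fit = ss_total - ss_residual
    if ss_fit < 0:
        warnings.warn(
            "cross-validated predictions are worse than the mean; SS_Fit floored at 0",
            stacklevel=2,
        )
        ss_fit = 0.0
        ss_residual = ss_total

    if isinstance(df_policy, (int, np.integer)):
        df_fit, policy_name = int(df_policy), f"explicit:{int(df_policy)}"
    elif df_policy == "lv2":
        if n_lv is None:
            raise ValueError('df_policy "lv2" requires n_lv')
        df_fit, policy_name = 2 * int(n_lv), "lv2"
    elif df_policy == "n_descriptors":
        if n_descriptors is None:
            raise ValueError('df_policy "n_descriptors" requires n_descriptors')
        df_fit, policy_name = int(n_descriptors), "n_descriptors"
    else:
        raise ValueError(f"unknown df_policy {df_policy!r}")

    df_total = m - 1
    df_residual = df_total - df_fit
    if df_residual < 1:
        raise ValueError("df_Residual < 1; too few training analytes for the policy")

    if ss_residual == 0:
        F, p = float("inf"), 0.0
    else:
        F = (ss_fit / df_fit) / (ss_residual / df_residual)
        p = float(stats.f.sf(F, df_fit, df_residual))
    return AnovaTable(
        ss_total, df_total, ss_fit, df_fit, ss_residual, df_residual, F, p,
        df_policy=policy_name,
    )


def external_validate(model: ConsensusModel, X_val, y_val) -> dict[str, float]:
    """Training / validation / averaged RMSE on ln and minute scales."""
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_val.size == 0:
        raise ValueError("empty validation set")
    yhat_train = model.predict(model.X_train)
    yhat_val = model.predict(X_val)
    y_train = model.y_train.to_numpy()
    out = {
        "RMSE_train_ln": rmse(yhat_train, y_train),
        "RMSE_val_ln": rmse(yhat_val, y_val),
        "RMSE_train_min": rmse(np.exp(yhat_train), np.exp(y_train)),
        "RMSE_val_min": rmse(np.exp(yhat_val), np.exp(y_val)),
    }
    out["RMSE_avg_ln"] = average_rmse(out["RMSE_train_ln"], out["RMSE_val_ln"])
    out["RMSE_avg_min"] = average_rmse(out["RMSE_train_min"], out["RMSE_val_min"])
    return out


def leverages(X_train_scaled, X_query_scaled) -> np.ndarray:
    """Diagonal of X2 (X1'X1)^-1 X2' for query rows against the training matrix.

    Inputs must already be autoscaled with the *training* scaling and
    restricted to the modeled descriptor subset. A singular cross-product
    falls back to the Moore-Penrose pseudo-inverse with a warning.
    """
    X1 = np.atleast_2d(np.asarray(X_train_scaled, dtype=float))
    X2 = np.atleast_2d(np.asarray(X_query_scaled, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("training and query matrices differ in column count")
    gram = X1.T @ X1
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("singular X'X; using pseudo-inverse", stacklevel=2)
        ginv = np.linalg.pinv(gram)
    return np.einsum("ij,jk,ik->i", X2, ginv, X2)


def critical_leverage(n_descriptors: int, m_train: int) -> float:
    """Warning-limit leverage h* = 3(n + 1)/m.

    ``n`` is the number of molecular descriptors in the model and ``m`` the
    training-set size.
    """
    if n_descriptors < 1 or m_train < 1:
        raise ValueError("counts must be >= 1")
    return 3.0 * (n_descriptors + 1) / m_train


@dataclass
class ADResult:
    """Williams-plot data: leverages, standardized residuals, and flags."""

    table: pd.DataFrame  # analyte_id, set, h, std_residual, flags
    h_star: float
    residual_limit: float
    train_residual_sd: float

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]

    @property
    def high_leverage(self) -> pd.DataFrame:
        return self.table[self.table["high_leverage"]]


def applicability_domain(
    model: ConsensusModel,
    X_train: pd.DataFrame | None = None,
    y_train=None,
    X_query: pd.DataFrame | None = None,
    y_query=None,
    residual_limit: float = 3.0,
) -> ADResult:
    """Williams-plot applicability domain for training and query analytes.

    Standardized residuals divide fitted residuals by the training-residual
    SD (the same denominator for both sets). Flags: |std residual| >
    ``residual_limit`` marks an outlier, leverage > h* marks high leverage;
    ``in_domain`` requires neither.
    """
    if X_train is None:
        X_train, y_train = model.X_train, model.y_train
    X_train = X_train[model.selected_names] if isinstance(X_train, pd.DataFrame) else X_train
    y_train = np.asarray(y_train, dtype=float).ravel()

    scaling = model.pls.scaling
    X1s = scaling.scale_x(np.asarray(X_train, dtype=float))
    resid_train = y_train - model.pls.predict(X_train)
    sd = float(np.std(resid_train, ddof=1))
    if sd == 0:
        raise ValueError("zero training-residual SD; standardized residuals undefined")

    m_train, n_sel = X1s.shape
    h_star = critical_leverage(n_sel, m_train)

    def block(X, y, label):
        Xsel = X[model.selected_names] if isinstance(X, pd.DataFrame) else X
        ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(y)))
        h = leverages(X1s, scaling.scale_x(np.asarray(Xsel, dtype=float)))
        std_resid = (np.asarray(y, dtype=float).ravel() - model.pls.predict(Xsel)) / sd
        return pd.DataFrame(
            {
                "analyte_id": ids,
                "set": label,
                "h": h,
                "std_residual": std_resid,
            }
        )

    frames = [block(X_train, y_train, "train")]
    if X_query is not None:
        frames.append(block(X_query, np.asarray(y_query, dtype=float), "query"))
    table = pd.concat(frames, ignore_index=True)
    table["high_leverage"] = table["h"] > h_star
    table["outlier"] = table["std_residual"].abs() > residual_limit
    table["in_domain"] = ~(table["high_leverage"] | table["outlier"])
    return ADResult(table, h_star, residual_limit, sd)
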