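"""Dataset container, retention transform, column similarity, Kennard-Stone split.

Retention times (minutes) are modeled on the natural-log scale, which brings
their distribution much closer to normal. Column-to-column similarity is
summarized by Pearson correlation with a two-tailed significance test.
The train/validation split uses the deterministic Kennard-Stone max-min
distance algorithm on autoscaled descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "ln_transform",
    "inverse_ln_transform",
    "CorrelationResult",
    "pearson_with_test",
    "correlation_matrix",
    "kennard_stone_split",
    "QSRRDataset",
    "read_retention",
]

TRAIN = "train"
VALIDATION = "validation"


def ln_transform(t_r):
    """Natural log of retention time (minutes). Requires t_R > 0."""
    arr = np.asarray(t_r, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("retention times must be finite and > 0")
    out = np.log(arr)
    return float(out) if np.isscalar(t_r) else out


def inverse_ln_transform(ln_t_r):
    """Back-transform ln-retention to minutes."""
    out = np.exp(np.asarray(ln_t_r, dtype=float))
    return float(out) if np.isscalar(ln_t_r) else out


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson R with its two-tailed p-value and sample size."""

    R: float
    p_value: float
    n: int


def pearson_with_test(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the two-tailed t-test significance.

    The p-value is the two-tailed tail mass of t = R sqrt((n-2)/(1-R^2))
    under Student's t with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def correlation_matrix(retention: pd.DataFrame, log_scale: bool = False) -> pd.DataFrame:
    """Pairwise column-similarity table for a wide retention table.

    ``retention`` has one row per analyte and one column per chromatographic
    column (minutes). Returns a long table (column_a, column_b, R, p_value, n)
    over unordered column pairs.
    """
    cols = list(retention.columns)
    values = retention if not log_scale else np.log(retention)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = pd.DataFrame({"a": values[a], "b": values[b]}).dropna()
            res = pearson_with_test(pair["a"].to_numpy(), pair["b"].to_numpy())
            rows.append(
                dict(column_a=a, column_b=b, R=res.R, p_value=res.p_value, n=res.n)
            )
    return pd.DataFrame(rows)


def kennard_stone_split(X, train_fraction: float) -> np.ndarray:
    """Deterministic Kennard-Stone labels (``train``/``validation``) per row.

    Distances are Euclidean on autoscaled columns. The first two training
    picks are the maximum-distance pair; each subsequent pick maximizes its
    minimum distance to the already-picked set. Ties break toward the lowest
    row index. ``round(train_fraction * m)`` rows become training.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m = X.shape[0]
    if m < 3:
        raise ValueError("need at least 3 rows")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * m))
    n_train = min(max(n_train, 2), m - 1)

    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    D = squareform(pdist(Z))

    # max-distance pair; ties resolve to the row-major first occurrence
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(m) if k not in selected]
    while len(selected) < n_train:
        dmin = D[np.ix_(remaining, selected)].min(axis=1)
        nxt = remaining[int(np.argmax(dmin))]
        selected.append(nxt)
        remaining.remove(nxt)

    labels = np.full(m, VALIDATION, dtype=object)
    labels[selected] = TRAIN
    return labels


@dataclass
class QSRRDataset:
    """Descriptor matrix X, ln-retention y, and train/validation membership."""

    X: pd.DataFrame
    y: pd.Series
    split: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index) or not self.X.index.equals(
            self.split.index
        ):
            raise ValueError("X, y and split must share the same analyte index")
        bad = set(self.split.unique()) - {TRAIN, VALIDATION}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.X.columns)

    def _subset(self, label: str) -> tuple[pd.DataFrame, pd.Series]:
        keep = self.split == label
        return self.X.loc[keep], self.y.loc[keep]

    @property
    def train(self) -> tuple[pd.DataFrame, pd.Series]:
        return self._subset(TRAIN)

    @property
    def validation(self) -> tuple[pd.DataFrame, pd.Series]:
        return self._subset(VALIDATION)

    def dropna(self, columns=None) -> "QSRRDataset":
        """Drop analytes with missing values in ``columns`` (default: any)."""
        sub = self.X[list(columns)] if columns is not None else self.X
        keep = sub.notna().all(axis=1)
        return QSRRDataset(self.X.loc[keep], self.y.loc[keep], self.split.loc[keep])

    def to_csv(self, dataset_path, split_path=None) -> None:
        merged = self.X.copy()
        merged["ln_t_R"] = self.y
        merged.to_csv(dataset_path, index=True, float_format="%.10g")
        if split_path is not None:
            self.split.rename("label").to_csv(split_path, index=True)

    @classmethod
    def from_csv(cls, dataset_path, split_path) -> "QSRRDataset":
        merged = pd.read_csv(dataset_path, index_col="analyte_id")
        split = pd.read_csv(split_path, index_col="analyte_id")["label"]
        y = merged["ln_t_R"]
        X = merged.drop(columns=["ln_t_R"])
        return cls(X, y.rename("ln_t_R"), split.reindex(X.index))

    @classmethod
    def from_tables(
        cls,
        descriptors: pd.DataFrame,
        retention_min: pd.Series,
        train_fraction: float = 0.7,
        exclude: list[str] | None = None,
    ) -> "QSRRDataset":
        """Merge a descriptor matrix and a retention series, split by Kennard-Stone.

        ``retention_min`` is in minutes; analytes listed in ``exclude`` (or
        missing in either table) are dropped before splitting.
        """
        ids = descriptors.index.intersection(retention_min.dropna().index)
        if exclude:
            ids = ids.difference(pd.Index(exclude))
        X = descriptors.loc[ids]
        y = pd.Series(ln_transform(retention_min.loc[ids].to_numpy()), index=ids,
                      name="ln_t_R")
        complete = X.notna().all(axis=1)
        labels = pd.Series(
            kennard_stone_split(X.loc[complete].to_numpy(), train_fraction),
            index=X.index[complete],
        )
        # analytes with missing descriptors stay out of training
        split = labels.reindex(X.index, fill_value=VALIDATION).rename("label")
        return cls(X, y, split)


def read_retention(path) -> pd.DataFrame:
    """Read long-format ``retention.csv`` (analyte_id, column_name, t_R_min).

    Returns a wide table (analyte x chromatographic column, minutes).
    """
    df = pd.read_csv(path, dtype={"analyte_id": str})
    required = {"analyte_id", "column_name", "t_R_min"}
    if missing := required - set(df.columns):
        raise ValueError(f"retention table missing columns: {sorted(missing)}")
    return df.pivot(index="analyte_id", columns="column_name", values="t_R_min")
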