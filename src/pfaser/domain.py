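"""Applicability domain: leverage, standardized residuals, Williams plots.

A prediction is trusted only inside the region of descriptor space the
model was trained on.  Two diagnostics delimit that region:

* leverage h_i, the diagonal of the hat (projection) matrix of the training
  design, compared against the critical value h* = 3(M+1)/N for M
  descriptors and N training compounds;
* the standardized residual, residual / s with s the training residual SD,
  with |r| > 3 flagging a poorly predicted compound.

Query compounds get the quadratic-form leverage x'(X'X)^-1 x under the
training design (no refit), the standard Williams-plot practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .qspr import LinearModel, _design, _check_rank, predict

__all__ = [
    "DomainClass",
    "ADResult",
    "critical_leverage",
    "leverages",
    "standardized_residuals",
    "williams_classify",
    "applicability_domain",
]


class DomainClass(str, Enum):
    IN_DOMAIN = "in_domain"
    RESIDUAL_OUTLIER = "residual_outlier"
    LEVERAGE_OUTLIER = "leverage_outlier"
    BOTH = "both"


def critical_leverage(M: int, N: int) -> float:
    """Critical leverage h* = 3(M+1)/N."""
    if M < 1:
        raise ValueError("need at least one descriptor")
    if N < M + 2:
        raise ValueError("need N >= M + 2 training compounds")
    return 3.0 * (M + 1) / N


def _hat_inverse(X_train: pd.DataFrame) -> np.ndarray:
    A = _design(X_train)
    _check_rank(A, list(X_train.columns))
    return np.linalg.inv(A.T @ A)


def leverages(
    X_train: pd.DataFrame, X_query: pd.DataFrame | None = None
) -> pd.Series:
    """Hat-diagonal leverage of training points, or of query points.

    Training leverages lie in (0, 1] and sum to M+1; query leverage is the
    quadratic form x'(X'X)^-1 x with intercept augmentation and may exceed 1.
    """
    n, m = X_train.shape
    if n <= m + 1:
        raise ValueError("need training rows > descriptors + 1")
    inv = _hat_inverse(X_train)
    target = X_train if X_query is None else X_query
    B = _design(target, list(X_train.columns))
    h = np.einsum("ij,jk,ik->i", B, inv, B)
    return pd.Series(h, index=target.index, name="leverage")


def standardized_residuals(
    model: LinearModel, X: pd.DataFrame, y, scale: float | None = None
) -> pd.Series:
    """Residuals divided by the training residual SD.

    ``scale`` defaults to the model's stored s = sqrt(RSS/(N-M-1)); the same
    scale is applied to external points so residuals are comparable across
    train and query sets.  A zero scale (perfect training fit) is an error.
    """
    s = model.residual_sd if scale is None else scale
    if s is None:
        raise ValueError("model has no stored residual SD; pass scale=")
    if s <= 0 or not np.isfinite(s):
        raise ValueError("degenerate fit: residual scale is zero")
    resid = np.asarray(y, dtype=float) - predict(model, X).to_numpy()
    return pd.Series(resid / s, index=X.index, name="std_residual")


def williams_classify(
    leverage: pd.Series,
    std_residual: pd.Series,
    h_star: float,
    residual_limit: float = 3.0,
) -> pd.Series:
    """Four-way domain classification per ligand.

    Outliers require strict inequality: |r| > residual_limit and/or
    h > h*; boundary points count as in-domain.
    """
    if not leverage.index.equals(std_residual.index):
        raise ValueError("leverage and residual series must share an index")
    res_out = std_residual.abs() > residual_limit
    lev_out = leverage > h_star
    cls = np.where(
        res_out & lev_out,
        DomainClass.BOTH.value,
        np.where(
            res_out,
            DomainClass.RESIDUAL_OUTLIER.value,
            np.where(lev_out, DomainClass.LEVERAGE_OUTLIER.value, DomainClass.IN_DOMAIN.value),
        ),
    )
    return pd.Series(cls, index=leverage.index, name="domain_class")


@dataclass
class ADResult:
    """Williams-plot ingredients plus the per-ligand classification."""

    leverage: pd.Series
    std_residual: pd.Series
    h_star: float
    classification: pd.Series

    @property
    def counts(self) -> dict[str, int]:
        base = {c.value: 0 for c in DomainClass}
        base.update(self.classification.value_counts().to_dict())
        return base

    def plot_data(self) -> pd.DataFrame:
        """Tidy frame for external Williams-plot renderers."""
        return pd.DataFrame(
            {
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "domain_class": self.classification,
            }
        )


def applicability_domain(
    model: LinearModel,
    X_train: pd.DataFrame,
    y_train,
    X_query: pd.DataFrame | None = None,
    y_query=None,
    residual_limit: float = 3.0,
) -> ADResult:
    """Full domain analysis for the training set or an external query set.

    h* always comes from the actual training dimensions supplied, never a
    hard-coded size.
    """
    Xt = X_train[model.descriptor_names]
    h_star = critical_leverage(len(model.descriptor_names), len(Xt))
    if X_query is None:
        lev = leverages(Xt)
        res = standardized_residuals(model, X_train, y_train)
    else:
        if y_query is None:
            raise ValueError("y_query required with X_query")
        lev = leverages(Xt, X_query[model.descriptor_names])
        res = standardized_residuals(model, X_query, y_query)
    cls = williams_classify(lev, res, h_star, residual_limit)
    return ADResult(lev, res, h_star, cls)
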