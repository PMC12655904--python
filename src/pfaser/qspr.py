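"""Multiple-linear-regression QSPR/QSAR models on descriptor tables.

Models map a ligand's descriptor vector to pIC50 through an ordinary
least-squares fit with intercept:

    pIC50 = b0 + sum_j b_j x_j

The four published receptor/dataset equations (top-binder and
commonly-exposed sets for the estrogen receptors alpha and beta) ship as
fixture models loadable by name.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "FitMetrics",
    "LinearModel",
    "fit_ols",
    "predict",
    "evaluate",
    "cross_validate_q2",
    "normalize_coefficients",
    "denormalize_coefficients",
    "load_published_model",
    "PUBLISHED_MODEL_NAMES",
]

#: Canonical names of the four packaged equations.  TB = top binders,
#: CE = commonly exposed; ERalpha/ERbeta are the receptor subtypes.
PUBLISHED_MODEL_NAMES = ("TB-ERalpha", "TB-ERbeta", "CE-ERalpha", "CE-ERbeta")

_NAME_ALIASES = {
    "tb-eralpha": "TB-ERalpha",
    "tb-era": "TB-ERalpha",
    "tb-erα": "TB-ERalpha",
    "tb-erbeta": "TB-ERbeta",
    "tb-erb": "TB-ERbeta",
    "tb-erβ": "TB-ERbeta",
    "ce-eralpha": "CE-ERalpha",
    "ce-era": "CE-ERalpha",
    "ce-erα": "CE-ERalpha",
    "ce-erbeta": "CE-ERbeta",
    "ce-erb": "CE-ERbeta",
    "ce-erβ": "CE-ERbeta",
}


@dataclass
class FitMetrics:
    """Goodness-of-fit numbers in pIC50 units.

    ``r2`` is NaN when the target has zero variance (undefined, never 1).
    """

    r2: float
    rmse: float
    mae: float
    q2: float | None = None


@dataclass
class LinearModel:
    """A fitted (or published) linear descriptor -> pIC50 model."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    descriptor_sds: np.ndarray | None = None
    normalized_coefficients: np.ndarray | None = None
    coef_standard_errors: np.ndarray | None = None
    residual_sd: float | None = None
    training_ids: list | None = None
    metrics: FitMetrics | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(self.descriptor_names):
            raise ValueError("coefficient count must equal descriptor count")
        for attr in ("descriptor_sds", "normalized_coefficients", "coef_standard_errors"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        d = dict(d)
        metrics = d.pop("metrics", None)
        if isinstance(metrics, dict):
            metrics = FitMetrics(**metrics)
        return cls(metrics=metrics, **d)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        return cls.from_dict(json.loads(text))


def _design(X: pd.DataFrame, names: list[str] | None = None) -> np.ndarray:
    if names is not None:
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        X = X[names]
    M = X.to_numpy(dtype=float)
    return np.column_stack([np.ones(M.shape[0]), M])


def _check_rank(A: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR localizes the dependent columns for the error message
        _, _, piv = sla.qr(A, pivoting=True, mode="economic")
        dep = sorted(piv[rank:])
        cols = ["(intercept)"] + list(names)
        bad = [cols[j] for j in dep]
        raise np.linalg.LinAlgError(f"rank-deficient design; dependent columns: {bad}")


def fit_ols(X: pd.DataFrame, y) -> LinearModel:
    """Ordinary least squares of pIC50 on all columns of ``X``, with intercept.

    Stores coefficient standard errors and the residual SD
    s = sqrt(RSS / (N - M - 1)) needed by domain diagnostics.
    """
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n <= m + 1:
        raise ValueError(f"need more than {m + 1} rows to fit {m} descriptors")
    if y.shape != (n,):
        raise ValueError("y length must match table rows")
    A = _design(X)
    _check_rank(A, list(X.columns))
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    dof = n - m - 1
    s2 = rss / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    ses = np.sqrt(np.diag(cov))[1:]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - rss / ss_tot
    metrics = FitMetrics(
        r2=r2,
        rmse=math.sqrt(rss / n),
        mae=float(np.abs(resid).mean()),
    )
    return LinearModel(
        descriptor_names=list(X.columns),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        coef_standard_errors=ses,
        residual_sd=math.sqrt(s2),
        training_ids=list(X.index),
        metrics=metrics,
    )


def predict(model: LinearModel, X: pd.DataFrame) -> pd.Series:
    """Evaluate the model row-wise; ``X`` may carry extra columns."""
    A = _design(X, model.descriptor_names)
    vals = A @ np.concatenate([[model.intercept], model.coefficients])
    return pd.Series(vals, index=X.index, name="pIC50_pred")


def evaluate(model: LinearModel, X: pd.DataFrame, y) -> FitMetrics:
    """R^2 (about the mean of y), RMSE and MAE of the model on (X, y)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    resid = y - predict(model, X).to_numpy()
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return FitMetrics(
        r2=r2,
        rmse=math.sqrt(ss_res / y.size),
        mae=float(np.abs(resid).mean()),
    )


def cross_validate_q2(X: pd.DataFrame, y, method: str = "press") -> float:
    """Leave-one-out Q^2 = 1 - PRESS / SS_tot.

    ``method="press"`` uses the exact algebraic shortcut through leverages
    (deleted residual = e_i / (1 - h_ii)); ``method="refit"`` refits n times.
    The two agree to numerical precision for full-rank designs.
    """
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n <= m + 2:
        raise ValueError("need rows > descriptors + 2 for leave-one-out")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("zero-variance target: Q^2 undefined")
    if method == "press":
        A = _design(X)
        _check_rank(A, list(X.columns))
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        h = np.einsum("ij,jk,ik->i", A, np.linalg.inv(A.T @ A), A)
        press = float(((resid / (1.0 - h)) ** 2).sum())
    elif method == "refit":
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            model = fit_ols(X.iloc[keep], y[keep])
            pred = predict(model, X.iloc[[i]]).to_numpy()[0]
            press += (y[i] - pred) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return 1.0 - press / ss_tot


def normalize_coefficients(
    model: LinearModel, descriptor_sds, y_sd: float | None = None
) -> LinearModel:
    """Attach scale-adjusted coefficients: normalized_j = raw_j * sd_j.

    An optional division by the response SD (``y_sd``) yields fully
    standardized betas; the default convention multiplies by the descriptor
    SD only, so a normalized coefficient reads as the pIC50 change per one
    SD of the descriptor.  The intercept is unchanged and the map inverts
    exactly.
    """
    sds = np.asarray(descriptor_sds, dtype=float)
    if sds.shape != model.coefficients.shape:
        raise ValueError("descriptor_sds must align with coefficients")
    if np.any(sds <= 0):
        raise ValueError("descriptor SDs must be positive")
    norm = model.coefficients * sds
    if y_sd is not None:
        if y_sd <= 0:
            raise ValueError("y_sd must be positive")
        norm = norm / y_sd
    out = LinearModel(**{**model.__dict__})
    out.descriptor_sds = sds
    out.normalized_coefficients = norm
    return out


def denormalize_coefficients(model: LinearModel) -> np.ndarray:
    """Recover raw coefficients from normalized ones (exact inverse)."""
    if model.normalized_coefficients is None or model.descriptor_sds is None:
        raise ValueError("model carries no normalized coefficients")
    return model.normalized_coefficients / model.descriptor_sds


def load_published_model(name: str) -> LinearModel:
    """Load one of the four packaged receptor/dataset equations by name.

    Accepts ``TB-ERalpha``, ``TB-ERbeta``, ``CE-ERalpha``, ``CE-ERbeta``
    (case-insensitive; the Greek-letter and short -ERa/-ERb spellings are
    also accepted).  Coefficients are the published raw values at 4-decimal
    precision; the normalized column and the implied descriptor SDs
    (normalized/raw) ride along for reference.
    """
    key = _NAME_ALIASES.get(name.lower())
    if key is None:
        raise KeyError(
            f"unknown model {name!r}; expected one of {PUBLISHED_MODEL_NAMES}"
        )
    text = (
        resources.files("pfaser").joinpath("data/published_models.json").read_text()
    )
    spec = json.loads(text)[key]
    raw = np.array(spec["coefficients"], dtype=float)
    norm = np.array(spec["normalized_coefficients"], dtype=float)
    return LinearModel(
        descriptor_names=list(spec["descriptor_names"]),
        coefficients=raw,
        intercept=float(spec["intercept"]),
        normalized_coefficients=norm,
        descriptor_sds=norm / raw,
        name=key,
    )
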