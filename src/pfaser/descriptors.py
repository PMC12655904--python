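"""Descriptor tables: validation, cleaning, standardization and VIF selection.

A descriptor table is a :class:`pandas.DataFrame` with ligand identifiers as
the index and one named physicochemical descriptor per column.  The canonical
set is the 11 descriptors used throughout the receptor-binding models, each
with a single-letter abbreviation used when writing model equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_DESCRIPTORS",
    "DESCRIPTOR_LETTERS",
    "EXCLUDED_DESCRIPTORS",
    "CleanResult",
    "VifReport",
    "clean",
    "compute_vif",
    "iterative_vif_elimination",
    "standardize",
]

#: Letter abbreviation -> canonical descriptor name.
DESCRIPTOR_LETTERS: dict[str, str] = {
    "a": "Average Mass",
    "c": "Number of H-Bond Donors",
    "d": "Density",
    "e": "LUMO",
    "f": "Number of Freely Rotating Bonds",
    "g": "Number of H-Bond Acceptors",
    "h": "F+ Max",
    "i": "Polar Surface Area",
    "j": "HOMO",
    "k": "LogD (pH 7.4)",
    "s": "Surface Tension",
}

#: The canonical 11 descriptor names, in letter order a,c,d,e,f,g,h,i,j,k,s.
CANONICAL_DESCRIPTORS: list[str] = list(DESCRIPTOR_LETTERS.values())

#: Descriptors dropped from the original 15 during multicollinearity
#: reduction, in removal order.  LogP was removed in place of LogD because
#: LogD at pH 7.4 carries ionization information relevant at physiological
#: pH.  Kept as a curated list: the 15->11 step was expert judgment.
EXCLUDED_DESCRIPTORS: list[str] = [
    "Enthalpy of Vaporization",
    "LogP",
    "Polarizability",
    "Boiling Point",
]


def _validate_table(table: pd.DataFrame, min_cols: int = 1) -> None:
    if not isinstance(table, pd.DataFrame):
        raise TypeError("descriptor table must be a pandas DataFrame")
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate descriptor columns: {dupes}")
    if table.shape[1] < min_cols:
        raise ValueError(f"need at least {min_cols} descriptor columns")


@dataclass
class CleanResult:
    """Outcome of missing-data removal."""

    table: pd.DataFrame
    removed_ids: list
    n_removed: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_removed = len(self.removed_ids)


def clean(table: pd.DataFrame) -> CleanResult:
    """Drop every ligand (row) with any missing descriptor value.

    Row order is preserved and surviving values are untouched.  An empty
    result is allowed (all rows incomplete), not an error.
    """
    _validate_table(table)
    mask = table.isna().any(axis=1)
    return CleanResult(table.loc[~mask].copy(), table.index[mask].tolist())


@dataclass
class VifReport:
    """Per-descriptor variance inflation factors, plus elimination history."""

    vif: pd.Series
    removal_history: list[tuple[str, float]] = field(default_factory=list)

    def max_descriptor(self) -> tuple[str, float]:
        name = self.vif.idxmax()
        return str(name), float(self.vif[name])


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) regressing it on the others + intercept."""
    n = X.shape[0]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(n), others])
    y = X[:, j]
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("constant column has no defined VIF")
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def compute_vif(table: pd.DataFrame) -> VifReport:
    """Variance inflation factor of every descriptor.

    VIF_j = 1/(1-R^2_j) where R^2_j comes from regressing descriptor j on
    all the others (with an intercept).  Exact collinearity is reported as
    ``inf``; a constant column is an error because its VIF is undefined.
    """
    _validate_table(table, min_cols=2)
    if table.shape[0] <= table.shape[1] + 1:
        raise ValueError("need more rows than descriptors + 1 for VIF")
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("table has missing values; clean() it first")
    for name in table.columns:
        if np.ptp(table[name].to_numpy(dtype=float)) == 0.0:
            raise ValueError(f"constant column: {name!r}")
    vifs = pd.Series(
        [_vif_one(X, j) for j in range(X.shape[1])], index=table.columns, name="VIF"
    )
    return VifReport(vifs)


def iterative_vif_elimination(
    table: pd.DataFrame,
    threshold: float = 5.0,
    substitutions: dict[str, str] | None = None,
    verify_only: bool = False,
) -> tuple[pd.DataFrame, VifReport]:
    """Repeatedly drop the max-VIF descriptor until all VIF < ``threshold``.

    ``substitutions`` maps a descriptor to a preferred casualty: if the
    max-VIF descriptor is a key, its mapped partner is removed instead (the
    workflow's LogP-for-LogD swap, keeping the physiologically relevant
    variant of two near-interchangeable descriptors).  Ties at the max are
    broken by column order.  With ``verify_only`` nothing is removed; the
    report simply lists descriptors at or above the threshold in
    ``removal_history``.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1 (the VIF lower bound)")
    substitutions = substitutions or {}
    current = table.copy()
    history: list[tuple[str, float]] = []
    while True:
        report = compute_vif(current)
        name, value = report.max_descriptor()
        if value < threshold:
            return current, VifReport(report.vif, history)
        if verify_only:
            offenders = report.vif[report.vif >= threshold]
            history = [(str(k), float(v)) for k, v in offenders.items()]
            return current, VifReport(report.vif, history)
        victim = substitutions.get(name, name)
        if victim not in current.columns:
            raise ValueError(f"substitution target {victim!r} not in table")
        if current.shape[1] - 1 < 2:
            raise ValueError("elimination would leave fewer than 2 descriptors")
        history.append((victim, value))
        current = current.drop(columns=[victim])


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale each column to mean 0, sample SD 1 (ddof=1).

    Returns the transformed table and a two-row frame (``mean``, ``sd``)
    needed to map model coefficients back to raw descriptor units.
    """
    _validate_table(table)
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("table has missing values; clean() it first")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    out = (table - mean) / sd
    scaler = pd.DataFrame({"mean": mean, "sd": sd}).T
    return out, scaler
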