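"""Conversions among docking score, IC50 and pIC50, and docking validation.

The quantity chain is

    pIC50 = -log10(IC50 [M]) = -log10(IC50_nM * 1e-9)

and the thermodynamic link between a docking score (a binding free-energy
estimate, kcal/mol, negative = favorable) and a dissociation-style constant

    IC50 [M] = exp(dG / (R * T)),   R = 1.987e-3 kcal/(mol K)

with T = 300 K by default.  Equating the docking free energy's implied
equilibrium constant with an IC50 is an assumption of the workflow, not a
pharmacological identity; it is what makes docking tables and experimental
IC50 tables comparable on the pIC50 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "score_to_ic50",
    "score_to_pic50",
    "ic50_to_score",
    "AffinityRecord",
    "ValidationSummary",
    "validate_against_experiment",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3

#: Default absolute temperature for score <-> IC50 conversion.
DEFAULT_TEMPERATURE_K = 300.0


def ic50_to_pic50(ic50_nM):
    """pIC50 = -log10(IC50 in molar); input in nM.

    Accepts scalars or arrays; raises ``ValueError`` on nonpositive input.
    """
    arr = np.asarray(ic50_nM, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 must be positive and finite (nM)")
    out = -np.log10(arr * 1e-9)
    return float(out) if np.isscalar(ic50_nM) or arr.ndim == 0 else out


def pic50_to_ic50(pic50):
    """Inverse of :func:`ic50_to_pic50`; returns IC50 in nM."""
    arr = np.asarray(pic50, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("pIC50 must be finite")
    out = 10.0 ** (-arr) * 1e9
    return float(out) if np.isscalar(pic50) or arr.ndim == 0 else out


def score_to_ic50(delta_g, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """Convert a docking score (kcal/mol) to IC50 in nM.

    IC50 [M] = exp(dG / RT); dG = 0 maps to 1 M = 1e9 nM, and the map is
    strictly increasing in dG (weaker score -> larger IC50).
    """
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    arr = np.asarray(delta_g, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("docking score must be finite")
    rt = GAS_CONSTANT_KCAL * temperature_K
    out = np.exp(arr / rt) * 1e9
    return float(out) if np.isscalar(delta_g) or arr.ndim == 0 else out


def score_to_pic50(delta_g, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """pIC50 implied by a docking score: composition of the two maps above."""
    return ic50_to_pic50(score_to_ic50(delta_g, temperature_K))


def ic50_to_score(ic50_nM, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """Exact inverse of :func:`score_to_ic50`: dG = RT ln(IC50 [M])."""
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    arr = np.asarray(ic50_nM, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 must be positive and finite (nM)")
    rt = GAS_CONSTANT_KCAL * temperature_K
    out = rt * np.log(arr * 1e-9)
    return float(out) if np.isscalar(ic50_nM) or arr.ndim == 0 else out


@dataclass
class AffinityRecord:
    """One ligand's affinity data; any of the three quantities may be absent.

    When both ``ic50_nM`` and ``pic50`` are given they must agree under the
    log conversion to 1e-9.
    """

    ligand_id: str
    delta_g: float | None = None
    ic50_nM: float | None = None
    pic50: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_nM is not None and self.pic50 is not None:
            if abs(self.pic50 - ic50_to_pic50(self.ic50_nM)) > 1e-9:
                raise ValueError(
                    f"{self.ligand_id}: pic50={self.pic50} inconsistent with "
                    f"ic50_nM={self.ic50_nM}"
                )

    def completed(self, temperature_K: float = DEFAULT_TEMPERATURE_K) -> "AffinityRecord":
        """Fill derivable fields (pIC50 from IC50, IC50/pIC50 from score)."""
        ic50, pic50 = self.ic50_nM, self.pic50
        if ic50 is None and pic50 is not None:
            ic50 = pic50_to_ic50(pic50)
        if ic50 is None and self.delta_g is not None:
            ic50 = score_to_ic50(self.delta_g, temperature_K)
        if pic50 is None and ic50 is not None:
            pic50 = ic50_to_pic50(ic50)
        return AffinityRecord(self.ligand_id, self.delta_g, ic50, pic50)


@dataclass
class ValidationSummary:
    """Predicted-minus-literature pIC50 differences and their dispersion.

    ``standard_error`` is the sample SD (n-1 denominator) over sqrt(n); it is
    the statistic used to judge how closely docking-derived affinities track
    experimental ones.
    """

    per_ligand_differences: np.ndarray
    mean_difference: float = field(init=False)
    sd: float = field(init=False)
    standard_error: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.per_ligand_differences, dtype=float)
        self.per_ligand_differences = d
        self.mean_difference = float(d.mean())
        self.sd = float(d.std(ddof=1))
        self.standard_error = self.sd / math.sqrt(d.size)

    @property
    def n(self) -> int:
        return int(self.per_ligand_differences.size)


def validate_against_experiment(
    pairs: Sequence[tuple[float, float]]
) -> ValidationSummary:
    """Summarize docking accuracy from (literature IC50, predicted IC50) pairs.

    Both columns are in nM; each is converted to pIC50 and the per-ligand
    difference predicted - literature is summarized as mean, sample SD and
    standard error SD/sqrt(n).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 ligand pairs (sample SD undefined)")
    lit = np.array([p[0] for p in pairs], dtype=float)
    pred = np.array([p[1] for p in pairs], dtype=float)
    diffs = ic50_to_pic50(pred) - ic50_to_pic50(lit)
    return ValidationSummary(diffs)
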