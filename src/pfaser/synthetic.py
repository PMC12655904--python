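"""Synthetic data with known ground truth for every pipeline stage.

Descriptor tables are drawn from a multivariate normal with a configurable
mean vector and covariance; affinities follow a linear descriptor model
plus Gaussian noise; docking scores are the exact thermodynamic inverse of
the true affinities (optionally noised), so conversion round-trips are
testable.  Toy receptor-ligand complexes place the ligand at the origin
and residues on spheres at controlled radii, so the contact set is known
by construction.

The ``pfas_like_spec`` preset emulates the statistical structure the
regression stages assume: centered descriptors with a one-factor
correlation structure (Average Mass and Polar Surface Area correlate at
r ≈ 0.81, the "big molecules are big in every way" effect), spreads chosen
so each term of the reference top-binder ERα equation contributes
≈ 0.35 pIC50 SD, and observation noise matching the published training
RMSE (≈ 0.35 pIC50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import ic50_to_score, pic50_to_ic50
from .contacts import ComplexStructure
from .descriptors import CANONICAL_DESCRIPTORS

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "pfas_like_spec",
    "generate_descriptors",
    "generate_affinities",
    "generate_dataset",
    "generate_complex",
]

#: One-factor loadings of the "pfas_like" correlation preset, by descriptor.
_PFAS_LOADINGS = {
    "Average Mass": 0.95,
    "Number of H-Bond Donors": 0.30,
    "Density": 0.35,
    "LUMO": 0.20,
    "Number of Freely Rotating Bonds": 0.60,
    "Number of H-Bond Acceptors": 0.40,
    "F+ Max": 0.10,
    "Polar Surface Area": 0.85,
    "HOMO": 0.20,
    "LogD (pH 7.4)": 0.45,
    "Surface Tension": 0.50,
}

#: Reference (top-binder ERα) coefficients in canonical descriptor order,
#: used as the default linear ground truth.
_REFERENCE_COEFFICIENTS = {
    "Average Mass": 0.2222,
    "Number of H-Bond Donors": -0.0312,
    "Density": 0.0887,
    "LUMO": 0.0285,
    "Number of Freely Rotating Bonds": -0.3843,
    "Number of H-Bond Acceptors": 0.0154,
    "F+ Max": 0.0166,
    "Polar Surface Area": -0.0185,
    "HOMO": -0.0198,
    "LogD (pH 7.4)": 0.0485,
    "Surface Tension": -0.0821,
}
_REFERENCE_INTERCEPT = 8.03

#: Per-term signal contribution of the equal-information preset (pIC50 SD).
_SIGNAL_PER_TERM = 0.35


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic dataset (descriptors + affinities)."""

    n_ligands: int
    descriptor_names: list[str] = field(
        default_factory=lambda: list(CANONICAL_DESCRIPTORS)
    )
    mean_vector: np.ndarray | None = None
    covariance: np.ndarray | None = None
    true_coefficients: np.ndarray | None = None
    true_intercept: float = _REFERENCE_INTERCEPT
    noise_sd: float = 0.35
    score_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.descriptor_names)
        if self.n_ligands < 0:
            raise ValueError("n_ligands must be nonnegative")
        if self.noise_sd < 0 or self.score_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.mean_vector is None:
            self.mean_vector = np.zeros(m)
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        if self.covariance is None:
            self.covariance = np.eye(m)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.true_coefficients is None:
            self.true_coefficients = np.array(
                [_REFERENCE_COEFFICIENTS.get(d, 0.1) for d in self.descriptor_names]
            )
        self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
        if self.mean_vector.shape != (m,):
            raise ValueError("mean_vector length must equal descriptor count")
        if self.covariance.shape != (m, m):
            raise ValueError("covariance dimension must equal descriptor count")
        if self.true_coefficients.shape != (m,):
            raise ValueError("true_coefficients length must equal descriptor count")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric (within 1e-10)")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-8:
            raise ValueError(
                f"covariance is not positive semidefinite: eigenvalue {eigvals.min():.3e}"
            )

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)


def pfas_like_spec(
    n_ligands: int = 69, noise_sd: float = 0.35, seed: int = 0, **overrides
) -> SyntheticSpec:
    """The default study conditions: correlated descriptors, reference truth.

    Descriptors are centered; the covariance is S @ R @ S with R a
    one-factor correlation matrix (R = diag(1-l^2) + l l') and S the
    diagonal of spreads sd_j = 0.35/|b_j| under the reference coefficients,
    so every descriptor carries comparable signal and the total pIC50
    spread (~1.2 SD) matches the few-unit range of docked affinities.
    """
    names = list(CANONICAL_DESCRIPTORS)
    loadings = np.array([_PFAS_LOADINGS[d] for d in names])
    corr = np.diag(1.0 - loadings**2) + np.outer(loadings, loadings)
    coefs = np.array([_REFERENCE_COEFFICIENTS[d] for d in names])
    sds = _SIGNAL_PER_TERM / np.abs(coefs)
    cov = corr * np.outer(sds, sds)
    cov = (cov + cov.T) / 2.0
    kwargs = dict(
        n_ligands=n_ligands,
        descriptor_names=names,
        mean_vector=np.zeros(len(names)),
        covariance=cov,
        true_coefficients=coefs,
        true_intercept=_REFERENCE_INTERCEPT,
        noise_sd=noise_sd,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def _ligand_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"PFAS-{i:0{width}d}" for i in range(1, n + 1)]


def generate_descriptors(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the descriptor table for ``spec`` (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    m = spec.n_descriptors
    eigvals, eigvecs = np.linalg.eigh(spec.covariance)
    eigvals = np.clip(eigvals, 0.0, None)
    transform = eigvecs * np.sqrt(eigvals)
    z = rng.standard_normal((spec.n_ligands, m))
    X = spec.mean_vector + z @ transform.T
    return pd.DataFrame(
        X, index=_ligand_ids(spec.n_ligands), columns=spec.descriptor_names
    )


@dataclass
class SyntheticDataset:
    """Descriptors plus the true and observed affinity chain."""

    descriptor_table: pd.DataFrame
    true_pic50: pd.Series
    observed_pic50: pd.Series
    docking_scores: pd.Series
    truth: SyntheticSpec


def generate_affinities(
    table: pd.DataFrame, spec: SyntheticSpec
) -> SyntheticDataset:
    """Attach true/observed pIC50 and docking scores to a descriptor table.

    true pIC50 = intercept + X b; observed adds N(0, noise_sd); the docking
    score is the exact inverse affinity conversion of the true pIC50 at
    300 K, plus optional Gaussian score noise.
    """
    missing = [d for d in spec.descriptor_names if d not in table.columns]
    if missing:
        raise KeyError(f"table lacks descriptor columns: {missing}")
    X = table[spec.descriptor_names].to_numpy(dtype=float)
    true = spec.true_intercept + X @ spec.true_coefficients
    # independent stream so affinity noise does not depend on table size
    rng = np.random.default_rng([spec.seed, 1])
    observed = true + rng.normal(0.0, spec.noise_sd, size=true.size)
    scores = ic50_to_score(pic50_to_ic50(true))
    if spec.score_noise_sd > 0:
        scores = scores + rng.normal(0.0, spec.score_noise_sd, size=true.size)
    idx = table.index
    return SyntheticDataset(
        descriptor_table=table,
        true_pic50=pd.Series(true, index=idx, name="true_pic50"),
        observed_pic50=pd.Series(observed, index=idx, name="pic50"),
        docking_scores=pd.Series(scores, index=idx, name="score_kcal_mol"),
        truth=spec,
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Convenience: descriptors and affinities in one call."""
    return generate_affinities(generate_descriptors(spec), spec)


_RESIDUE_CYCLE = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


def generate_complex(
    n_receptor_residues: int,
    contact_residue_indices,
    cutoff: float = 5.0,
    seed: int = 0,
    complex_id: str = "synthetic-complex",
) -> ComplexStructure:
    """A toy complex where exactly the designated residues touch the ligand.

    The ligand (residue LIG, HETATM on write) sits in a 0.5 Å ball at the
    origin.  Each contact residue's backbone sits on a sphere of radius
    cutoff - 1 Å, guaranteeing at least one atom pair within the cutoff;
    every other residue sits beyond cutoff + 2 Å, keeping all its atoms
    strictly farther than cutoff + 0.5 Å from every ligand atom.
    Deterministic in the seed.
    """
    contacts = set(int(i) for i in contact_residue_indices)
    valid = set(range(1, n_receptor_residues + 1))
    if not contacts <= valid:
        raise ValueError(
            f"contact indices {sorted(contacts - valid)} outside residue "
            f"range 1..{n_receptor_residues}"
        )
    if cutoff <= 2.0:
        raise ValueError(
            "cutoff <= 2 Å: contact shell would overlap the ligand region "
            "(impossible geometry)"
        )
    rng = np.random.default_rng(seed)

    def random_unit() -> np.ndarray:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)

    rows = []
    for j in range(6):  # ligand atoms
        pos = random_unit() * rng.uniform(0.0, 0.5)
        rows.append(
            {
                "atom_name": f"C{j + 1}",
                "element": "C",
                "x": pos[0], "y": pos[1], "z": pos[2],
                "resname": "LIG",
                "resseq": n_receptor_residues + 1,
                "chain": "A",
                "is_ligand": True,
            }
        )
    backbone = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    for i in range(1, n_receptor_residues + 1):
        radius = (cutoff - 1.0) if i in contacts else (cutoff + 2.0 + 0.1 * i)
        center = random_unit() * radius
        for name, element in backbone:
            offset = random_unit() * rng.uniform(0.0, 0.3)
            pos = center + offset
            rows.append(
                {
                    "atom_name": name,
                    "element": element,
                    "x": pos[0], "y": pos[1], "z": pos[2],
                    "resname": _RESIDUE_CYCLE[(i - 1) % len(_RESIDUE_CYCLE)],
                    "resseq": i,
                    "chain": "A",
                    "is_ligand": False,
                }
            )
    atoms = pd.DataFrame(rows)
    # receptor rows first is not required; keep ligand first for readability
    return ComplexStructure(atoms, complex_id)
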