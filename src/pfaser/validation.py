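"""Model validation machinery: pairwise ensembles, large-set refinement,
and active/decoy benchmark separation.

Three validation strategies for descriptor->pIC50 regression models:

* a pairwise ensemble: every unique pair of experimentally characterized
  compounds anchors one train/test split, giving C(n, 2) models whose
  train/test R^2 and leave-one-out Q^2 are averaged;
* large-set refinement: docking-score cutoff filtering followed by
  iterative removal of the highest-|residual| compounds (10% then 20% by
  default), re-splitting 80/20 each round;
* an active/decoy benchmark: decoys standardized to a fixed weak affinity
  (100,000 nM, pIC50 4.0) and separation measured as
  min(active predictions) - max(decoy predictions) in pIC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .affinity import ic50_to_pic50
from .qspr import FitMetrics, cross_validate_q2, evaluate, fit_ols, predict

__all__ = [
    "SplitPlan",
    "EnsembleSummary",
    "RefinementRound",
    "RefinementTrajectory",
    "BenchmarkResult",
    "enumerate_pair_splits",
    "run_ensemble",
    "score_cutoff_filter",
    "iterative_outlier_refinement",
    "benchmark_separation",
    "standardize_decoys",
    "DECOY_IC50_NM",
]

#: Standardized decoy affinity: the benchmark lists decoys as ">100,000 nM".
DECOY_IC50_NM = 100_000.0


@dataclass
class SplitPlan:
    """One ensemble member's train/test/excluded partition."""

    test_ids: list
    train_ids: list
    excluded_ids: list
    seed: int
    experimental_pair: tuple = ()

    def __post_init__(self) -> None:
        overlap = set(self.test_ids) & set(self.train_ids)
        if overlap:
            raise ValueError(f"test/train overlap: {sorted(overlap)}")


def enumerate_pair_splits(
    experimental_ids: Sequence,
    pool_ids: Sequence,
    n_pool_test: int = 5,
    n_pool_train: int | None = 45,
    excluded: Sequence = (),
    seed: int = 0,
) -> list[SplitPlan]:
    """One split plan per unique pair of experimental compounds.

    Each plan's test set is the experimental pair plus ``n_pool_test``
    pool compounds sampled without replacement (fresh draw per plan, all
    driven by one master seed); the training set is the remaining
    experimental compounds plus ``n_pool_train`` further pool compounds
    (``None`` = all remaining pool).  ``excluded`` ids are removed from the
    pool before any sampling and appear in every plan's ``excluded_ids``.
    """
    experimental = list(experimental_ids)
    if len(experimental) < 2:
        raise ValueError("need at least 2 experimental compounds")
    excluded = list(excluded)
    pool = [p for p in pool_ids if p not in set(excluded)]
    need = n_pool_test + (n_pool_train or 0)
    if len(pool) < max(need, n_pool_test):
        raise ValueError(
            f"pool of {len(pool)} cannot supply {n_pool_test} test"
            + (f" + {n_pool_train} train" if n_pool_train else "")
            + " compounds"
        )
    rng = np.random.default_rng(seed)
    plans = []
    for pair in combinations(experimental, 2):
        order = rng.permutation(len(pool))
        pool_test = [pool[i] for i in order[:n_pool_test]]
        rest = [pool[i] for i in order[n_pool_test:]]
        pool_train = rest if n_pool_train is None else rest[:n_pool_train]
        unused = [] if n_pool_train is None else rest[n_pool_train:]
        train = [e for e in experimental if e not in pair] + pool_train
        plans.append(
            SplitPlan(
                test_ids=list(pair) + pool_test,
                train_ids=train,
                excluded_ids=excluded + unused,
                seed=seed,
                experimental_pair=pair,
            )
        )
    return plans


@dataclass
class EnsembleSummary:
    """Per-model and average metrics over an ensemble of split plans."""

    per_model: pd.DataFrame

    @property
    def mean_train_r2(self) -> float:
        return float(self.per_model["train_r2"].mean())

    @property
    def mean_test_r2(self) -> float:
        return float(self.per_model["test_r2"].mean())

    @property
    def mean_q2(self) -> float:
        return float(self.per_model["q2"].mean())

    @property
    def n_models(self) -> int:
        return len(self.per_model)


def run_ensemble(
    plans: Sequence[SplitPlan], table: pd.DataFrame, pic50: pd.Series
) -> EnsembleSummary:
    """Fit one OLS model per plan and collect train/test R^2 and Q^2."""
    rows = []
    for i, plan in enumerate(plans):
        missing = [t for t in plan.train_ids + plan.test_ids if t not in table.index]
        if missing:
            raise KeyError(f"plan {i}: unknown ligand ids {missing[:5]}")
        Xtr, ytr = table.loc[plan.train_ids], pic50.loc[plan.train_ids]
        Xte, yte = table.loc[plan.test_ids], pic50.loc[plan.test_ids]
        model = fit_ols(Xtr, ytr)
        rows.append(
            {
                "model": i,
                "experimental_pair": plan.experimental_pair,
                "train_r2": model.metrics.r2,
                "test_r2": evaluate(model, Xte, yte).r2,
                "q2": cross_validate_q2(Xtr, ytr),
            }
        )
    return EnsembleSummary(pd.DataFrame(rows).set_index("model"))


def score_cutoff_filter(scores: pd.Series, cutoff: float) -> pd.Index:
    """Ids of ligands with docking score <= cutoff (inclusive boundary).

    More negative scores are stronger binders, so the filter retains
    everything at least as favorable as the cutoff.
    """
    scores = pd.Series(scores)
    return scores.index[scores <= cutoff]


@dataclass
class RefinementRound:
    fraction_removed: float
    n_removed: int
    n_remaining: int
    train_r2: float
    test_r2: float
    removed_ids: list = field(default_factory=list)


@dataclass
class RefinementTrajectory:
    rounds: list[RefinementRound]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fraction_removed": r.fraction_removed,
                    "n_removed": r.n_removed,
                    "n_remaining": r.n_remaining,
                    "train_r2": r.train_r2,
                    "test_r2": r.test_r2,
                }
                for r in self.rounds
            ]
        )


def _split_8020(ids: list, rng: np.random.Generator, test_fraction: float):
    order = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test = [ids[i] for i in order[:n_test]]
    train = [ids[i] for i in order[n_test:]]
    return train, test


def iterative_outlier_refinement(
    table: pd.DataFrame,
    pic50: pd.Series,
    fractions: Sequence[float] = (0.10, 0.20),
    split_seed: int = 0,
    test_fraction: float = 0.2,
    ranking: str = "pooled",
) -> RefinementTrajectory:
    """Iteratively drop the highest-|residual| compounds and refit.

    Round k: fit on the current 80/20 split, rank compounds by absolute
    residual (training residuals from the fit, test residuals from
    prediction; ``ranking="train"`` restricts to the training set), remove
    the top floor(fraction_k * current size), re-split with the recorded
    seed and refit.  The first trajectory entry is the unrefined baseline.
    Fractions are cumulative: each applies to the then-current set.
    """
    for f in fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError("fractions must lie in [0, 1)")
    if ranking not in ("pooled", "train"):
        raise ValueError("ranking must be 'pooled' or 'train'")
    ids = list(table.index)
    rng = np.random.default_rng(split_seed)
    rounds: list[RefinementRound] = []

    def fit_round(current: list):
        train, test = _split_8020(current, rng, test_fraction)
        model = fit_ols(table.loc[train], pic50.loc[train])
        test_r2 = evaluate(model, table.loc[test], pic50.loc[test]).r2
        resid = (pic50.loc[current] - predict(model, table.loc[current])).abs()
        if ranking == "train":
            resid = resid.loc[train]
        return model, test_r2, resid

    model, test_r2, resid = fit_round(ids)
    rounds.append(RefinementRound(0.0, 0, len(ids), model.metrics.r2, test_r2))
    current = ids
    for frac in fractions:
        n_remove = math.floor(frac * len(current))
        worst = list(resid.sort_values(ascending=False).index[:n_remove])
        current = [i for i in current if i not in set(worst)]
        min_rows = table.shape[1] + 3
        if len(current) * (1 - test_fraction) < min_rows:
            raise ValueError("refinement would leave too few compounds to fit")
        model, test_r2, resid = fit_round(current)
        rounds.append(
            RefinementRound(
                frac, n_remove, len(current), model.metrics.r2, test_r2, worst
            )
        )
    return RefinementTrajectory(rounds)


@dataclass
class BenchmarkResult:
    """Active/decoy separation of predicted affinities.

    ``separation`` is min(active) - max(decoy) in pIC50; ``fold_ratio`` is
    the corresponding IC50 ratio 10**separation (> 1 iff the weakest
    predicted active still beats the strongest predicted decoy).
    """

    predictions: pd.Series
    labels: pd.Series
    separation: float = field(init=False)
    fold_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        active = self.predictions[self.labels.astype(bool)]
        decoy = self.predictions[~self.labels.astype(bool)]
        if active.empty or decoy.empty:
            raise ValueError("need at least one active and one decoy")
        self.separation = float(active.min() - decoy.max())
        self.fold_ratio = 10.0 ** self.separation


def benchmark_separation(predictions: pd.Series, labels: pd.Series) -> BenchmarkResult:
    """Separation statistics from per-compound predictions and active flags."""
    predictions = pd.Series(predictions)
    labels = pd.Series(labels).reindex(predictions.index)
    if labels.isna().any():
        raise ValueError("labels must cover every prediction")
    return BenchmarkResult(predictions, labels)


def standardize_decoys(
    records: pd.DataFrame,
    decoy_column: str = "is_decoy",
    ic50_column: str = "ic50_nM",
    ki_column: str = "ki_nM",
) -> pd.DataFrame:
    """Assign every decoy the standardized weak affinity and fill pIC50.

    Decoys get IC50 = 100,000 nM (pIC50 4.0).  Actives keep their listed
    IC50; actives with only a Ki are passed through an identity Ki -> IC50
    mapping (recorded in the ``affinity_source`` column, so the assumption
    is visible downstream).
    """
    out = records.copy()
    if decoy_column not in out.columns:
        raise KeyError(f"missing decoy flag column {decoy_column!r}")
    decoy = out[decoy_column].astype(bool)
    if ic50_column not in out.columns:
        out[ic50_column] = np.nan
    source = pd.Series("ic50", index=out.index, dtype=object)
    if ki_column in out.columns:
        use_ki = out[ic50_column].isna() & out[ki_column].notna() & ~decoy
        out.loc[use_ki, ic50_column] = out.loc[use_ki, ki_column]
        source[use_ki] = "ki_as_ic50"
    out.loc[decoy, ic50_column] = DECOY_IC50_NM
    source[decoy] = "decoy_standardized"
    out["affinity_source"] = source
    out["pic50"] = ic50_to_pic50(out[ic50_column].to_numpy())
    return out
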