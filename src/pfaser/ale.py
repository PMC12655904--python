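"""Accumulated local effects (ALE) profiles for fitted models.

ALE answers "how does the prediction move as one descriptor sweeps its
observed range", while staying honest under correlated descriptors: within
each interval of the descriptor's range, only the observations actually in
that interval are perturbed to the interval edges, and the local differences
are accumulated across the grid.  The curve is finally centered by the
observation-weighted mean so values read as deviations from the average
prediction, in pIC50 units here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .qspr import LinearModel, predict

__all__ = ["ALEProfile", "ale_curve", "ale_summary"]


@dataclass
class ALEProfile:
    """One descriptor's ALE curve over a fixed grid.

    ``ale_values`` has one entry per grid edge (grid_size + 1 points),
    centered; ``raw_values`` is the uncentered accumulated curve starting
    at 0.  ``delta_range`` is (min, max) of the centered values.
    """

    descriptor: str
    grid_edges: np.ndarray
    ale_values: np.ndarray
    raw_values: np.ndarray
    interval_counts: np.ndarray

    @property
    def delta_range(self) -> tuple[float, float]:
        return float(self.ale_values.min()), float(self.ale_values.max())

    @property
    def raw_delta_range(self) -> tuple[float, float]:
        return float(self.raw_values.min()), float(self.raw_values.max())

    @property
    def width(self) -> float:
        lo, hi = self.delta_range
        return hi - lo

    def weighted_mean(self) -> float:
        """Observation-weighted mean of the centered curve (≈ 0)."""
        w = self._edge_weights()
        return float((self.ale_values * w).sum() / w.sum())

    def _edge_weights(self) -> np.ndarray:
        n = self.interval_counts.astype(float)
        padded = np.concatenate([[0.0], n, [0.0]])
        return (padded[:-1] + padded[1:]) / 2.0


def _as_predictor(model) -> Callable[[pd.DataFrame], np.ndarray]:
    if isinstance(model, LinearModel):
        return lambda df: predict(model, df).to_numpy()
    if callable(model):
        return lambda df: np.asarray(model(df), dtype=float)
    raise TypeError("model must be a LinearModel or a callable on DataFrames")


def _grid(x: np.ndarray, grid_size: int, placement: str) -> np.ndarray:
    if placement == "quantile":
        edges = np.quantile(x, np.linspace(0.0, 1.0, grid_size + 1))
        edges = np.unique(edges)
        if edges.size < 2:
            raise ValueError("descriptor has too few distinct values")
        return edges
    if placement == "uniform":
        return np.linspace(x.min(), x.max(), grid_size + 1)
    raise ValueError(f"unknown grid placement {placement!r}")


def ale_curve(
    model,
    table: pd.DataFrame,
    descriptor: str,
    grid_size: int = 20,
    placement: str = "quantile",
) -> ALEProfile:
    """First-order ALE of ``descriptor`` under ``model`` over ``table``.

    Grid edges partition the observed range (quantile placement by default,
    ``placement="uniform"`` for equal-width bins).  Empty intervals
    contribute zero local effect and the accumulation carries forward.
    """
    if descriptor not in table.columns:
        raise KeyError(f"descriptor {descriptor!r} not in table")
    f = _as_predictor(model)
    x = table[descriptor].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError(f"constant descriptor {descriptor!r}: ALE undefined")
    edges = _grid(x, grid_size, placement)
    k = edges.size - 1
    # interval index per observation: 1..k, with the left edge folded into bin 1
    idx = np.clip(np.searchsorted(edges, x, side="left"), 1, k)
    local = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    for j in range(1, k + 1):
        sel = idx == j
        counts[j - 1] = int(sel.sum())
        if not counts[j - 1]:
            continue
        sub = table.loc[sel]
        hi = sub.copy()
        hi[descriptor] = edges[j]
        lo = sub.copy()
        lo[descriptor] = edges[j - 1]
        local[j - 1] = float((f(hi) - f(lo)).mean())
    raw = np.concatenate([[0.0], np.cumsum(local)])
    # observation-weighted centering: each interval contributes its count at
    # the midpoint of the accumulated curve over that interval
    n = counts.sum()
    center = float((counts * (raw[:-1] + raw[1:]) / 2.0).sum() / n)
    return ALEProfile(descriptor, edges, raw - center, raw, counts)


def ale_summary(
    model,
    table: pd.DataFrame,
    descriptors: Sequence[str] | None = None,
    grid_size: int = 20,
    placement: str = "quantile",
) -> list[ALEProfile]:
    """ALE profile per descriptor, ordered by |delta range| descending."""
    names = list(table.columns) if descriptors is None else list(descriptors)
    profiles = [
        ale_curve(model, table, d, grid_size=grid_size, placement=placement)
        for d in names
    ]
    profiles.sort(key=lambda p: p.width, reverse=True)
    return profiles
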