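"""Deviance-weighted averaging of fold expansion across heterogeneous donors.

Donor panels contain non-responders (flat fold expansion across conditions,
so near-zero cross-condition variance) and super-responders (one donor can
reach ~70-fold at the best condition, roughly threefold above the cohort).
A plain mean over donors is dominated by these extremes, so per-donor
weights are built from each donor's cross-condition variance σ_i²:

    medme   = 0.1 * mean(σ²) + 0.9 * median(σ²)
    d_i     = |σ_i² − medme|          (floored to stay positive)
    ω_i     ∝ 1 / d_i,   Σ ω_i = 1

Donors with variance near the robust center medme get the largest weights;
both low-variance and extreme-variance donors are damped.  The weighted
average for condition α is Y_α = Σ_i ω_i f_iα, a convex combination of
donor values.  Each donor group (A/B/C) is weighted independently and the
per-group averages are concatenated in condition order to form the
12-condition response vector Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study_data import DonorGroup, FoldExpansionTable

__all__ = [
    "DonorWeights",
    "WeightedResponse",
    "donor_variances",
    "deviance_weights",
    "weighted_average",
    "combined_Y",
]


@dataclass(frozen=True)
class DonorWeights:
    """Per-donor variance, deviance and normalized weight for one group."""

    donor_ids: tuple[int, ...]
    variances: np.ndarray
    deviances: np.ndarray
    weights: np.ndarray
    group_id: str
    variance_convention: str = "sample"

    def __post_init__(self) -> None:
        if not np.all(self.weights >= 0):
            raise ValueError("weights must be non-negative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.donor_ids), name="weight")


@dataclass(frozen=True)
class WeightedResponse:
    """Per-condition weighted averages plus provenance."""

    condition_ids: tuple[int, ...]
    values: np.ndarray
    day: int
    weights: tuple[DonorWeights, ...]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.condition_ids), name=f"Y_day{self.day}")

    def __getitem__(self, condition_id: int) -> float:
        return float(self.values[self.condition_ids.index(condition_id)])


def donor_variances(
    table: FoldExpansionTable,
    day: int,
    group: DonorGroup,
    convention: str = "sample",
) -> pd.Series:
    """Cross-condition variance of fold expansion per donor at ``day``.

    ``convention`` is ``"sample"`` (n-1 denominator, default) or
    ``"population"``.  Missing (donor, condition) cells raise with the gap
    named.
    """
    if convention not in {"sample", "population"}:
        raise ValueError(f"unknown variance convention {convention!r}")
    wide = table.values(day, group.donor_ids, group.condition_ids)
    ddof = 1 if convention == "sample" else 0
    return wide.var(axis=1, ddof=ddof).rename("variance")


def deviance_weights(
    variances: pd.Series,
    group_id: str = "",
    floor_scale: float = 1e-9,
    power: int = 1,
    convention: str = "sample",
) -> DonorWeights:
    """Weights inversely proportional to |σ_i² − medme|.

    ``power=1`` uses the absolute deviance (default); ``power=2`` squares
    it.  Deviances below ``floor_scale * median(σ²)`` are floored so a donor
    sitting exactly on medme does not receive infinite weight.  If every
    deviance hits the floor the weights fall back to uniform with a warning.
    """
    sigma2 = np.asarray(variances, dtype=float)
    donor_ids = tuple(int(d) for d in variances.index)
    if sigma2.size < 2:
        warnings.warn("single donor: degenerate weight of 1", stacklevel=2)
        return DonorWeights(donor_ids, sigma2, np.zeros_like(sigma2), np.ones_like(sigma2), group_id, convention)
    medme = 0.1 * float(np.mean(sigma2)) + 0.9 * float(np.median(sigma2))
    dev = np.abs(sigma2 - medme) ** power
    floor = floor_scale * max(float(np.median(sigma2)), np.finfo(float).tiny)
    dev_floored = np.maximum(dev, floor)
    if np.all(dev <= floor):
        warnings.warn("all deviances at the floor; falling back to uniform weights", stacklevel=2)
        w = np.full_like(sigma2, 1.0 / sigma2.size)
    else:
        inv = 1.0 / dev_floored
        w = inv / inv.sum()
    return DonorWeights(donor_ids, sigma2, dev_floored, w, group_id, convention)


def weighted_average(
    table: FoldExpansionTable,
    weights: DonorWeights,
    day: int,
    conditions: tuple[int, ...] | list[int],
) -> WeightedResponse:
    """Y_α = Σ_i ω_i f_iα for each requested condition."""
    group = None
    for g in table.groups:
        if set(weights.donor_ids) <= set(g.donor_ids):
            group = g
            break
    if group is not None:
        outside = set(conditions) - set(group.condition_ids)
        if outside:
            raise ValueError(
                f"conditions {sorted(outside)} lie outside group {group.group_id}'s "
                f"condition list {list(group.condition_ids)}"
            )
    wide = table.values(day, weights.donor_ids, tuple(conditions))
    y = weights.weights @ wide.to_numpy()
    return WeightedResponse(tuple(conditions), y, day, (weights,))


def combined_Y(
    table: FoldExpansionTable,
    day: int = 9,
    convention: str = "sample",
    floor_scale: float = 1e-9,
    power: int = 1,
) -> WeightedResponse:
    """Concatenated per-group weighted averages across all modeled conditions.

    Group weights are computed independently within each group; the output
    is ordered by condition id.
    """
    if not table.groups:
        raise ValueError("table has no donor groups")
    pieces: list[WeightedResponse] = []
    for g in table.groups:
        if not g.donor_ids:
            raise ValueError(f"group {g.group_id} is empty")
        var = donor_variances(table, day, g, convention)
        w = deviance_weights(var, g.group_id, floor_scale=floor_scale, power=power, convention=convention)
        pieces.append(weighted_average(table, w, day, g.condition_ids))
    cond_ids = [c for p in pieces for c in p.condition_ids]
    values = np.concatenate([p.values for p in pieces])
    order = np.argsort(cond_ids)
    return WeightedResponse(
        tuple(np.asarray(cond_ids)[order]),
        values[order],
        day,
        tuple(w for p in pieces for w in p.weights),
    )
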