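"""Regression Relief (RReliefF) feature weights and imputation-map filtering.

RReliefF scores each feature by how well differences in the feature track
differences in a continuous response among nearest neighbors.  For every
instance the k nearest neighbors (Manhattan distance on the features, ties
broken by instance order) contribute, with uniform influence,

    N_dY      += dY(i, j)
    N_dA[A]   += dA(A, i, j)
    N_dYdA[A] += dY(i, j) * dA(A, i, j)

where dY is the absolute response difference normalized by the response
range and dA is, for binary features, the inequality indicator.  The weight
of feature A over m instances is

    W[A] = N_dYdA[A] / N_dY  −  (N_dA[A] − N_dYdA[A]) / (m*k − N_dY)

which lies in [−1, +1]; a constant feature scores exactly 0.

Map filtering mirrors two observations from STAT3/NF-κB inhibitor
experiments: (1) condition 2 must induce STAT3 (checked structurally on the
activation matrix), and (2) STAT3 and NF-κB must carry positive RReliefF
weights in both priming and PP-I, evaluated over a range of neighbor counts
k.  Maps failing either constraint are infeasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imputation_maps import ActivationMatrix, ImputationMap, activation_matrix, factor_label
from .study_data import CytokineCondition, Factor
from .weighting import WeightedResponse

__all__ = ["ReliefWeights", "MapFilterResult", "rrelieff", "filter_maps"]


@dataclass(frozen=True)
class ReliefWeights:
    """Per-feature RReliefF weights in [−1, 1]."""

    feature_labels: tuple[str, ...]
    weights: np.ndarray
    k: int
    m: int

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.feature_labels.index(label)])


def rrelieff(X: np.ndarray, y: np.ndarray, k: int, feature_labels: Sequence[str] | None = None) -> ReliefWeights:
    """RReliefF feature weights with uniform neighbor influence.

    Every instance serves as a target; neighbors are the k nearest others by
    Manhattan distance, with distance ties broken by instance order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n_feat = X.shape
    if y.shape != (m,):
        raise ValueError("X and y have incompatible shapes")
    if k >= m:
        raise ValueError(f"neighbor count k={k} must be smaller than the instance count m={m}")
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = tuple(feature_labels) if feature_labels is not None else tuple(f"x{j}" for j in range(n_feat))

    y_range = float(y.max() - y.min())
    if y_range == 0.0:
        warnings.warn("response has zero range; all RReliefF weights are 0", stacklevel=2)
        return ReliefWeights(labels, np.zeros(n_feat), k, m)

    n_dy = 0.0
    n_da = np.zeros(n_feat)
    n_dyda = np.zeros(n_feat)
    for i in range(m):
        dist = np.abs(X - X[i]).sum(axis=1)
        dist[i] = np.inf
        # stable sort => ties broken by instance order
        neighbors = np.argsort(dist, kind="stable")[:k]
        for j in neighbors:
            dy = abs(y[i] - y[j]) / y_range
            da = (X[i] != X[j]).astype(float)
            n_dy += dy
            n_da += da
            n_dyda += dy * da
    w = np.zeros(n_feat)
    if n_dy > 0:
        w += n_dyda / n_dy
    denom = m * k - n_dy
    if denom > 0:
        w -= (n_da - n_dyda) / denom
    return ReliefWeights(labels, w, k, m)


_CONSTRAINT2_LABELS = tuple(
    factor_label(f, phase) for f in (Factor.STAT3, Factor.NFKB) for phase in ("priming", "pp1")
)


@dataclass(frozen=True)
class MapFilterResult:
    """Constraint outcomes for one imputation map."""

    map_signature: str
    map_index: int
    passes_constraint1: bool
    passes_constraint2: bool
    k_passed: tuple[int, ...]
    feasible: bool


def _condition2_induces_stat3(M: ActivationMatrix, condition_id: int = 2) -> bool:
    row = M.row(condition_id)
    s3_prime = M.column_labels.index(factor_label(Factor.STAT3, "priming"))
    s3_pp1 = M.column_labels.index(factor_label(Factor.STAT3, "pp1"))
    return bool(row[s3_prime] or row[s3_pp1])


def filter_maps(
    maps: Sequence[ImputationMap],
    conditions: Sequence[CytokineCondition],
    Y: WeightedResponse | np.ndarray,
    k_range: Sequence[int] = tuple(range(2, 11)),
    rule: str = "all",
    constraint1_condition: int = 2,
) -> list[MapFilterResult]:
    """Apply the inhibitor-experiment constraints to candidate maps.

    ``rule`` aggregates constraint 2 over ``k_range``: ``"all"`` requires
    the four STAT3/NF-κB weights positive for every k (default),
    ``"majority"`` for more than half of the k values.
    """
    k_range = tuple(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if rule not in {"all", "majority"}:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    y = Y.values if isinstance(Y, WeightedResponse) else np.asarray(Y, dtype=float)
    if len(y) != len(conditions):
        raise ValueError("Y must cover every modeled condition")

    results = []
    for imap in maps:
        M = activation_matrix(imap, conditions)
        c1 = _condition2_induces_stat3(M, constraint1_condition)
        k_passed: list[int] = []
        idx = [M.column_labels.index(lbl) for lbl in _CONSTRAINT2_LABELS]
        for k in k_range:
            w = rrelieff(M.values.astype(float), y, k, M.column_labels)
            if np.all(w.weights[idx] > 0):
                k_passed.append(k)
        if rule == "all":
            c2 = len(k_passed) == len(k_range)
        else:
            c2 = len(k_passed) > len(k_range) / 2
        results.append(
            MapFilterResult(
                map_signature=imap.content_signature,
                map_index=imap.map_index,
                passes_constraint1=c1,
                passes_constraint2=c2,
                k_passed=tuple(k_passed),
                feasible=c1 and c2,
            )
        )
    return results
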