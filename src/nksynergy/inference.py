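"""Bootstrap uncertainty on coefficients, synergy calls and predictions.

Coefficient uncertainty is propagated from donor sampling: each bootstrap
replicate resamples donors *with replacement within their group* (sizes
10/4/3), recomputes the deviance weights and the per-group weighted
averages, concatenates them into a resampled response Ỹ and refits the
model on the design restricted to the predictors retained by the full-data
fit.  A predictor is called a synergy when |⟨β⟩/σ_β| > 2 with ⟨β⟩ > 0,
an antagonism when the ratio exceeds 2 with ⟨β⟩ < 0, and inconclusive
otherwise.

The fitted model also supports counterfactuals: predicting an unseen
cytokine regimen (e.g. a condition-13-style cocktail) and simulating a
STAT3 or NF-κB inhibitor by zeroing that factor's activation entries —
priming phase only by default, mirroring inhibitor exposure during priming
with a washout before PP-I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation_maps import ActivationMatrix, ImputationMap, activation_matrix, factor_label
from .regression import DesignMatrix, FitResult, build_design, fit
from .study_data import CytokineCondition, Factor, FoldExpansionTable
from .weighting import deviance_weights

__all__ = [
    "BootstrapBeta",
    "bootstrap_beta",
    "restrict_predictors",
    "predict_condition",
    "simulate_inhibitor",
]


@dataclass(frozen=True)
class BootstrapBeta:
    """Bootstrap summary per retained predictor."""

    labels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    seed: int
    n_redrawn: int
    samples: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.abs(self.mean) / self.sd
        r[(self.sd == 0) & (self.mean != 0)] = np.inf
        r[(self.sd == 0) & (self.mean == 0)] = 0.0
        return r

    @property
    def calls(self) -> tuple[str, ...]:
        out = []
        for m, r in zip(self.mean, self.ratio):
            if r > 2 and m > 0:
                out.append("synergy")
            elif r > 2 and m < 0:
                out.append("antagonism")
            else:
                out.append("inconclusive")
        return tuple(out)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "ratio": self.ratio, "call": self.calls},
            index=list(self.labels),
        )


def restrict_predictors(fit_result: FitResult, X: DesignMatrix) -> DesignMatrix:
    """Drop design columns whose fitted coefficient is (numerically) zero."""
    kept = fit_result.nonzero_labels
    if not kept:
        raise ValueError("all coefficients are zero; nothing to bootstrap")
    return X.restrict(kept)


def _resampled_Y(
    table: FoldExpansionTable,
    day: int,
    rng: np.random.Generator,
    max_redraw: int = 100,
) -> tuple[np.ndarray, tuple[int, ...], int]:
    """One group-respecting donor resample and its weighted response."""
    cond_ids: list[int] = []
    values: list[np.ndarray] = []
    n_redrawn = 0
    for g in table.groups:
        donors = np.asarray(g.donor_ids)
        for _ in range(max_redraw):
            draw = rng.choice(donors, size=donors.size, replace=True)
            if np.unique(draw).size > 1 or donors.size == 1:
                break
            n_redrawn += 1
        wide = table.values(day, list(g.donor_ids), list(g.condition_ids))
        sampled = wide.loc[list(draw)]
        var = sampled.var(axis=1, ddof=1)
        var.index = range(len(var))  # resampled donors are distinct observations
        w = deviance_weights(var, g.group_id)
        values.append(w.weights @ sampled.to_numpy())
        cond_ids.extend(g.condition_ids)
    y = np.concatenate(values)
    order = np.argsort(cond_ids)
    return y[order], tuple(np.asarray(cond_ids)[order]), n_redrawn


def bootstrap_beta(
    table: FoldExpansionTable,
    imap: ImputationMap,
    family: str,
    conditions: list[CytokineCondition],
    n: int = 1000,
    seed: int = 0,
    day: int = 9,
    regularization: str = "lasso",
    lam: float = 0.01,
) -> BootstrapBeta:
    """Donor-resampling bootstrap of the retained coefficients.

    A full-data fit first identifies the retained (nonzero) predictors;
    each replicate refits on the restricted design against its resampled
    response.  Replicates that draw a single unique donor in any group are
    redrawn (count reported).
    """
    X = build_design(activation_matrix(imap, conditions), family)
    y_full, cond_ids, _ = _full_Y(table, day)
    if cond_ids != X.condition_ids:
        raise ValueError("table condition coverage does not match the design")
    full_fit = fit(X, y_full, regularization, lam)
    Xr = restrict_predictors(full_fit, X)

    rng = np.random.default_rng(seed)
    samples = np.empty((n, Xr.values.shape[1]))
    total_redrawn = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-weight warnings inside replicates
        for b in range(n):
            y_b, _, redrawn = _resampled_Y(table, day, rng)
            total_redrawn += redrawn
            f = fit(Xr.values, y_b, regularization, lam, labels=Xr.labels, family=family)
            samples[b] = f.beta
    return BootstrapBeta(
        labels=Xr.labels,
        mean=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=1),
        n_replicates=n,
        seed=seed,
        n_redrawn=total_redrawn,
        samples=samples,
    )


def _full_Y(table: FoldExpansionTable, day: int) -> tuple[np.ndarray, tuple[int, ...], list]:
    from .weighting import combined_Y

    resp = combined_Y(table, day)
    return resp.values, resp.condition_ids, list(resp.weights)


def _design_row(
    imap: ImputationMap, family: str, condition: CytokineCondition, zero_factors: dict[Factor, tuple[str, ...]] | None = None
) -> np.ndarray:
    M = activation_matrix(imap, [condition])
    if zero_factors:
        vals = M.values.copy()
        for factor, phases in zero_factors.items():
            for phase in phases:
                j = M.column_labels.index(factor_label(factor, phase))
                vals[0, j] = 0
        M = ActivationMatrix(vals, M.condition_ids, M.column_labels)
    return build_design(M, family).values[0]


def predict_condition(
    fit_result: FitResult, imap: ImputationMap, condition: CytokineCondition
) -> float:
    """Predicted weighted fold expansion for an arbitrary regimen.

    The condition's activation row is built under the map, expanded to the
    model family's predictors, restricted to the fit's labels and pushed
    through the coefficients.
    """
    row = _design_row(imap, fit_result.family, condition)
    full = build_design(activation_matrix(imap, [condition]), fit_result.family)
    idx = [full.labels.index(lbl) for lbl in fit_result.labels]
    return float(row[idx] @ fit_result.beta + fit_result.intercept)


def simulate_inhibitor(
    fit_result: FitResult,
    imap: ImputationMap,
    condition: CytokineCondition,
    inhibited: Factor,
    phases: tuple[str, ...] = ("priming",),
) -> float:
    """Prediction with one factor's activation zeroed in the given phases.

    Default zeroes priming only (inhibitors present during priming, washed
    out before PP-I); pass ``("priming", "pp1")`` to silence both phases.
    """
    inhibited = Factor(inhibited)
    if inhibited not in {Factor.STAT3, Factor.NFKB}:
        raise ValueError("inhibitors are modeled for STAT3 and NFKB only")
    mapped = set().union(*imap.activated.values())
    if inhibited not in mapped:
        warnings.warn(f"{inhibited.value} is not activated by any cytokine under this map; no-op", stacklevel=2)
    row = _design_row(imap, fit_result.family, condition, {inhibited: tuple(phases)})
    full = build_design(activation_matrix(imap, [condition]), fit_result.family)
    idx = [full.labels.index(lbl) for lbl in fit_result.labels]
    return float(row[idx] @ fit_result.beta + fit_result.intercept)
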