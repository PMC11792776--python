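"""Design-matrix families, regularized fits and LOOCV model selection.

The weighted day-9 response Y over the 12 conditions is regressed on binary
predictors built from the activation matrix.  Four interaction scenarios,
each in a linear and a linear+pairwise flavor, give eight families:

==============================  =========  ==========================================
family                          columns    construction
==============================  =========  ==========================================
linear-priming                  5          priming factor indicators
linear+pairwise-priming         15         + within-priming pair products
linear-pp1                      5          PP-I factor indicators
linear+pairwise-pp1             15         + within-PP-I pair products
additive                        10         priming ⊕ PP-I linear blocks
additive-pairwise               30         both linear+pairwise blocks concatenated
multiplicative                  25         all priming x PP-I cross products
multiplicative-pairwise         225        cross products of the 15-column blocks
==============================  =========  ==========================================

Multiplicative families are fit as free linear models over the product
predictors (no rank-1 constraint).  Coefficients β > 0 on a cross-phase
product (e.g. "S3·Sb~") are read as synergy between the two factors across
phases; β < 0 as antagonism.

Fits minimize ½‖Y − Xβ − b‖² + λ‖β‖₁ (LASSO, coordinate descent via
scikit-learn) or the Ridge analogue, with a free intercept and
unstandardized binary predictors; λ = 0 reduces to (minimum-norm) least
squares.  Model selection runs leave-one-out cross-validation over the 12
conditions for every (map, family) pair and picks the pair with minimum
out-of-fold RSS; R² is the squared Pearson correlation of predictions with
observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, Ridge

from .imputation_maps import ActivationMatrix, ImputationMap, activation_matrix
from .study_data import CytokineCondition
from .weighting import WeightedResponse

__all__ = [
    "FAMILIES",
    "FAMILY_SIZES",
    "DesignMatrix",
    "FitResult",
    "SelectionEntry",
    "SelectionResult",
    "build_design",
    "fit",
    "loocv",
    "select_optimal",
    "DEFAULT_LAMBDA",
    "LAMBDA_GRID",
]

FAMILIES: tuple[str, ...] = (
    "linear-priming",
    "linear+pairwise-priming",
    "linear-pp1",
    "linear+pairwise-pp1",
    "additive",
    "additive-pairwise",
    "multiplicative",
    "multiplicative-pairwise",
)

FAMILY_SIZES: dict[str, int] = {
    "linear-priming": 5,
    "linear+pairwise-priming": 15,
    "linear-pp1": 5,
    "linear+pairwise-pp1": 15,
    "additive": 10,
    "additive-pairwise": 30,
    "multiplicative": 25,
    "multiplicative-pairwise": 225,
}

#: Fixed regularization strength used when no rule is given.
DEFAULT_LAMBDA = 0.01
#: Log grid for the inner-CV λ rule.
LAMBDA_GRID = np.logspace(-4, 1, 25)


@dataclass(frozen=True)
class DesignMatrix:
    """Binary conditions x predictors matrix with unique labels."""

    values: np.ndarray
    labels: tuple[str, ...]
    condition_ids: tuple[int, ...]
    family: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.condition_ids), columns=list(self.labels))

    def restrict(self, labels: Sequence[str]) -> "DesignMatrix":
        idx = [self.labels.index(lbl) for lbl in labels]
        return DesignMatrix(self.values[:, idx], tuple(labels), self.condition_ids, self.family)


def _phase_block(M: ActivationMatrix, phase: str, pairwise: bool) -> tuple[np.ndarray, list[str]]:
    offset = 0 if phase == "priming" else 5
    cols = M.values[:, offset : offset + 5].astype(float)
    labels = list(M.column_labels[offset : offset + 5])
    if pairwise:
        for p, q in combinations(range(5), 2):
            cols = np.column_stack([cols, cols[:, p] * cols[:, q]])
            labels.append(f"{labels[p]}·{labels[q]}")
    return cols, labels


def build_design(M: ActivationMatrix, family: str) -> DesignMatrix:
    """Build the family's design matrix from an activation matrix."""
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    pairwise = "pairwise" in family
    if family in {"linear-priming", "linear+pairwise-priming"}:
        X, labels = _phase_block(M, "priming", pairwise)
    elif family in {"linear-pp1", "linear+pairwise-pp1"}:
        X, labels = _phase_block(M, "pp1", pairwise)
    elif family in {"additive", "additive-pairwise"}:
        Xp, lp = _phase_block(M, "priming", pairwise)
        Xq, lq = _phase_block(M, "pp1", pairwise)
        X, labels = np.column_stack([Xp, Xq]), lp + lq
    else:  # multiplicative
        Xp, lp = _phase_block(M, "priming", pairwise)
        Xq, lq = _phase_block(M, "pp1", pairwise)
        cols, labels = [], []
        for a in range(Xp.shape[1]):
            for b in range(Xq.shape[1]):
                cols.append(Xp[:, a] * Xq[:, b])
                labels.append(f"{lp[a]}·{lq[b]}")
        X = np.column_stack(cols)
    assert X.shape[1] == FAMILY_SIZES[family]
    assert len(set(labels)) == len(labels)
    return DesignMatrix(X, tuple(labels), M.condition_ids, family)


@dataclass(frozen=True)
class FitResult:
    """Fitted coefficients for one design."""

    labels: tuple[str, ...]
    beta: np.ndarray
    intercept: float
    regularization: str
    lam: float
    family: str
    nonzero_threshold: float = 1e-10

    @property
    def nonzero_labels(self) -> tuple[str, ...]:
        return tuple(l for l, b in zip(self.labels, self.beta) if abs(b) > self.nonzero_threshold)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.intercept

    def as_series(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.labels), name="beta")


def fit(
    X: DesignMatrix | np.ndarray,
    y: np.ndarray,
    regularization: str = "lasso",
    lam: float = DEFAULT_LAMBDA,
    labels: Sequence[str] | None = None,
    family: str = "",
) -> FitResult:
    """Fit ½‖y − Xβ − b‖² + λ·penalty with a free intercept.

    LASSO penalty is λ‖β‖₁; Ridge is λ‖β‖₂².  λ = 0 falls back to
    minimum-norm least squares.  Predictors are used unstandardized.
    """
    if isinstance(X, DesignMatrix):
        labels = X.labels
        family = family or X.family
        Xv = X.values.astype(float)
    else:
        Xv = np.asarray(X, dtype=float)
        labels = tuple(labels) if labels is not None else tuple(f"x{j}" for j in range(Xv.shape[1]))
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if regularization not in {"lasso", "ridge", "none"}:
        raise ValueError(f"unknown regularization {regularization!r}")
    if lam < 0:
        raise ValueError("lambda must be non-negative")

    n = Xv.shape[0]
    if regularization == "none" or lam == 0.0:
        A = np.column_stack([np.ones(n), Xv])
        coefs, *_ = np.linalg.lstsq(A, y, rcond=None)
        return FitResult(tuple(labels), coefs[1:], float(coefs[0]), "none" if lam == 0 else regularization, 0.0, family)
    if regularization == "lasso":
        # sklearn objective: (1/2n)||r||^2 + alpha||b||_1  =>  alpha = lam/n
        model = Lasso(alpha=lam / n, fit_intercept=True, max_iter=500_000, tol=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xv, y)
    else:
        # sklearn Ridge objective: ||r||^2 + alpha||b||^2  =>  alpha = 2*lam
        model = Ridge(alpha=2.0 * lam, fit_intercept=True)
        model.fit(Xv, y)
    return FitResult(tuple(labels), np.asarray(model.coef_, dtype=float), float(model.intercept_), regularization, lam, family)


def _resolve_lambda(
    Xv: np.ndarray, y: np.ndarray, regularization: str, lam_rule: float | str
) -> float:
    """Fixed λ, or inner LOOCV over LAMBDA_GRID when lam_rule == "cv"."""
    if isinstance(lam_rule, (int, float)):
        return float(lam_rule)
    if lam_rule != "cv":
        raise ValueError(f"unknown lambda rule {lam_rule!r}")
    n = Xv.shape[0]
    best_lam, best_err = float(LAMBDA_GRID[0]), np.inf
    for lam in LAMBDA_GRID:
        err = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            f = fit(Xv[mask], y[mask], regularization, float(lam))
            err += float((y[i] - f.predict(Xv[i : i + 1]))[0] ** 2)
        if err < best_err:
            best_err, best_lam = err, float(lam)
    return best_lam


@dataclass(frozen=True)
class SelectionEntry:
    """LOOCV result for one (map, family) pair."""

    map_signature: str
    map_index: int
    family: str
    predictions: np.ndarray
    rss: float
    r2: float | None
    rho: float | None


def loocv(
    imap: ImputationMap,
    family: str,
    conditions: Sequence[CytokineCondition],
    Y: WeightedResponse | np.ndarray,
    regularization: str = "lasso",
    lam: float | str = DEFAULT_LAMBDA,
) -> SelectionEntry:
    """Leave-one-condition-out predictions, RSS and R² for one pair.

    ``lam`` is a fixed λ or ``"cv"`` for an inner LOOCV λ search within
    each training fold.
    """
    y = Y.values if isinstance(Y, WeightedResponse) else np.asarray(Y, dtype=float)
    X = build_design(activation_matrix(imap, conditions), family)
    n = len(y)
    if X.values.shape[0] != n:
        raise ValueError("Y does not cover all modeled conditions")
    preds = np.empty(n)
    for a in range(n):
        mask = np.ones(n, dtype=bool)
        mask[a] = False
        lam_a = _resolve_lambda(X.values[mask], y[mask], regularization, lam)
        f = fit(X.values[mask], y[mask], regularization, lam_a, labels=X.labels, family=family)
        preds[a] = f.predict(X.values[a : a + 1])[0]
    rss = float(np.sum((y - preds) ** 2))
    if np.ptp(preds) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant predictions: Pearson correlation undefined, R² reported as missing", stacklevel=2)
        rho, r2 = None, None
    else:
        rho = float(stats.pearsonr(y, preds).statistic)
        r2 = rho**2
    return SelectionEntry(imap.content_signature, imap.map_index, family, preds, rss, r2, rho)


@dataclass(frozen=True)
class SelectionResult:
    """Grid of LOOCV results with the argmin-RSS pair."""

    entries: tuple[SelectionEntry, ...]
    best: SelectionEntry
    tie_note: str = ""

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "map_index": [e.map_index for e in self.entries],
                "map_signature": [e.map_signature for e in self.entries],
                "family": [e.family for e in self.entries],
                "rss": [e.rss for e in self.entries],
                "r2": [e.r2 for e in self.entries],
            }
        )


def select_optimal(
    maps: Sequence[ImputationMap],
    conditions: Sequence[CytokineCondition],
    Y: WeightedResponse | np.ndarray,
    families: Sequence[str] = FAMILIES,
    regularization: str = "lasso",
    lam: float | str = DEFAULT_LAMBDA,
) -> SelectionResult:
    """Grid search (map x family) by LOOCV RSS.

    Ties on RSS break toward higher R², then canonical (map index, family
    order); any tie is noted on the result.
    """
    if not maps:
        raise ValueError("need at least one feasible map")
    if not families:
        raise ValueError("family list is empty")
    entries = [loocv(m, fam, conditions, Y, regularization, lam) for m in maps for fam in families]

    def sort_key(e: SelectionEntry) -> tuple:
        return (e.rss, -(e.r2 if e.r2 is not None else -np.inf), e.map_index, FAMILIES.index(e.family))

    ranked = sorted(entries, key=sort_key)
    best = ranked[0]
    tie_note = ""
    near = [e for e in ranked[1:] if np.isclose(e.rss, best.rss, rtol=0, atol=1e-12)]
    if near:
        tie_note = (
            f"RSS tie between {1 + len(near)} pairs; resolved by higher R², then canonical order: "
            + ", ".join(f"(map {e.map_index}, {e.family})" for e in [best] + near)
        )
    return SelectionResult(tuple(entries), best, tie_note)
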