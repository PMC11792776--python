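"""Day-8 condition comparison: imputation, net weights, bootstrap and tests.

The end-of-expansion comparison across conditions 1-6 uses a day-8 value
imputed as the midpoint of the day-7 and day-9 observations (cells start
dying after day 9).  Each donor gets a *net weight* per condition,

    W_net ∝ W_viability + W_variability       (renormalized to sum 1),

where the viability weight encodes early-culture health from days 2 and 4
(rule 1: both > 1 and rising → the day-4 value; rule 2: both > 1 but not
rising → the day-2/day-4 average; rule 3: otherwise → the smaller of the
two) and the variability weight damps day-8 outliers via the squared
distance to the leave-one-out median, inverted and normalized:

    W_variability_i ∝ 1 / (fe_i − median{fe_j, j≠i})².

Uncertainty in the per-condition weighted averages comes from a donor
bootstrap (default 10 000 replicates, weights recomputed per replicate).
An ANOVA F omnibus (the protected first stage of Fisher's least significant
difference procedure) tests equality of the condition means on donor-level
day-8 values, and a paired label-swap permutation test compares a reference
condition (condition 3 in the study design) against each other condition,
swapping the two full trajectories within a donor with probability ½ and
recomputing all weights for every permuted dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study_data import FoldExpansionTable, ValidationError

__all__ = [
    "day8_table",
    "viability_weights",
    "variability_weights",
    "net_weights",
    "weighted_day8_average",
    "ConditionComparison",
    "bootstrap_condition_distributions",
    "fisher_lsd_omnibus",
    "permutation_test_vs_reference",
]

_EARLY_DAYS = (2, 4)


def day8_table(table: FoldExpansionTable) -> pd.DataFrame:
    """Imputed day-8 fold expansion: (day-7 + day-9) / 2 per (donor, condition)."""
    d7 = table.data[table.data["day"] == 7].set_index(["donor_id", "condition_id"])["fold_expansion"]
    d9 = table.data[table.data["day"] == 9].set_index(["donor_id", "condition_id"])["fold_expansion"]
    both = pd.concat({"day7": d7, "day9": d9}, axis=1).dropna()
    out = ((both["day7"] + both["day9"]) / 2).rename("day8")
    return out.reset_index()


def _viability_raw(d2: np.ndarray, d4: np.ndarray) -> np.ndarray:
    """Raw viability weight from the day-2/day-4 values (vectorized rules)."""
    d2 = np.asarray(d2, float)
    d4 = np.asarray(d4, float)
    both_above = (d2 > 1) & (d4 > 1)
    rising = both_above & (d4 > d2)
    flat_or_falling = both_above & ~rising
    out = np.where(rising, d4, np.where(flat_or_falling, (d2 + d4) / 2, np.minimum(d2, d4)))
    return out


def _day_matrix(table: FoldExpansionTable, day: int, donors: Sequence[int], conditions: Sequence[int]) -> np.ndarray:
    return table.values(day, tuple(donors), tuple(conditions)).to_numpy()


def viability_weights(table: FoldExpansionTable, condition: int, donors: Sequence[int] | None = None) -> pd.Series:
    """Normalized early-culture viability weights for one condition."""
    donors = tuple(donors) if donors is not None else table.groups[0].donor_ids
    d2 = _day_matrix(table, 2, donors, [condition])[:, 0]
    d4 = _day_matrix(table, 4, donors, [condition])[:, 0]
    raw = _viability_raw(d2, d4)
    return pd.Series(raw / raw.sum(), index=list(donors), name="W_viability")


def _loo_median(rows: np.ndarray) -> np.ndarray:
    """Leave-one-out median along the last axis, vectorized.

    ``out[..., i]`` is the median of ``rows[..., j != i]``.
    """
    rows = np.asarray(rows, float)
    n = rows.shape[-1]
    if n < 3:
        raise ValueError("leave-one-out median needs at least 3 values")
    s = np.sort(rows, axis=-1)
    order = np.argsort(rows, axis=-1, kind="stable")
    pos = np.argsort(order, axis=-1, kind="stable")  # sorted position of each element
    k = n - 1
    m1, m2 = (k - 1) // 2, k // 2

    def pick(j: int) -> np.ndarray:
        # j-th order statistic of the row with one element removed at `pos`
        return np.where(j < pos, s[..., j : j + 1], s[..., j + 1 : j + 2])

    return (pick(m1) + pick(m2)) / 2.0


def variability_weights(day8_values: pd.Series | np.ndarray, floor_scale: float = 1e-9) -> np.ndarray | pd.Series:
    """Outlier-damping weights from squared LOO-median deviance of day-8 values."""
    fe = np.asarray(day8_values, float)
    if fe.size < 3:
        raise ValueError("variability weights need at least 3 donors")
    d = (fe - _loo_median(fe)) ** 2
    # additive floor: donors exactly on the LOO median get large finite
    # weight; if every deviance is zero the weights become uniform
    eps = floor_scale * float(np.mean(d)) + 1e-100
    inv = 1.0 / (d + eps)
    w = inv / inv.sum()
    if isinstance(day8_values, pd.Series):
        return pd.Series(w, index=day8_values.index, name="W_variability")
    return w


def net_weights(table: FoldExpansionTable, condition: int, donors: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-donor viability, variability and renormalized net weights."""
    donors = tuple(donors) if donors is not None else table.groups[0].donor_ids
    w_v = viability_weights(table, condition, donors)
    d7 = _day_matrix(table, 7, donors, [condition])[:, 0]
    d9 = _day_matrix(table, 9, donors, [condition])[:, 0]
    fe8 = (d7 + d9) / 2
    w_var = variability_weights(pd.Series(fe8, index=list(donors)))
    net = w_v.to_numpy() + w_var.to_numpy()
    net = net / net.sum()
    return pd.DataFrame(
        {"W_viability": w_v.to_numpy(), "W_variability": w_var.to_numpy(), "W_net": net, "day8": fe8},
        index=list(donors),
    )


def weighted_day8_average(table: FoldExpansionTable, condition: int, donors: Sequence[int] | None = None) -> float:
    nw = net_weights(table, condition, donors)
    return float((nw["W_net"] * nw["day8"]).sum())


# ---------------------------------------------------------------------------
# Vectorized net-weighted means over many donor assignments


def _net_weighted_means(d2: np.ndarray, d4: np.ndarray, d7: np.ndarray, d9: np.ndarray) -> np.ndarray:
    """Net-weighted day-8 mean along the last (donor) axis; leading axes free."""
    fe8 = (d7 + d9) / 2.0
    v_raw = _viability_raw(d2, d4)
    w_v = v_raw / v_raw.sum(axis=-1, keepdims=True)
    d = (fe8 - _loo_median(fe8)) ** 2
    eps = 1e-9 * np.mean(d, axis=-1, keepdims=True) + 1e-100
    inv = 1.0 / (d + eps)
    w_var = inv / inv.sum(axis=-1, keepdims=True)
    w_net = w_v + w_var
    w_net = w_net / w_net.sum(axis=-1, keepdims=True)
    return (w_net * fe8).sum(axis=-1)


@dataclass(frozen=True)
class ConditionComparison:
    """Bootstrap distributions of net-weighted day-8 averages per condition."""

    condition_ids: tuple[int, ...]
    distributions: np.ndarray  # (n_replicates, n_conditions)
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicates: int
    seed: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "ci_low": self.ci_low, "ci_high": self.ci_high},
            index=list(self.condition_ids),
        )


def bootstrap_condition_distributions(
    table: FoldExpansionTable,
    conditions: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n: int = 10_000,
    seed: int = 0,
    donors: Sequence[int] | None = None,
) -> ConditionComparison:
    """Donor-bootstrap distributions of the day-8 weighted averages.

    Each replicate resamples the donor panel with replacement and recomputes
    viability, variability and net weights from the resampled trajectories.
    """
    donors = tuple(donors) if donors is not None else table.groups[0].donor_ids
    conditions = tuple(conditions)
    mats = {day: _day_matrix(table, day, donors, conditions) for day in (2, 4, 7, 9)}
    rng = np.random.default_rng(seed)
    nd = len(donors)
    draws = rng.integers(0, nd, size=(n, nd))
    dist = np.empty((n, len(conditions)))
    for j in range(len(conditions)):
        d2 = mats[2][draws, j]
        d4 = mats[4][draws, j]
        d7 = mats[7][draws, j]
        d9 = mats[9][draws, j]
        dist[:, j] = _net_weighted_means(d2, d4, d7, d9)
    return ConditionComparison(
        condition_ids=conditions,
        distributions=dist,
        means=dist.mean(axis=0),
        ci_low=np.percentile(dist, 2.5, axis=0),
        ci_high=np.percentile(dist, 97.5, axis=0),
        n_replicates=n,
        seed=seed,
    )


def fisher_lsd_omnibus(
    table: FoldExpansionTable | None = None,
    conditions: Sequence[int] = (1, 2, 3, 4, 5, 6),
    donors: Sequence[int] | None = None,
    comparison: ConditionComparison | None = None,
) -> float:
    """Omnibus equality p-value across conditions (ANOVA F stage of LSD).

    By default runs on donor-level imputed day-8 values.  Passing a
    ``comparison`` instead computes the F test on the bootstrap
    distributions; that variant inflates the effective sample size and is
    reported descriptively only.
    """
    if comparison is not None:
        groups = [comparison.distributions[:, j] for j in range(comparison.distributions.shape[1])]
    else:
        if table is None:
            raise ValueError("provide a table or a comparison")
        conditions = tuple(conditions)
        if len(conditions) < 2:
            raise ValueError("omnibus test needs at least two conditions")
        donors = tuple(donors) if donors is not None else table.groups[0].donor_ids
        d7 = _day_matrix(table, 7, donors, conditions)
        d9 = _day_matrix(table, 9, donors, conditions)
        fe8 = (d7 + d9) / 2.0
        groups = [fe8[:, j] for j in range(len(conditions))]
    return float(stats.f_oneway(*groups).pvalue)


def permutation_test_vs_reference(
    table: FoldExpansionTable,
    reference: int = 3,
    other: int = 1,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
    donors: Sequence[int] | None = None,
) -> float:
    """Paired label-swap permutation p-value (one-sided: reference > other).

    Per donor, the reference and comparison trajectories (days 2, 4, 7, 9)
    are exchanged with probability ½; the statistic is the difference of
    net-weighted day-8 averages with all weights recomputed per permuted
    dataset.  With ``exact=True`` all 2^n swap patterns are enumerated and
    the p-value is the exact fraction of patterns with a statistic at least
    as large as observed; otherwise ``n_perm`` random patterns are drawn and
    the add-one estimate (1 + #{≥ obs}) / (n_perm + 1) is returned.
    """
    if donors is None:
        group = next((g for g in table.groups if reference in g.condition_ids), None)
        if group is None or other not in group.condition_ids:
            raise ValidationError(
                f"conditions {reference} and {other} are not observed on the same donor group"
            )
        donors = group.donor_ids
    donors = tuple(donors)
    nd = len(donors)
    pair = (reference, other)
    mats = {day: _day_matrix(table, day, donors, pair) for day in (2, 4, 7, 9)}

    if exact:
        if nd > 20:
            raise ValueError("exact enumeration is limited to 20 donors")
        patterns = (np.arange(2**nd)[:, None] >> np.arange(nd)) & 1
    else:
        rng = np.random.default_rng(seed)
        patterns = rng.integers(0, 2, size=(n_perm, nd))
    swap = patterns.astype(bool)

    stats_all = _swap_statistics(mats, swap)
    observed = _swap_statistics(mats, np.zeros((1, nd), dtype=bool))[0]
    if exact:
        return float(np.mean(stats_all >= observed))
    hits = int(np.sum(stats_all >= observed))
    return float((1 + hits) / (len(stats_all) + 1))


def _swap_statistics(mats: dict[int, np.ndarray], swap: np.ndarray) -> np.ndarray:
    """Difference of net-weighted means for each swap pattern.

    ``mats[day]`` has shape (n_donors, 2) with columns (reference, other);
    ``swap`` has shape (P, n_donors).
    """
    t_ref = swap.astype(int)  # trajectory index assigned to the reference slot
    t_oth = 1 - t_ref
    idx = np.arange(swap.shape[1])

    def assigned(day: int, t: np.ndarray) -> np.ndarray:
        return mats[day][idx, t]

    mean_ref = _net_weighted_means(
        assigned(2, t_ref), assigned(4, t_ref), assigned(7, t_ref), assigned(9, t_ref)
    )
    mean_oth = _net_weighted_means(
        assigned(2, t_oth), assigned(4, t_oth), assigned(7, t_oth), assigned(9, t_oth)
    )
    return mean_ref - mean_oth
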