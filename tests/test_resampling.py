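import itertools

import numpy as np
import pandas as pd
import pytest

from nksynergy.resampling import (
    _viability_raw,
    bootstrap_condition_distributions,
    day8_table,
    fisher_lsd_omnibus,
    net_weights,
    permutation_test_vs_reference,
    variability_weights,
    viability_weights,
    weighted_day8_average,
)
from nksynergy.study_data import ValidationError
from tests.conftest import make_paired_table, random_paired_table


@pytest.mark.parametrize(
    "d2, d4, expect",
    [
        (1.2, 1.5, 1.5),  # rising and healthy: day-4 value
        (1.5, 1.2, 1.35),  # healthy but declining: average
        (0.8, 0.9, 0.8),  # below 1 at some early day: the minimum
        (1.5, 1.5, 1.5),  # tie at day 2/day 4 handled as non-rising: average
        (0.9, 1.4, 0.9),
    ],
)
def test_viability_rules(d2, d4, expect):
    assert _viability_raw(np.array([d2]), np.array([d4]))[0] == pytest.approx(expect)


def test_viability_weights_normalized(default_table):
    w = viability_weights(default_table, condition=3)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert (w >= 0).all()


def test_variability_weight_hand_example():
    # fe = {2, 4, 30}: LOO medians {17, 16, 3}; d = {225, 144, 729}
    w = variability_weights(pd.Series([2.0, 4.0, 30.0], index=[1, 2, 3]))
    assert w.to_numpy() == pytest.approx([0.3483, 0.5442, 0.1075], abs=5e-5)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_variability_symmetric_pair_equal_weights():
    w = variability_weights(np.array([2.0, 10.0, 18.0]))
    assert w[0] == pytest.approx(w[2])  # symmetric outer values


def test_variability_far_outlier_smallest_weight():
    w = variability_weights(np.array([5.0, 6.0, 7.0, 100.0]))
    assert np.argmin(w) == 3


def test_variability_needs_three_donors():
    with pytest.raises(ValueError, match="at least 3"):
        variability_weights(np.array([1.0, 2.0]))


def test_day8_is_exact_midpoint(default_table):
    d8 = day8_table(default_table)
    merged = d8.merge(
        default_table.data.pivot_table(index=["donor_id", "condition_id"], columns="day", values="fold_expansion"),
        on=["donor_id", "condition_id"],
    )
    assert np.all(np.abs(merged["day8"] - (merged[7] + merged[9]) / 2) == 0)


def test_net_weights_sum_to_one(default_table):
    for cond in (1, 2, 3):
        nw = net_weights(default_table, cond)
        for col in ("W_viability", "W_variability", "W_net"):
            assert nw[col].sum() == pytest.approx(1.0, abs=1e-12)
            assert (nw[col] >= 0).all()


def test_bootstrap_point_mass_for_identical_donors():
    values = {d: {c: {2: 1.5, 4: 2.5, 7: 8.0, 9: 12.0} for c in (1, 2, 3)} for d in range(1, 11)}
    table = make_paired_table(values, conditions=(1, 2, 3))
    comp = bootstrap_condition_distributions(table, (1, 2, 3), n=200, seed=0)
    assert np.all(comp.distributions == 10.0)  # (8+12)/2 for every donor


def test_bootstrap_determinism_and_ci_support(default_table):
    a = bootstrap_condition_distributions(default_table, n=500, seed=3)
    b = bootstrap_condition_distributions(default_table, n=500, seed=3)
    assert np.array_equal(a.distributions, b.distributions)
    assert np.all(a.ci_low <= a.means) and np.all(a.means <= a.ci_high)
    assert np.all(a.ci_low >= a.distributions.min(axis=0))
    assert np.all(a.ci_high <= a.distributions.max(axis=0))


def test_bootstrap_mean_consistent_with_plug_in(default_table):
    comp = bootstrap_condition_distributions(default_table, n=4000, seed=5)
    for j, cond in enumerate(comp.condition_ids):
        full = weighted_day8_average(default_table, cond)
        # resampling perturbs the weighting, so agree only to MC/weighting error
        assert comp.means[j] == pytest.approx(full, rel=0.25)


def test_omnibus_detects_a_strongly_shifted_condition():
    rng = np.random.default_rng(0)
    values = {}
    for d in range(1, 11):
        values[d] = {}
        for cond in (1, 2, 3):
            boost = 6.0 if cond == 3 else 1.0  # +5 sigma shift on condition 3
            traj = {2: 1.5, 4: 2.5, 7: 8.0 * boost, 9: 12.0 * boost}
            values[d][cond] = {k: v * float(np.exp(rng.normal(0, 0.1))) for k, v in traj.items()}
    table = make_paired_table(values, conditions=(1, 2, 3))
    assert fisher_lsd_omnibus(table, (1, 2, 3)) < 0.001


def test_omnibus_null_p_is_roughly_uniform():
    # independent donor x condition draws from one distribution (the F test
    # assumes independent groups; a shared donor effect would make it
    # conservative)
    rng = np.random.default_rng(1)
    pvals = []
    for _ in range(200):
        values = {}
        for d in range(1, 11):
            values[d] = {}
            for cond in (1, 2):
                level = float(np.exp(rng.normal(2.3, 0.4)))
                values[d][cond] = {2: 1.5, 4: 2.5, 7: level * 0.9, 9: level * 1.1}
        table = make_paired_table(values, conditions=(1, 2))
        pvals.append(fisher_lsd_omnibus(table, (1, 2)))
    from scipy import stats

    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_omnibus_needs_two_conditions(default_table):
    with pytest.raises(ValueError, match="two conditions"):
        fisher_lsd_omnibus(default_table, (1,))


def brute_force_paired_permutation(table, reference, other, donors):
    """Exhaustive sign-flip enumeration via the scalar weighting path."""
    base = {}
    for d in donors:
        base[d] = {}
        for cond in (reference, other):
            sub = table.data[(table.data.donor_id == d) & (table.data.condition_id == cond)]
            base[d][cond] = dict(zip(sub.day, sub.fold_expansion))

    def stat(swapped):
        values = {}
        for i, d in enumerate(donors):
            ref_traj = base[d][other] if swapped[i] else base[d][reference]
            oth_traj = base[d][reference] if swapped[i] else base[d][other]
            values[d] = {reference: ref_traj, other: oth_traj}
        t = make_paired_table(values, conditions=tuple(sorted((reference, other))))
        return weighted_day8_average(t, reference, donors) - weighted_day8_average(t, other, donors)

    observed = stat((False,) * len(donors))
    stats_all = [stat(pattern) for pattern in itertools.product([False, True], repeat=len(donors))]
    return float(np.mean([s >= observed for s in stats_all]))


def test_exact_permutation_matches_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    table = random_paired_table(rng, 4, conditions=(1, 3), shift=0.4)
    donors = table.groups[0].donor_ids
    got = permutation_test_vs_reference(table, reference=3, other=1, exact=True)
    want = brute_force_paired_permutation(table, 3, 1, donors)
    assert got == pytest.approx(want, abs=1e-12)


def test_identical_conditions_never_significant():
    rng = np.random.default_rng(3)
    for _ in range(5):
        table = random_paired_table(rng, 6, conditions=(1, 3), shift=0.0)
        p = permutation_test_vs_reference(table, 3, 1, n_perm=200, seed=1)
        assert p >= 1 / 201


def test_strong_shift_saturates_p():
    # p approaches the resolution floor; it may sit slightly above it
    # because the outlier-damping weights make a few partial swaps nearly
    # as extreme as the observed split
    rng = np.random.default_rng(4)
    table = random_paired_table(rng, 10, conditions=(1, 3), shift=3.0)
    p = permutation_test_vs_reference(table, 3, 1, n_perm=999, seed=0)
    assert 1 / 1000 <= p <= 0.01


def test_unpaired_conditions_rejected(default_table):
    with pytest.raises(ValidationError, match="same donor group"):
        permutation_test_vs_reference(default_table, reference=3, other=7)
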