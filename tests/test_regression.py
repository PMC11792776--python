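import numpy as np
import pytest
from sklearn.linear_model import Ridge

from nksynergy.imputation_maps import activation_matrix, reference_optimal_map
from nksynergy.regression import (
    FAMILIES,
    FAMILY_SIZES,
    build_design,
    fit,
    loocv,
    select_optimal,
)
from nksynergy.synthetic_data import SyntheticSpec, default_beta, generate_ground_truth_Y


@pytest.fixture(scope="module")
def ref_matrix(registry12):
    return activation_matrix(reference_optimal_map(), registry12)


@pytest.mark.parametrize(
    "family, ncols",
    [
        ("linear-priming", 5),
        ("linear+pairwise-priming", 15),
        ("linear-pp1", 5),
        ("linear+pairwise-pp1", 15),
        ("additive", 10),
        ("additive-pairwise", 30),
        ("multiplicative", 25),
        ("multiplicative-pairwise", 225),
    ],
)
def test_predictor_counts_per_family(ref_matrix, family, ncols):
    X = build_design(ref_matrix, family)
    assert X.values.shape == (12, ncols)
    assert len(set(X.labels)) == ncols
    assert FAMILY_SIZES[family] == ncols
    assert set(np.unique(X.values)) <= {0.0, 1.0}


def test_unknown_family_rejected(ref_matrix):
    with pytest.raises(ValueError, match="unknown model family"):
        build_design(ref_matrix, "cubic")


def test_cross_product_row_matches_outer_product_oracle(ref_matrix):
    # condition 2 under the reference map: priming active {S3,S4,S5,Sb},
    # PP-I active {S1~,S4~,S5~} -> 4 x 3 = 12 ones in the 25-column row
    X = build_design(ref_matrix, "multiplicative")
    row = X.values[list(ref_matrix.condition_ids).index(2)]
    assert row.sum() == 12
    act = ref_matrix.row(2)
    outer = np.outer(act[:5], act[5:]).ravel()
    assert row.tolist() == outer.tolist()
    for lbl, v in zip(X.labels, row):
        prime, pp1 = lbl.split("·")
        i = ["S1", "S3", "S4", "S5", "Sb"].index(prime)
        j = ["S1~", "S3~", "S4~", "S5~", "Sb~"].index(pp1)
        assert v == act[i] * act[5 + j]


def test_lambda_zero_reduces_to_least_squares():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, size=(12, 5)).astype(float)
    y = rng.normal(size=12)
    f = fit(X, y, "lasso", 0.0)
    A = np.column_stack([np.ones(12), X])
    coefs, *_ = np.linalg.lstsq(A, y, rcond=None)
    assert f.beta == pytest.approx(coefs[1:], abs=1e-8)
    assert f.intercept == pytest.approx(coefs[0], abs=1e-8)


def test_single_column_response_recovered(ref_matrix):
    X = build_design(ref_matrix, "linear-priming")
    y = 2.0 * X.values[:, 1]
    f = fit(X, y, "lasso", 0.0)
    expect = np.zeros(5)
    expect[1] = 2.0
    assert f.beta == pytest.approx(expect, abs=1e-8)


def test_large_lambda_shrinks_to_intercept_only():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, size=(10, 4)).astype(float)
    y = rng.normal(5.0, 1.0, size=10)
    f = fit(X, y, "lasso", 1e6)
    assert np.all(np.abs(f.beta) < 1e-10)
    assert f.intercept == pytest.approx(y.mean(), abs=1e-6)


def _lasso_objective(X, y, beta, b, lam):
    r = y - X @ beta - b
    return 0.5 * float(r @ r) + lam * float(np.abs(beta).sum())


def test_lasso_objective_matches_refining_grid_search():
    """Objective at the coordinate-descent solution matches a brute-force
    minimization of 0.5||y - Xb - b0||^2 + lam*||b||_1 within 1e-6."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, size=(8, 2)).astype(float)
    y = rng.normal(size=8)
    lam = 0.3
    f = fit(X, y, "lasso", lam)
    mine = _lasso_objective(X, y, f.beta, f.intercept, lam)

    # refining 3-d grid search, independent of the solver
    center = np.zeros(3)  # (b0, beta1, beta2)
    width = 4.0
    best = np.inf
    for _ in range(12):
        grid = [np.linspace(c - width, c + width, 9) for c in center]
        for b0 in grid[0]:
            for b1 in grid[1]:
                for b2 in grid[2]:
                    val = _lasso_objective(X, y, np.array([b1, b2]), b0, lam)
                    if val < best:
                        best, center = val, np.array([b0, b1, b2])
        width /= 3.0
    assert mine == pytest.approx(best, abs=1e-6)
    assert mine <= best + 1e-9  # the solver is at least as good as the search


def test_nonzero_label_bookkeeping(ref_matrix):
    X = build_design(ref_matrix, "linear-priming")
    y = 3.0 * X.values[:, 0] + 0.5
    f = fit(X, y, "lasso", 0.0)
    assert f.nonzero_labels == (X.labels[0],)


def test_non_finite_response_rejected(ref_matrix):
    X = build_design(ref_matrix, "linear-priming")
    with pytest.raises(ValueError, match="non-finite"):
        fit(X, np.array([np.nan] * 12), "lasso", 0.1)


def test_loocv_exact_fit_limit():
    # a condition panel whose linear-priming design keeps full column rank
    # in every leave-one-out fold: noise-free data is recovered exactly
    from nksynergy.study_data import Cytokine as C
    from nksynergy.study_data import CytokineCondition

    primings = [
        {C.IL2}, {C.IL12}, {C.IL15}, {C.IL18}, {C.IL21},
        {C.IL12, C.IL18}, {C.IL15, C.IL21}, {C.IL2, C.IL18},
        {C.IL12, C.IL15}, {C.IL15, C.IL18}, {C.IL12, C.IL21}, {C.IL18, C.IL21},
    ]
    conds = [CytokineCondition(i + 1, frozenset(p), frozenset({C.IL2})) for i, p in enumerate(primings)]
    imap = reference_optimal_map()
    X = build_design(activation_matrix(imap, conds), "linear-priming")
    A = np.column_stack([np.ones(12), X.values])
    for a in range(12):  # precondition: every fold keeps full rank
        assert np.linalg.matrix_rank(np.delete(A, a, axis=0)) == 6
    beta = np.array([1.0, 2.0, 0.5, 1.5, 0.7])
    y = X.values @ beta + 3.0
    entry = loocv(imap, "linear-priming", conds, y, "lasso", 0.0)
    assert entry.rss < 1e-8
    assert entry.r2 == pytest.approx(1.0)


def test_loocv_matches_explicit_fold_loop_with_independent_solver(registry12):
    imap = reference_optimal_map()
    beta = default_beta(SyntheticSpec(seed=2))
    rng = np.random.default_rng(3)
    y = generate_ground_truth_Y(imap, "multiplicative", beta) * np.exp(rng.normal(0, 0.05, 12))
    lam = 0.1
    entry = loocv(imap, "multiplicative", registry12, y, "ridge", lam)
    X = build_design(activation_matrix(imap, registry12), "multiplicative").values
    preds = np.empty(12)
    for a in range(12):  # explicit fold loop, sklearn Ridge directly
        mask = np.ones(12, bool)
        mask[a] = False
        model = Ridge(alpha=2 * lam, fit_intercept=True).fit(X[mask], y[mask])
        preds[a] = model.predict(X[a : a + 1])[0]
    assert entry.predictions == pytest.approx(preds, abs=1e-8)
    assert entry.rss == pytest.approx(float(((y - preds) ** 2).sum()), abs=1e-6)


def test_constant_predictions_report_missing_r2(registry12):
    imap = reference_optimal_map()
    with pytest.warns(UserWarning, match="constant predictions"):
        entry = loocv(imap, "linear-priming", registry12, np.full(12, 5.0), "lasso", 1e6)
    assert entry.r2 is None


def test_select_single_pair_passthrough(registry12):
    imap = reference_optimal_map()
    y = np.linspace(2, 20, 12)
    sel = select_optimal([imap], registry12, y, families=("linear-priming",))
    assert sel.best.map_signature == imap.content_signature
    assert sel.best.family == "linear-priming"
    assert len(sel.entries) == 1


def test_duplicate_winner_tie_is_logged(registry12):
    imap = reference_optimal_map()
    y = np.linspace(2, 20, 12)
    sel = select_optimal([imap, imap], registry12, y, families=("linear-priming",))
    assert "tie" in sel.tie_note.lower()
    assert sel.best.map_index == imap.map_index


def test_empty_inputs_rejected(registry12):
    with pytest.raises(ValueError, match="feasible map"):
        select_optimal([], registry12, np.linspace(2, 20, 12))
    with pytest.raises(ValueError, match="family list"):
        select_optimal([reference_optimal_map()], registry12, np.linspace(2, 20, 12), families=())


def test_noise_free_planted_beta_recovery_on_identifiable_design(registry12):
    # linear-priming design is full rank for the reference map's matrix
    imap = reference_optimal_map()
    X = build_design(activation_matrix(imap, registry12), "linear-priming")
    assert np.linalg.matrix_rank(np.column_stack([np.ones(12), X.values])) == 6
    beta = np.array([0.8, 2.2, 0.4, 1.1, 1.9])
    y = X.values @ beta + 1.0
    f = fit(X, y, "lasso", 0.0)
    assert f.beta == pytest.approx(beta, abs=1e-8)
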