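"""OPLS-DA core: NIPALS oracle agreement, VIP identity, Q2, permutations."""

import numpy as np
import pytest

from herbgrade.opls import (
    OplsError,
    PreprocessSpec,
    cross_validated_q2,
    fit_opls_da,
    permutation_test,
    preprocess,
    vip,
)


# ----------------------------------------------------------------------
# independent oracle: minimal NIPALS PLS1/PLS2 run to tight convergence
# ----------------------------------------------------------------------
def _nipals_oracle(X, Y, n_components, tol=1e-12):
    Xr = X.copy()
    Yr = Y.copy()
    T = []
    for _ in range(n_components):
        u = Yr[:, 0].copy()
        t_prev = None
        for _ in range(5000):
            w = Xr.T @ u
            w /= np.linalg.norm(w)
            t = Xr @ w
            c = Yr.T @ t / (t @ t)
            u = Yr @ c / (c @ c)
            if t_prev is not None and np.linalg.norm(t - t_prev) <= tol:
                break
            t_prev = t
        p = Xr.T @ t / (t @ t)
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, c)
        T.append(t)
    return np.column_stack(T)


def _two_class(rng, n=16, p=5, shift=0.0):
    X = rng.normal(size=(n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    X[y == "b", :2] += shift
    return X, y


def test_zero_orthogonal_matches_nipals_oracle(rng):
    X, y = _two_class(rng, n=8, p=3)
    model = fit_opls_da(X, y, n_orthogonal=0)
    Xt, _ = preprocess(X)
    Yc = (y == "b").astype(float)[:, None]
    Yc = Yc - Yc.mean()
    T_ref = _nipals_oracle(Xt, Yc, model.n_predictive)
    for a in range(model.n_predictive):
        sign = np.sign(T_ref[:, a] @ model.T[:, a])
        assert np.allclose(model.T[:, a], sign * T_ref[:, a], atol=1e-8)


def test_zero_orthogonal_matches_sklearn_pls(rng):
    from sklearn.cross_decomposition import PLSRegression

    X, y = _two_class(rng, n=20, p=6, shift=1.0)
    model = fit_opls_da(X, y, n_orthogonal=0)
    ref = PLSRegression(n_components=1, scale=True).fit(X, (y == "b").astype(float))
    t_ref = ref.x_scores_[:, 0]
    sign = np.sign(t_ref @ model.T[:, 0])
    assert np.allclose(model.T[:, 0], sign * t_ref, atol=1e-6)


def test_perfectly_predictive_column(rng):
    n = 20
    y = np.array(["a", "b"] * (n // 2))
    X = rng.normal(size=(n, 6))
    X[:, 0] = (y == "b").astype(float)  # exact class indicator
    # the class block lies in the column span, so a full fit is exact
    full = fit_opls_da(X, y, n_orthogonal=0, n_predictive=6)
    assert full.r2y_cum == pytest.approx(1.0, abs=1e-6)
    scores = vip(fit_opls_da(X, y, n_orthogonal=0))
    assert scores.values.idxmax() == 0
    assert scores.values.iloc[0] > 1


@pytest.mark.parametrize("n_classes,n_orth", [(2, 1), (2, 2), (4, 1)])
def test_orthogonal_scores_uncorrelated_with_class_block(rng, n_classes, n_orth):
    n, p = 12 * n_classes, 8
    X = rng.normal(size=(n, p))
    y = np.repeat([f"g{i}" for i in range(n_classes)], n // n_classes)
    model = fit_opls_da(X, y, n_orthogonal=n_orth)
    from herbgrade.opls import _class_block

    Yc = _class_block(y, np.unique(y))
    Yc = Yc - Yc.mean(axis=0)
    for a in range(n_orth):
        for k in range(Yc.shape[1]):
            r = np.corrcoef(model.T_o[:, a], Yc[:, k])[0, 1]
            assert abs(r) < 1e-8


@pytest.mark.parametrize("n_classes,n_orth,shift", [
    (2, 0, 0.0), (2, 1, 2.0), (4, 1, 1.0), (3, 2, 0.5),
])
def test_vip_mean_square_is_one(rng, n_classes, n_orth, shift):
    n, p = 10 * n_classes, 9
    X = rng.normal(size=(n, p))
    y = np.repeat([f"g{i}" for i in range(n_classes)], n // n_classes)
    for i in range(n_classes):
        X[y == f"g{i}", i % p] += shift * i
    model = fit_opls_da(X, y, n_orthogonal=n_orth)
    v = vip(model).values.to_numpy()
    assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-8)
    assert (v >= 0).all()


def test_single_variable_vip_is_exactly_one(rng):
    X = rng.normal(size=(12, 1))
    y = np.array(["a", "b"] * 6)
    model = fit_opls_da(X, y, n_orthogonal=0)
    assert vip(model).values.iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_planted_variables_take_top_vip(rng):
    X, y = _two_class(rng, n=30, p=10, shift=3.0)
    model = fit_opls_da(X, y, n_orthogonal=1)
    top2 = set(vip(model).values.nlargest(2).index)
    assert top2 == {0, 1}
    assert (vip(model).values[[0, 1]] > 1).all()


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------
def test_leave_one_out_matches_brute_force(rng):
    X, y = _two_class(rng, n=6, p=4, shift=2.0)
    q2 = cross_validated_q2(X, y, n_orthogonal=0, k_folds=6, seed=0)
    # brute force: refit on every leave-one-out split, accumulate PRESS
    Y = (y == "b").astype(float)[:, None]
    ss = float(((Y - Y.mean()) ** 2).sum())
    press = 0.0
    for i in range(6):
        tr = np.delete(np.arange(6), i)
        m = fit_opls_da(X[tr], y[tr], n_orthogonal=0)
        press += float(((Y[i] - m.predict_y(X[[i]])) ** 2).sum())
    assert q2 == pytest.approx(1.0 - press / ss, abs=1e-10)


def test_q2_null_distribution(rng):
    hits = 0
    for s in range(50):
        r = np.random.default_rng(s)
        X = r.normal(size=(60, 10))
        y = r.permutation(np.repeat(["a", "b"], 30))
        if cross_validated_q2(X, y, n_orthogonal=1, seed=s) <= 0.05:
            hits += 1
    assert hits >= 48  # label-independent data almost never predicts


def test_q2_strong_signal(rng):
    X = rng.normal(size=(60, 10))
    y = np.repeat(["a", "b"], 30)
    X[y == "b", :3] += 5.0
    assert cross_validated_q2(X, y, n_orthogonal=1, seed=0) > 0.9


@pytest.mark.parametrize("shift", [0.5, 2.0])
def test_q2_never_exceeds_r2y(rng, shift):
    X, y = _two_class(rng, n=30, p=8, shift=shift)
    model = fit_opls_da(X, y, n_orthogonal=1)
    q2 = cross_validated_q2(X, y, n_orthogonal=1, seed=1)
    assert q2 <= model.r2y_cum + 1e-8


def test_orthogonal_deflation_never_increases_r2y(rng):
    X, y = _two_class(rng, n=24, p=8, shift=1.0)
    r2y = [fit_opls_da(X, y, n_orthogonal=k).r2y_cum for k in range(3)]
    # removing Y-orthogonal variation cannot add explained Y variance
    # beyond the single-component ceiling reached without it
    assert max(r2y) <= r2y[2] + 1e-6


# ----------------------------------------------------------------------
# permutation test
# ----------------------------------------------------------------------
def test_permutation_p_floor_with_strong_separation(rng):
    X, y = _two_class(rng, n=20, p=8, shift=5.0)
    summary = permutation_test(X, y, n_permutations=200, seed=3)
    assert summary.p_value == pytest.approx(1 / 201)
    assert summary.valid


def test_single_permutation_p_is_half(rng):
    X, y = _two_class(rng, n=20, p=8, shift=5.0)
    summary = permutation_test(X, y, n_permutations=1, seed=0)
    assert summary.p_value == pytest.approx(0.5)


def test_permutation_rejects_constant_labels(rng):
    X = rng.normal(size=(10, 4))
    with pytest.raises(OplsError, match="constant"):
        permutation_test(X, np.repeat("a", 10))


# ----------------------------------------------------------------------
# preprocessing and error handling
# ----------------------------------------------------------------------
def test_preprocess_unit_variance(rng):
    X = rng.normal(2.0, 3.0, size=(15, 5))
    Xt, fitted = preprocess(X)
    assert np.allclose(Xt.mean(axis=0), 0, atol=1e-8)
    assert np.allclose(Xt.var(axis=0, ddof=1), 1, atol=1e-8)


def test_preprocess_drops_constant_column_and_records_it(rng):
    X = rng.normal(size=(10, 3))
    X[:, 1] = 7.0
    Xt, fitted = preprocess(X)
    assert Xt.shape[1] == 2
    assert fitted.dropped == [1]
    with pytest.raises(OplsError, match="zero-variance"):
        preprocess(X, PreprocessSpec(zero_variance="error"))


def test_preprocess_rejects_all_constant():
    with pytest.raises(OplsError, match="zero variance"):
        preprocess(np.ones((5, 3)))


def test_held_out_rows_use_training_parameters(rng):
    X = rng.normal(5.0, 2.0, size=(10, 4))
    _, fitted = preprocess(X)
    new = rng.normal(50.0, 1.0, size=(2, 4))
    applied = fitted.apply(new)
    manual = (new - fitted.mean) / fitted.sd
    assert np.allclose(applied, manual)


def test_fit_rejects_degenerate_inputs(rng):
    X = rng.normal(size=(5, 3))
    with pytest.raises(OplsError, match="fewer than 2"):
        fit_opls_da(X, np.array(["a", "a", "a", "a", "b"]))
    with pytest.raises(OplsError, match="at least 2 classes"):
        fit_opls_da(X, np.repeat("a", 5))
    with pytest.raises(OplsError, match="rank"):
        fit_opls_da(X, np.array(["a", "a", "b", "b", "b"]), n_orthogonal=10)
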