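"""Correlation, regression, and canonical discriminant analysis."""

import numpy as np
import pandas as pd
import pytest

from weedvol.stats import (
    GroupSizeError,
    analyze_dataset,
    cda_confusion,
    cda_fit,
    ols_fit,
    pearson,
)


# ---------------------------------------------------------------------------
# pearson / OLS


def test_perfect_lines_give_unit_correlation():
    x = np.arange(1.0, 11.0)
    assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_matches_hand_formula():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 5.0])
    r, p = pearson(x, y)
    cx, cy = x - x.mean(), y - y.mean()
    expected = (cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum())
    assert r == pytest.approx(expected, abs=1e-12)
    # p from the exact t transform with n-2 dof
    from scipy.stats import t as tdist

    tstat = expected * np.sqrt(2 / (1 - expected**2))
    assert p == pytest.approx(2 * tdist.sf(abs(tstat), 2), rel=1e-6)


def test_constant_input_raises_zero_variance():
    with pytest.raises(ValueError, match="zero variance"):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_affine_invariance_and_sign_flip():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=50), rng.normal(size=50)
    r0 = pearson(x, y)[0]
    assert pearson(3.0 * x + 5.0, y)[0] == pytest.approx(r0, abs=1e-12)
    assert pearson(-x, y)[0] == pytest.approx(-r0, abs=1e-12)


def test_ols_exact_line_and_degenerate_y():
    x = np.arange(1.0, 8.0)
    fit = ols_fit(x, 3 * x - 2)
    assert fit.slope == pytest.approx(3.0)
    assert fit.intercept == pytest.approx(-2.0)
    assert fit.r_squared == pytest.approx(1.0)
    flat = ols_fit(x, np.full_like(x, 4.0))
    assert flat.slope == 0.0 and flat.r_squared == 0.0 and flat.intercept == 4.0


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    y = 1.7 * x + rng.normal(size=30)
    fit = ols_fit(x, y)
    A = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert fit.slope == pytest.approx(beta[0], abs=1e-10)
    assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
    assert fit.r_squared == pytest.approx(fit.r**2, abs=1e-12)


# ---------------------------------------------------------------------------
# CDA


def test_well_separated_groups_classify_perfectly():
    rng = np.random.default_rng(2)
    a = rng.normal(0.05, 0.01, size=(15, 1))
    b = rng.normal(0.18, 0.01, size=(15, 1))
    X = np.vstack([a, b])
    y = np.array(["dicots"] * 15 + ["monocots"] * 15)
    cm = cda_confusion(cda_fit(X, y), X, y, scheme="leave_one_out")
    assert np.allclose(np.diag(cm.percentages), 100.0)


def test_identical_groups_score_at_chance_level():
    rng = np.random.default_rng(3)
    n = 60
    X = rng.normal(size=(2 * n, 2))
    y = np.array(["monocots"] * n + ["dicots"] * n)
    cm = cda_confusion(None, X, y, scheme="leave_one_out")
    acc = np.trace(cm.counts) / cm.counts.sum()
    # binomial 99% band around p = 0.5 for 120 trials
    from scipy.stats import binom

    lo, hi = binom.ppf([0.005, 0.995], 2 * n, 0.5) / (2 * n)
    assert lo <= acc <= hi


def test_canonical_axes_match_generalized_eigenproblem_oracle():
    rng = np.random.default_rng(4)
    X = np.vstack(
        [
            rng.normal([0, 0], 0.3, size=(20, 2)),
            rng.normal([1.0, 0.3], 0.3, size=(20, 2)),
            rng.normal([0.4, 1.2], 0.3, size=(20, 2)),
        ]
    )
    y = np.array(["monocots"] * 20 + ["dicots"] * 20 + ["mixture"] * 20)
    model = cda_fit(X, y)
    # brute-force oracle: eigenvectors of inv(Sw) @ Sb
    groups = model.group_labels
    means = np.vstack([X[y == g].mean(axis=0) for g in groups])
    center = X.mean(axis=0)
    Sw = sum((X[y == g] - means[i]).T @ (X[y == g] - means[i]) for i, g in enumerate(groups))
    Sw /= len(X) - 3
    Sb = sum(
        (y == g).sum() * np.outer(means[i] - center, means[i] - center)
        for i, g in enumerate(groups)
    ) / 2
    w, v = np.linalg.eig(np.linalg.inv(Sw) @ Sb)
    order = np.argsort(w.real)[::-1]
    for k in range(model.n_axes):
        mine = model.canonical_coefficients[:, k]
        ref = v.real[:, order[k]]
        cos = abs(mine @ ref) / (np.linalg.norm(mine) * np.linalg.norm(ref))
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_classification_matches_sklearn_lda():
    """Nearest centroid in canonical space equals LDA with equal priors."""
    sklearn = pytest.importorskip("sklearn.discriminant_analysis")
    rng = np.random.default_rng(5)
    X = np.vstack(
        [
            rng.normal([0, 0], 0.5, size=(25, 2)),
            rng.normal([1.2, 0.2], 0.5, size=(25, 2)),
            rng.normal([0.5, 1.0], 0.5, size=(25, 2)),
        ]
    )
    y = np.array(["monocots"] * 25 + ["dicots"] * 25 + ["mixture"] * 25)
    model = cda_fit(X, y)
    lda = sklearn.LinearDiscriminantAnalysis(priors=[1 / 3, 1 / 3, 1 / 3])
    lda.fit(X, y)
    assert np.array_equal(model.classify(X), lda.predict(X))


def test_classification_invariant_to_affine_feature_transform():
    rng = np.random.default_rng(6)
    X = np.vstack(
        [rng.normal([0, 0], 0.4, size=(20, 2)), rng.normal([1, 1], 0.4, size=(20, 2))]
    )
    y = np.array(["monocots"] * 20 + ["dicots"] * 20)
    A = np.array([[2.0, 0.5], [-0.3, 1.5]])
    Xt = X @ A.T + [10.0, -4.0]
    assert np.array_equal(cda_fit(X, y).classify(X), cda_fit(Xt, y).classify(Xt))


def test_confusion_rows_sum_to_100_and_small_group_errors():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 2))
    y = np.array(["monocots"] * 10 + ["dicots"] * 10 + ["mixture"] * 10)
    cm = cda_confusion(None, X, y, scheme="resubstitution")
    assert np.allclose(cm.percentages.sum(axis=1), 100.0, atol=0.1)
    with pytest.raises(GroupSizeError, match="dicots"):
        cda_fit(X[:11], np.array(["monocots"] * 10 + ["dicots"]))


def test_collinear_features_are_ridge_handled():
    """Perfectly collinear features (p90 = 0.9 max) must still fit."""
    rng = np.random.default_rng(8)
    h = np.concatenate([rng.uniform(0.02, 0.10, 10), rng.uniform(0.12, 0.20, 10)])
    X = np.column_stack([h, 0.9 * h])
    y = np.array(["dicots"] * 10 + ["monocots"] * 10)
    cm = cda_confusion(cda_fit(X, y), X, y, scheme="leave_one_out")
    assert np.allclose(np.diag(cm.percentages), 100.0)


# ---------------------------------------------------------------------------
# dataset analysis


def _toy_dataset(n=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    maize_v = rng.uniform(0, 3e-3, n)
    weed_v = rng.uniform(0, 1e-3, n)
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "maize_volume_m3": maize_v,
            "weed_volume_m3": weed_v,
            "maize_biomass_g": 14000 * maize_v * (1 + noise * rng.normal(size=n)),
            "weed_biomass_g": 10000 * weed_v * (1 + noise * rng.normal(size=n)),
            "weed_density": rng.integers(0, 12, n),
            "maize_count": np.full(n, 3),
            "weed_class": ["monocots", "dicots", "mixture"] * (n // 3),
            "weed_max_height_m": rng.uniform(0.02, 0.2, n),
            "weed_p90_height_m": rng.uniform(0.02, 0.18, n),
        }
    )
    return df


def test_exact_proportionality_gives_unit_correlations():
    rep = analyze_dataset(_toy_dataset())
    rel = rep["relationships"]
    assert rel["maize_volume~maize_biomass"]["r"] == pytest.approx(1.0)
    assert rel["weed_volume~weed_biomass"]["r"] == pytest.approx(1.0)


def test_constant_maize_count_is_flagged_degenerate():
    rep = analyze_dataset(_toy_dataset())
    entry = rep["relationships"]["maize_count~maize_volume"]
    assert "flag" in entry and "degenerate" in entry["flag"]


def test_cda_block_present_with_row_order():
    rep = analyze_dataset(_toy_dataset())
    assert rep["cda"]["labels"] == ["monocots", "dicots", "mixture"]
    assert np.allclose(np.sum(rep["cda"]["percentages"], axis=1), 100.0, atol=0.1)
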