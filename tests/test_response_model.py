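import numpy as np
import pandas as pd
import pytest

from iratri.response_model import (
    FeatureTable,
    _cd_binomial,
    assemble_features,
    bootstrap_evaluate,
    confusion_stats,
    feature_weightage,
    fit_penalized_logistic,
    majority_vote,
    roc_auc,
    standardize,
)


def make_table(X, y, names=None):
    n, p = X.shape
    names = names or [f"f{j}" for j in range(p)]
    _, (means, sds) = standardize(X)
    return FeatureTable(
        samples=np.array([f"s{i:02d}" for i in range(n)]),
        feature_names=list(names), X_raw=X, y=np.asarray(y, dtype=int),
        means=means, sds=sds, missing_mask=np.isnan(X),
    )


def logistic_sample(rng, n, beta, intercept=0.0):
    X = rng.normal(size=(n, len(beta)))
    p = 1.0 / (1.0 + np.exp(-(X @ beta + intercept)))
    y = (rng.random(n) < p).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# ROC AUC


def auc_pairwise_oracle(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_worked_example_and_edges():
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_auc_equals_pairwise_concordance_on_random_instances():
    rng = np.random.default_rng(21)
    for _ in range(200):
        n = int(rng.integers(4, 30))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pairwise_oracle(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# elastic-net GLM


def irls_logistic_oracle(X, y, ridge=1e-8, iters=200):
    """Unpenalized (ridge-floored) logistic MLE by plain Newton/IRLS."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    theta = np.zeros(p + 1)
    for _ in range(iters):
        eta = Z @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Z.T @ (y - mu) - ridge * np.r_[0.0, theta[1:]]
        hess = (Z * w[:, None]).T @ Z + ridge * np.diag(np.r_[0.0, np.ones(p)])
        step = np.linalg.solve(hess, grad)
        theta += step
        if np.max(np.abs(step)) < 1e-12:
            break
    return theta[0], theta[1:]


def test_cd_matches_irls_oracle_at_vanishing_penalty():
    """At lambda -> 0 the elastic-net fit is the unpenalized MLE."""
    rng = np.random.default_rng(4)
    X, y = logistic_sample(rng, 120, np.array([0.8, -0.6, 0.0]), intercept=0.3)
    beta, b0 = _cd_binomial(X, y.astype(float), 1e-9, 0.3, np.zeros(3), 0.0,
                            max_outer=500, tol=1e-12)
    b0_ref, beta_ref = irls_logistic_oracle(X, y.astype(float))
    np.testing.assert_allclose(beta, beta_ref, atol=1e-4)
    assert b0 == pytest.approx(b0_ref, abs=1e-4)


def test_cd_matches_sklearn_saga_at_matched_penalty():
    """Independent cross-check of the elastic-net objective and solution."""
    import warnings
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(8)
    X, y = logistic_sample(rng, 40, np.array([1.2, -0.8, 0.4, 0.0]))
    for lam in (0.02, 0.1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = LogisticRegression(penalty="elasticnet", solver="saga",
                                    l1_ratio=0.3, C=1.0 / (len(y) * lam),
                                    max_iter=500_000, tol=1e-12).fit(X, y)
        beta, b0 = _cd_binomial(X, y.astype(float), lam, 0.3, np.zeros(4), 0.0,
                                max_outer=500, tol=1e-12)
        np.testing.assert_allclose(beta, sk.coef_[0], atol=1e-6)
        assert b0 == pytest.approx(float(sk.intercept_[0]), abs=1e-6)


def test_large_penalty_zeroes_all_coefficients():
    rng = np.random.default_rng(2)
    X, y = logistic_sample(rng, 60, np.array([1.0, -1.0]))
    fit = fit_penalized_logistic(X, y, lambdas=np.array([50.0]), seed=0)
    np.testing.assert_allclose(fit.coef, 0.0)


def test_single_class_labels_raise():
    with pytest.raises(ValueError, match="single-class"):
        fit_penalized_logistic(np.zeros((5, 2)), np.ones(5))


def test_cv_fit_deterministic_under_seed():
    rng = np.random.default_rng(14)
    X, y = logistic_sample(rng, 50, np.array([1.0, 0.0, -0.5]))
    f1 = fit_penalized_logistic(X, y, seed=7, n_lambda=30)
    f2 = fit_penalized_logistic(X, y, seed=7, n_lambda=30)
    assert f1.lambda_ == f2.lambda_
    np.testing.assert_array_equal(f1.coef, f2.coef)


# ---------------------------------------------------------------------------
# feature assembly


def index_rows(samples, cell_types, values, column):
    rows = []
    for s, per_ct in zip(samples, values):
        for ct, v in zip(cell_types, per_ct):
            rows.append((s, ct, v))
    return pd.DataFrame(rows, columns=["sample_id", "cell_type", column])


def test_assemble_features_schema_and_standardization():
    cts = ["CD4_CXCL13_Tfh", "CD8_CXCL13", "CD4_TGFB1", "CD8_Temra"]
    samples = [f"s{i}" for i in range(6)]
    rng = np.random.default_rng(0)
    gsea = index_rows(samples, cts, rng.normal(size=(6, 4)), "gsea_index")
    clonal = index_rows(samples, cts, rng.normal(size=(6, 4)), "fc_index")
    meta = pd.DataFrame(
        {"barcode": samples, "sample_id": samples, "treatment": "post",
         "response": ["R", "R", "R", "NR", "NR", "NR"], "cell_type": "x"}
    )
    table = assemble_features(gsea, clonal, meta, cell_types=cts)
    assert table.X_raw.shape == (6, 8)
    assert len(table.feature_names) == 8
    Xs = table.X_standardized
    np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-9)


def test_assemble_features_imputes_missing_as_zero_after_standardization():
    cts = ["CD4_CXCL13_Tfh", "CD8_CXCL13", "CD4_TGFB1", "CD8_Temra"]
    samples = [f"s{i}" for i in range(5)]
    rng = np.random.default_rng(1)
    values = rng.normal(size=(5, 4))
    values[2, 1] = np.nan
    gsea = index_rows(samples, cts, values, "gsea_index")
    clonal = index_rows(samples, cts, rng.normal(size=(5, 4)), "fc_index")
    meta = pd.DataFrame(
        {"barcode": samples, "sample_id": samples, "treatment": "post",
         "response": ["R", "R", "NR", "NR", "NR"], "cell_type": "x"}
    )
    table = assemble_features(gsea, clonal, meta, cell_types=cts)
    col = table.feature_names.index("gsea_index.CD8_CXCL13")
    assert table.missing_mask[2, col]
    assert table.X_standardized[2, col] == 0.0


# ---------------------------------------------------------------------------
# bootstrap evaluation


def test_bootstrap_separable_features_reach_auc_one():
    rng = np.random.default_rng(3)
    y = np.r_[np.ones(12), np.zeros(12)].astype(int)
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.1, 24), rng.normal(size=24)])
    res = bootstrap_evaluate(make_table(X, y), n_rounds=20, seed=5, n_lambda=30)
    assert res.mean_auc == pytest.approx(1.0)


def test_bootstrap_null_labels_auc_near_half():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(30, 4))
    y = rng.permutation(np.r_[np.ones(15), np.zeros(15)]).astype(int)
    res = bootstrap_evaluate(make_table(X, y), n_rounds=100, seed=6, n_lambda=30)
    assert abs(res.mean_auc - 0.5) < 0.1


def test_bootstrap_deterministic_and_70_30_split():
    rng = np.random.default_rng(11)
    X, y = logistic_sample(rng, 20, np.array([1.0, -0.5]))
    if y.min() == y.max():
        y[0] = 1 - y[0]
    r1 = bootstrap_evaluate(make_table(X, y), n_rounds=10, seed=9, n_lambda=20)
    r2 = bootstrap_evaluate(make_table(X, y), n_rounds=10, seed=9, n_lambda=20)
    assert r1.aucs == r2.aucs and r1.votes == r2.votes
    for idx in r1.train_indices:
        assert len(idx) == round(0.7 * (y == 1).sum()) + round(0.7 * (y == 0).sum())
    for a in r1.aucs:
        assert np.isnan(a) or 0.0 <= a <= 1.0


# ---------------------------------------------------------------------------
# voting and confusion


def test_majority_vote_boundary_rules():
    votes = {"a": [1] * 11 + [0] * 10,    # 11/21 -> responder
             "b": [1] * 10 + [0] * 10,    # 10/20 tie -> non-responder
             "c": [0, 0, 1]}
    classes, flags = majority_vote(votes)
    assert classes == {"a": 1, "b": 0, "c": 0}
    assert not any(flags.values())


def test_majority_vote_fallback_for_never_tested_sample():
    rng = np.random.default_rng(2)
    y = np.r_[np.ones(6), np.zeros(6)].astype(int)
    X = np.column_stack([y * 3.0 + rng.normal(0, 0.1, 12)])
    table = make_table(X, y)
    fit = fit_penalized_logistic(table.X_standardized, table.y, seed=0, n_lambda=20)
    votes = {s: [int(v)] for s, v in zip(table.samples, y)}
    votes[table.samples[0]] = []
    classes, flags = majority_vote(votes, fallback=fit, table=table)
    assert flags[table.samples[0]]
    assert classes[table.samples[0]] == 1
    with pytest.raises(ValueError):
        majority_vote({"x": []})


def test_confusion_stats_closed_form():
    # TP=3, FP=1, FN=2, TN=4
    truth = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
    out = confusion_stats(pred, truth)
    assert out["table"] == {"TP": 3, "FP": 1, "FN": 2, "TN": 4}
    assert out["accuracy"] == pytest.approx(0.7)
    assert out["sensitivity"] == pytest.approx(0.6)
    assert out["specificity"] == pytest.approx(0.8)
    assert out["precision"] == pytest.approx(0.75)
    p_e = 0.4 * 0.5 + 0.6 * 0.5
    assert out["kappa"] == pytest.approx((0.7 - p_e) / (1 - p_e))


def test_confusion_stats_perfect_and_chance():
    perfect = confusion_stats([1, 0, 1], [1, 0, 1])
    assert perfect["accuracy"] == 1.0 and perfect["kappa"] == 1.0
    chance = confusion_stats([1, 1, 1, 1], [1, 0, 1, 0])
    assert chance["kappa"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# weightage


def test_weightage_zero_coefficient_and_rescaling_invariance():
    coefs = np.array([[0.0, 2.0], [0.0, -1.0]])
    w = feature_weightage(coefs)
    assert w[0] == 0.0 and w[1] == pytest.approx(1.5)
    # raw-scale coefficients: rescaling a feature by c multiplies its sd by c
    # and divides its coefficient by c, leaving the weightage unchanged
    rng = np.random.default_rng(0)
    raw_coef = rng.normal(size=(5, 3))
    sds = np.array([1.0, 2.0, 0.5])
    w1 = feature_weightage(raw_coef, sds)
    w2 = feature_weightage(raw_coef / 10.0, sds * 10.0)
    np.testing.assert_allclose(w1, w2)


def test_planted_feature_receives_top_weightage_and_duplication_splits_it():
    """A class-shifted feature dominates the weightages; duplicating that
    column splits its weight without letting noise features overtake."""
    rng = np.random.default_rng(17)
    n = 60
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    X = rng.normal(size=(n, 6))
    X[:, 2] += y * 1.5
    res = bootstrap_evaluate(make_table(X, y), n_rounds=40, seed=13, n_lambda=30)
    w = feature_weightage(res.coefs)
    assert int(np.argmax(w)) == 2

    X_dup = np.column_stack([X, X[:, 2]])
    res_dup = bootstrap_evaluate(make_table(X_dup, y), n_rounds=40, seed=13, n_lambda=30)
    w_dup = feature_weightage(res_dup.coefs)
    noise = [j for j in range(6) if j != 2]
    assert w_dup[2] + w_dup[6] > max(w_dup[j] for j in noise)
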