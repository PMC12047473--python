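"""Penalized binomial response classifier with bootstrap evaluation.

Features are, per post-treatment sample, the GSEA index and the clonal
fold-change index of each of the four response-associated T cell subsets
(8 features). The classifier is a binomial GLM with elastic-net penalty

    (1/n) sum_i -loglik_i + lambda * (alpha * |beta|_1 + (1-alpha)/2 * |beta|_2^2)

with mixing alpha = 0.3 (30% lasso, 70% ridge) and lambda chosen by
10-fold cross-validated binomial deviance on a 100-point log-spaced grid
descending four decades from lambda_max (the smallest lambda that zeroes
every coefficient). The fit is the standard glmnet-style algorithm:
an outer iteratively reweighted least-squares (IRLS) quadratic
approximation with an inner cyclic coordinate descent and soft
thresholding, warm-started along the lambda path.

Evaluation repeats 100 rounds of stratified random 70/30 resplits;
standardization is refit on each round's training set so no information
leaks into the test fold. Final per-sample classes come from majority
voting over the rounds in which the sample was held out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

INDEX_FAMILIES = ("gsea_index", "clonal_fc_index")


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class FeatureTable:
    """Per-sample feature matrix with labels and standardization parameters."""

    samples: np.ndarray
    feature_names: list[str]
    X_raw: np.ndarray           # may contain NaN where an index is missing
    y: np.ndarray               # 1 = responder, 0 = non-responder
    means: np.ndarray
    sds: np.ndarray
    missing_mask: np.ndarray    # True where a raw value was imputed

    @property
    def X_standardized(self) -> np.ndarray:
        Xs = (self.X_raw - self.means) / self.sds
        return np.where(np.isnan(Xs), 0.0, Xs)


def standardize(X: np.ndarray, params: tuple[np.ndarray, np.ndarray] | None = None):
    """Zero-mean unit-variance scaling, NaN-aware; returns (Xs, (means, sds)).

    Missing values are imputed as the column mean (0 after scaling).
    Constant columns get sd 1 so they map to 0 rather than NaN.
    """
    if params is None:
        means = np.nanmean(X, axis=0)
        sds = np.nanstd(X, axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)
    else:
        means, sds = params
    Xs = (X - means) / sds
    return np.where(np.isnan(Xs), 0.0, Xs), (means, sds)


def assemble_features(
    gsea_rows: pd.DataFrame,
    clonal_rows: pd.DataFrame,
    meta: pd.DataFrame,
    cell_types: list[str] | None = None,
) -> FeatureTable:
    """Pivot per-sample indices into the 8-column feature table.

    Keeps post-treatment samples with a known R/NR label. A sample missing
    every feature is dropped with a warning; individual missing features are
    flagged and imputed as the (training) mean, i.e. 0 after
    standardization.
    """
    labeled_post = (meta["treatment"] == "post") & meta["response"].isin(["R", "NR"])
    sample_meta = (
        meta[labeled_post]
        .drop_duplicates("sample_id")[["sample_id", "response"]]
        .sort_values("sample_id")
    )
    if cell_types is None:
        cell_types = sorted(set(gsea_rows["cell_type"]) | set(clonal_rows["cell_type"]))

    g = gsea_rows.pivot_table(index="sample_id", columns="cell_type",
                              values="gsea_index", aggfunc="first")
    c = clonal_rows.pivot_table(index="sample_id", columns="cell_type",
                                values="fc_index", aggfunc="first")
    cols, names = [], []
    for ct in cell_types:
        for family, frame in (("gsea_index", g), ("clonal_fc_index", c)):
            series = frame[ct] if ct in frame.columns else pd.Series(dtype=float)
            cols.append(series.reindex(sample_meta["sample_id"]).to_numpy(dtype=float))
            names.append(f"{family}.{ct}")
    X = np.column_stack(cols)
    y = (sample_meta["response"] == "R").to_numpy(dtype=int)
    samples = sample_meta["sample_id"].to_numpy()

    all_missing = np.isnan(X).all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d samples with no features: %s",
                       int(all_missing.sum()), list(samples[all_missing]))
        X, y, samples = X[~all_missing], y[~all_missing], samples[~all_missing]

    missing = np.isnan(X)
    _, (means, sds) = standardize(X)
    return FeatureTable(samples=samples, feature_names=names, X_raw=X, y=y,
                        means=means, sds=sds, missing_mask=missing)


# ---------------------------------------------------------------------------
# elastic-net binomial GLM (coordinate descent)


@dataclass
class GlmFit:
    coef: np.ndarray
    intercept: float
    lambda_: float
    mixing: float
    cv_lambdas: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(X))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@numba.njit(cache=False)
def _cd_kernel(X, y, lam, alpha, beta, b0, max_outer, tol, max_inner):  # pragma: no cover
    """Elastic-net binomial coordinate-descent kernel (JIT-compiled).

    Outer loop: IRLS quadratic approximation at the current coefficients;
    inner loop: cyclic coordinate descent with soft thresholding on the
    penalized weighted least-squares problem, residual updated
    incrementally. Mutates *beta* in place; returns the intercept.
    """
    n, p = X.shape
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    w = np.empty(n)
    r = np.empty(n)
    denom = np.empty(p)
    for _outer in range(max_outer):
        wsum = 0.0
        for i in range(n):
            eta = b0
            for j in range(p):
                eta += X[i, j] * beta[j]
            ec = min(max(eta, -30.0), 30.0)
            mu = 1.0 / (1.0 + np.exp(-ec))
            wi = mu * (1.0 - mu)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            r[i] = (y[i] - mu) / wi  # working response minus current eta
            wsum += wi
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            denom[j] = s / n + l2
        beta_start = beta.copy()
        b0_start = b0
        for _cycle in range(max_inner):
            delta = 0.0
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            db0 = num / wsum
            if db0 != 0.0:
                b0 += db0
                for i in range(n):
                    r[i] -= db0
                delta = abs(db0)
            for j in range(p):
                rho = 0.0
                for i in range(n):
                    rho += w[i] * X[i, j] * r[i]
                rho = rho / n + (denom[j] - l2) * beta[j]
                if rho > l1:
                    bj = (rho - l1) / denom[j]
                elif rho < -l1:
                    bj = (rho + l1) / denom[j]
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bj
                    if abs(d) > delta:
                        delta = abs(d)
            if delta < tol:
                break
        change = abs(b0 - b0_start)
        for j in range(p):
            if abs(beta[j] - beta_start[j]) > change:
                change = abs(beta[j] - beta_start[j])
        if change < tol:
            break
    return b0


def _cd_binomial(X, y, lam, alpha, beta, b0, max_outer=50, tol=1e-7, max_inner=200):
    """One elastic-net binomial fit; see :func:`_cd_kernel`."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    b0 = _cd_kernel(X, y, float(lam), float(alpha), beta, float(b0),
                    int(max_outer), float(tol), int(max_inner))
    return beta, float(b0)


def lambda_path(X, y, mixing: float, n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from lambda_max (all coefficients zero) down *decades*."""
    n = X.shape[0]
    ybar = y.mean()
    grad = X.T @ (y - ybar) / n
    lam_max = np.max(np.abs(grad)) / max(mixing, 1e-3)
    lam_max = max(lam_max, 1e-10)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def _fit_path(X, y, lambdas, mixing, tol=1e-7):
    """Warm-started coefficient path; returns arrays (len(lambdas), p) and intercepts."""
    n, p = X.shape
    beta = np.zeros(p)
    b0 = float(np.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9)))
    coefs = np.empty((len(lambdas), p))
    intercepts = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        beta, b0 = _cd_binomial(X, y, lam, mixing, beta, b0, tol=tol)
        coefs[i] = beta
        intercepts[i] = b0
    return coefs, intercepts


def _binomial_deviance(y, proba) -> float:
    proba = np.clip(proba, 1e-9, 1 - 1e-9)
    return float(-2.0 * np.sum(y * np.log(proba) + (1 - y) * np.log(1 - proba)))


def _stratified_folds(y, n_folds, rng) -> np.ndarray:
    """Fold id per observation, classes balanced across folds."""
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def fit_penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    mixing: float = 0.3,
    n_folds: int = 10,
    seed: int | np.random.Generator = 0,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    tol: float = 1e-7,
) -> GlmFit:
    """Elastic-net binomial GLM with lambda chosen by cross-validated deviance.

    Folds are stratified by label; when a class has fewer members than
    *n_folds* the fold count is reduced with a warning. Deterministic under
    *seed*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels are single-class")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lambdas is None:
        lambdas = lambda_path(X, y, mixing, n_lambda=n_lambda)
    min_class = int(min((y == c).sum() for c in classes))
    folds = n_folds
    if min_class < n_folds:
        folds = max(2, min_class)
        logger.warning("reducing CV folds from %d to %d (smallest class has %d samples)",
                       n_folds, folds, min_class)
    fold_id = _stratified_folds(y, folds, rng)
    deviance = np.zeros(len(lambdas))
    for k in range(folds):
        train, test = fold_id != k, fold_id == k
        if len(np.unique(y[train])) < 2:
            continue
        coefs, intercepts = _fit_path(X[train], y[train], lambdas, mixing, tol=tol)
        for i in range(len(lambdas)):
            proba = _sigmoid(X[test] @ coefs[i] + intercepts[i])
            deviance[i] += _binomial_deviance(y[test], proba)
    best = int(np.argmin(deviance))
    coefs, intercepts = _fit_path(X, y, lambdas, mixing, tol=tol)
    return GlmFit(coef=coefs[best], intercept=float(intercepts[best]),
                  lambda_=float(lambdas[best]), mixing=mixing,
                  cv_lambdas=lambdas, cv_deviance=deviance)


# ---------------------------------------------------------------------------
# evaluation


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability of correct pair ordering (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class BootstrapResult:
    mean_auc: float
    aucs: list[float]
    votes: dict                      # sample -> list of 0/1 test-set predictions
    coefs: np.ndarray                # (n_effective_rounds, p) standardized scale
    lambdas: list[float]
    feature_names: list[str]
    n_rounds: int
    n_excluded_rounds: int = 0
    train_indices: list = field(default_factory=list)


def _stratified_split(y, train_frac, rng):
    train_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
    train = np.sort(np.concatenate(train_idx))
    mask = np.zeros(len(y), dtype=bool)
    mask[train] = True
    return mask


def bootstrap_evaluate(
    table: FeatureTable,
    n_rounds: int = 100,
    train_frac: float = 0.70,
    seed: int = 0,
    mixing: float = 0.3,
    n_folds: int = 10,
    n_lambda: int = 100,
    stratified: bool = True,
    threshold: float = 0.5,
) -> BootstrapResult:
    """Repeated stratified 70/30 resplits with per-round refitting.

    Each round standardizes on its training samples, fits the penalized GLM
    with cross-validated lambda, scores the held-out samples, and records
    the round AUC plus hard class predictions at *threshold*. Rounds whose
    test set is single-class have no AUC and are excluded from the mean.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    ss = np.random.SeedSequence(seed)
    round_seeds = ss.spawn(n_rounds)
    votes: dict = {s: [] for s in table.samples}
    aucs, all_aucs, coefs, lambdas, train_record = [], [], [], [], []
    n_excluded = 0
    for r in range(n_rounds):
        rng = np.random.default_rng(round_seeds[r])
        if stratified:
            train_mask = _stratified_split(table.y, train_frac, rng)
        else:
            idx = rng.permutation(len(table.y))
            n_train = int(round(train_frac * len(table.y)))
            train_mask = np.zeros(len(table.y), dtype=bool)
            train_mask[idx[:n_train]] = True
        Xtr_raw, ytr = table.X_raw[train_mask], table.y[train_mask]
        Xte_raw, yte = table.X_raw[~train_mask], table.y[~train_mask]
        Xtr, params = standardize(Xtr_raw)
        Xte, _ = standardize(Xte_raw, params)
        fit = fit_penalized_logistic(Xtr, ytr, mixing=mixing, n_folds=n_folds,
                                     seed=rng, n_lambda=n_lambda)
        proba = fit.predict_proba(Xte)
        test_samples = table.samples[~train_mask]
        for s, p in zip(test_samples, proba):
            votes[s].append(int(p > threshold))
        coefs.append(fit.coef)
        lambdas.append(fit.lambda_)
        train_record.append(np.flatnonzero(train_mask))
        if len(np.unique(yte)) < 2:
            n_excluded += 1
            all_aucs.append(float("nan"))
            logger.info("round %d: single-class test set, AUC excluded", r)
            continue
        auc = roc_auc(proba, yte)
        aucs.append(auc)
        all_aucs.append(auc)
    mean_auc = float(np.mean(aucs)) if aucs else float("nan")
    return BootstrapResult(mean_auc=mean_auc, aucs=all_aucs, votes=votes,
                           coefs=np.array(coefs), lambdas=lambdas,
                           feature_names=list(table.feature_names),
                           n_rounds=n_rounds, n_excluded_rounds=n_excluded,
                           train_indices=train_record)


def majority_vote(
    votes: dict,
    fallback: GlmFit | None = None,
    table: FeatureTable | None = None,
) -> tuple[dict, dict]:
    """Final class per sample: 1 iff strictly more than half the recorded
    test-set predictions are 1 (a 50/50 tie is a non-responder call).

    Samples with no recorded prediction fall back to a model refit on all
    data (flagged); without a fallback they raise.
    """
    classes, flags = {}, {}
    for sample, preds in votes.items():
        if preds:
            classes[sample] = int(np.mean(preds) > 0.5)
            flags[sample] = False
        else:
            if fallback is None or table is None:
                raise ValueError(f"sample {sample!r} was never in a test set and "
                                 "no fallback model was provided")
            i = int(np.flatnonzero(table.samples == sample)[0])
            proba = fallback.predict_proba(table.X_standardized[i: i + 1])[0]
            classes[sample] = int(proba > 0.5)
            flags[sample] = True
            logger.info("sample %s never tested; class from full-data refit", sample)
    return classes, flags


def confusion_stats(pred, truth) -> dict:
    """Accuracy, sensitivity, specificity, precision and Cohen's kappa.

    Positive class is 1 (responder). Undefined ratios (zero denominators)
    are reported as NaN.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else float("nan")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    p_yes = ((tp + fp) / n) * ((tp + fn) / n) if n else float("nan")
    p_no = ((tn + fn) / n) * ((tn + fp) / n) if n else float("nan")
    p_e = p_yes + p_no
    kappa = (acc - p_e) / (1 - p_e) if n and p_e < 1 else (1.0 if acc == 1 else 0.0)
    return {
        "accuracy": acc, "sensitivity": sens, "specificity": spec,
        "precision": prec, "kappa": kappa,
        "table": {"TP": tp, "FP": fp, "FN": fn, "TN": tn},
    }


def feature_weightage(coefs: np.ndarray, sds: np.ndarray | None = None) -> np.ndarray:
    """Per-feature mean absolute standardized coefficient across rounds.

    *coefs* has one row per round. When fits were on raw-scale features,
    pass the per-feature *sds* used in each round (or one vector) so the
    coefficients are scaled to the standardized scale before averaging;
    coefficients from standardized fits need no scaling.
    """
    coefs = np.atleast_2d(np.asarray(coefs, dtype=float))
    if sds is not None:
        coefs = coefs * np.asarray(sds, dtype=float)
    return np.abs(coefs).mean(axis=0)
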