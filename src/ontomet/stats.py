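"""Statistical layer: correlation, PERMANOVA, dispersion, IndVal, elastic net.

Every permutation-based procedure here uses the add-one convention

    p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)

so that p can never be zero and its floor at 999 permutations is exactly
0.001.  All randomness flows through a caller-supplied seed, making every
result bit-reproducible for a given (seed, n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNet, LogisticRegression, enet_path

__all__ = [
    "CorrelationResult",
    "PermanovaResult",
    "DispersionResult",
    "IndicatorResult",
    "EnetResult",
    "StatsError",
    "spearman",
    "permanova",
    "dispersion_test",
    "indval",
    "elastic_net_select",
    "zscale_coefficients",
]


class StatsError(Exception):
    pass


# ---------------------------------------------------------------------------
# Spearman


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int


def spearman(x: Sequence[float | None], y: Sequence[float | None]) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of nulls.

    Equivalent to the Pearson correlation of average-ranked values (ties
    receive average ranks).  Requires at least 3 complete pairs and
    nondegenerate ranks.
    """
    xs, ys = [], []
    for a, b in zip(x, y, strict=True):
        if a is None or b is None or not np.isfinite(a) or not np.isfinite(b):
            continue
        xs.append(float(a))
        ys.append(float(b))
    if len(xs) < 3:
        raise StatsError(f"need >= 3 complete pairs, have {len(xs)}")
    xa, ya = np.asarray(xs), np.asarray(ys)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise StatsError("zero rank variance: correlation undefined")
    rho = float(sps.spearmanr(xa, ya).statistic)
    return CorrelationResult(rho=rho, n=len(xs))


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int


def _group_arrays(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    labels = sorted(set(groups))
    codes = np.asarray([labels.index(g) for g in groups])
    return codes, labels


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """(pseudo-F, R2) from a squared Euclidean distance matrix and labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.where(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    return f, ss_among / ss_total


def _check_groups(codes: np.ndarray, k: int) -> None:
    if k < 2:
        raise StatsError("need at least 2 groups")
    sizes = np.bincount(codes, minlength=k)
    if (sizes < 2).any():
        raise StatsError("every group needs at least 2 samples")


def permanova(
    X: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with Euclidean distances.

    pseudo-F = ((SS_total - SS_within)/(k-1)) / (SS_within/(n-k)) where the
    sums of squares are computed from pairwise squared distances; in one
    dimension this is exactly the classical one-way ANOVA F.  Significance
    by permutation of group labels.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, labels = _group_arrays(groups)
    k = len(labels)
    _check_groups(codes, k)
    n = X.shape[0]
    sq = (X[:, None, :] - X[None, :, :]) ** 2
    d2 = sq.sum(axis=2)
    if not d2[np.triu_indices(n, 1)].any():
        raise StatsError("all rows identical: zero total variance")

    f_obs, r2 = _permanova_stats(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(codes), k)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=p, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# dispersion (betadisper analogue)


@dataclass(frozen=True)
class DispersionResult:
    F: float
    p: float
    group_mean_dists: Mapping[str, float]
    n_perm: int
    seed: int


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(k):
        v = values[codes == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def dispersion_test(
    X: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Each sample's Euclidean distance to its own group centroid is computed;
    the one-way ANOVA F of those distances is the statistic, with
    significance from permuting group labels over the distances (the
    distances are held fixed, as in the classical procedure).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, labels = _group_arrays(groups)
    k = len(labels)
    _check_groups(codes, k)

    dists = np.empty(len(codes))
    for g in range(k):
        idx = codes == g
        centroid = X[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(X[idx] - centroid, axis=1)

    f_obs = _anova_f(dists, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _anova_f(dists, rng.permutation(codes), k) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    means = {lab: float(dists[codes == g].mean()) for g, lab in enumerate(labels)}
    return DispersionResult(F=float(f_obs), p=p, group_mean_dists=means, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# IndVal.g


@dataclass
class IndicatorResult:
    """Per-feature indicator statistics.

    ``table`` has one row per feature with columns ``feature``, ``A``
    (group-size-corrected specificity), ``B`` (fidelity), ``stat``
    (sqrt(A*B)), ``best_group`` and ``p``.  All-zero features carry no
    information and are excluded (``absent`` lists them).
    """

    table: pd.DataFrame
    absent: list[str]
    n_perm: int
    seed: int


def _indval_max(M: np.ndarray, codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature best (stat, group index) under IndVal.g."""
    means = np.stack([M[codes == g].mean(axis=0) for g in range(k)])  # k x p
    occ = np.stack([(M[codes == g] > 0).mean(axis=0) for g in range(k)])
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    stat = np.sqrt(A * occ)
    best = stat.argmax(axis=0)
    return stat[best, np.arange(M.shape[1])], best


def indval(
    M: np.ndarray,
    groups: Sequence[str],
    features: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> IndicatorResult:
    """Group-size-corrected indicator value analysis (IndVal.g).

    For feature f and group g, specificity A = mean(f in g) / sum over
    groups of mean(f in group) and fidelity B = fraction of g's samples
    where f is present; the indicator statistic is sqrt(A*B), attaining 1
    only for a feature present in every sample of one group and absent
    elsewhere.  p-values come from permuting sample labels and comparing
    each feature's best-group statistic to its permuted distribution.
    Single groups only (no site-group combinations).
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise StatsError("abundances must be nonnegative")
    codes, labels = _group_arrays(groups)
    k = len(labels)
    if k < 2:
        raise StatsError("need at least 2 groups")
    p_feat = M.shape[1]
    if features is None:
        features = [f"f{j}" for j in range(p_feat)]
    features = list(features)

    present = M.sum(axis=0) > 0
    absent = [f for f, keep in zip(features, present) if not keep]
    Mk = M[:, present]
    kept = [f for f, keepf in zip(features, present) if keepf]

    stat_obs, best = _indval_max(Mk, codes, k)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(kept))
    for _ in range(n_perm):
        stat_perm, _ = _indval_max(Mk, rng.permutation(codes), k)
        hits += stat_perm >= stat_obs
    pvals = (1 + hits) / (1 + n_perm)

    means = np.stack([Mk[codes == g].mean(axis=0) for g in range(k)])
    occ = np.stack([(Mk[codes == g] > 0).mean(axis=0) for g in range(k)])
    denom = means.sum(axis=0)
    cols = np.arange(len(kept))
    A = means[best, cols] / denom
    B = occ[best, cols]
    table = pd.DataFrame(
        {
            "feature": kept,
            "A": A,
            "B": B,
            "stat": stat_obs,
            "best_group": [labels[b] for b in best],
            "p": pvals,
        }
    )
    return IndicatorResult(table=table, absent=absent, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# elastic net with CV and the 1-SE rule


@dataclass
class EnetResult:
    family: str
    alpha: float
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    coefficients: pd.Series  # original scale, at lambda_1se
    intercept: float
    selected: list[str]
    seed: int
    n_folds: int


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, family: str, alpha: float, n_lambda: int) -> np.ndarray:
    n = len(y)
    if family == "gaussian":
        grad = Xs.T @ (y - y.mean())
    else:
        grad = Xs.T @ (y - y.mean())  # null-model gradient, p_hat constant
    lam_max = np.abs(grad).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    # shorter path for binomial: tiny penalties are ill-conditioned for
    # near-separable small-n fits and never win the 1-SE rule anyway
    ratio = 1e-3 if family == "gaussian" else 1e-2
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_path_gaussian(
    Xs: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray
) -> np.ndarray:
    # glmnet objective (1/2n)||y - b0 - Xb||^2 + lam*(a|b|_1 + (1-a)/2 |b|_2^2)
    # matches sklearn's ElasticNet(alpha=lam, l1_ratio=a) exactly.
    _, coefs, _ = enet_path(Xs, y - y.mean(), l1_ratio=alpha, alphas=lambdas)
    return coefs.T  # n_lambda x p


def _fit_path_binomial(
    Xs: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    coefs = np.zeros((len(lambdas), Xs.shape[1]))
    icepts = np.zeros(len(lambdas))
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=1.0,
        max_iter=2000,
        tol=1e-6,
        warm_start=True,
    )
    for i, lam in enumerate(lambdas):
        clf.C = 1.0 / (n * lam)
        clf.fit(Xs, y)
        coefs[i] = clf.coef_[0]
        icepts[i] = clf.intercept_[0]
    return coefs, icepts


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # mean deviance, 2 * negative log-likelihood / n
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(-2.0 * ll.mean())


def _cv_folds(n: int, n_folds: int, seed: int, y: np.ndarray | None) -> list[np.ndarray]:
    """Seeded fold assignment; stratified on y when given (binomial)."""
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if y is None:
        order = rng.permutation(n)
        assign[order] = np.arange(n) % n_folds
    else:
        for cls in np.unique(y):
            idx = np.where(y == cls)[0]
            order = rng.permutation(idx)
            assign[order] = np.arange(len(idx)) % n_folds
    return [np.where(assign == f)[0] for f in range(n_folds)]


def elastic_net_select(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str] | None = None,
    family: str = "gaussian",
    alpha: float = 1.0,
    n_folds: int = 10,
    rule: str = "lambda_1se",
    n_lambda: int = 100,
    seed: int = 0,
) -> EnetResult:
    """Cross-validated elastic-net feature selection, glmnet style.

    Minimizes (1/2n) deviance + lambda * (alpha*|b|_1 + (1-alpha)/2*|b|_2^2)
    along a decreasing lambda path, with K-fold CV (seeded assignment,
    stratified for binomial) scoring mean squared error (gaussian) or mean
    binomial deviance.  ``lambda_1se`` is the largest lambda whose CV error
    is within one standard error of the minimum — the parsimonious default.
    Features are standardized internally; reported coefficients are on the
    original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if features is None:
        features = [f"x{j}" for j in range(p)]
    features = list(features)
    if family not in ("gaussian", "binomial"):
        raise StatsError(f"unknown family: {family}")
    if not 0 < alpha <= 1:
        raise StatsError("alpha must be in (0, 1]")
    if n_folds > n:
        raise StatsError("more folds than samples")
    if family == "binomial":
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all() or len(uniq) != 2:
            raise StatsError("binomial response must be binary 0/1")

    Xs, x_mean, x_sd = _standardize(X)

    # degenerate gaussian response: the null model
    if family == "gaussian" and np.ptp(y) == 0:
        lam = np.array([1.0])
        zero = np.zeros(1)
        return EnetResult(
            family=family, alpha=alpha, lambda_path=lam, cv_mean=zero, cv_se=zero,
            lambda_min=1.0, lambda_1se=1.0,
            coefficients=pd.Series(np.zeros(p), index=features),
            intercept=float(y.mean()), selected=[], seed=seed, n_folds=n_folds,
        )

    lambdas = _lambda_grid(Xs, y, family, alpha, n_lambda)
    folds = _cv_folds(n, n_folds, seed, y if family == "binomial" else None)

    errs = np.zeros((n_folds, len(lambdas)))
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        Xt, Xv = Xs[train], Xs[test]
        yt, yv = y[train], y[test]
        if family == "gaussian":
            coefs = _fit_path_gaussian(Xt, yt, alpha, lambdas)
            pred = Xv @ coefs.T + yt.mean()
            errs[f] = ((yv[:, None] - pred) ** 2).mean(axis=0)
        else:
            coefs, icepts = _fit_path_binomial(Xt, yt, alpha, lambdas)
            eta = Xv @ coefs.T + icepts
            errs[f] = [
                _binomial_deviance(yv, eta[:, i]) for i in range(len(lambdas))
            ]
    cv_mean = errs.mean(axis=0)
    cv_se = errs.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(cv_mean.argmin())
    lambda_min = float(lambdas[i_min])
    threshold = cv_mean[i_min] + cv_se[i_min]
    ok = np.where(cv_mean <= threshold)[0]
    i_1se = int(ok[0])  # path is decreasing, first index = largest lambda
    lambda_1se = float(lambdas[i_1se])

    lam_star = lambda_1se if rule == "lambda_1se" else lambda_min
    if family == "gaussian":
        model = ElasticNet(alpha=lam_star, l1_ratio=alpha, max_iter=50_000, tol=1e-8)
        model.fit(Xs, y - y.mean())
        beta_std = model.coef_
        beta = beta_std / x_sd
        intercept = float(y.mean() - beta @ x_mean)
    else:
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha,
            C=1.0 / (n * lam_star), max_iter=5000, tol=1e-7,
        )
        clf.fit(Xs, y)
        beta_std = clf.coef_[0]
        beta = beta_std / x_sd
        intercept = float(clf.intercept_[0] - beta @ x_mean)

    coefficients = pd.Series(beta, index=features)
    selected = [f for f, b in coefficients.items() if b != 0.0]
    return EnetResult(
        family=family, alpha=alpha, lambda_path=lambdas,
        cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=lambda_min, lambda_1se=lambda_1se,
        coefficients=coefficients, intercept=intercept,
        selected=selected, seed=seed, n_folds=n_folds,
    )


def zscale_coefficients(result: EnetResult, ddof: int = 1) -> pd.DataFrame:
    """Z-scale the selected coefficients of an elastic-net fit.

    z_i = (b_i - mean(b_selected)) / sd(b_selected); the default sample-sd
    convention (ddof=1) matches R's ``scale``.  The returned frame also
    carries ``abs_z_negative`` — |z| restricted to negative-coefficient
    features, the ranking used to display taxa that increase as a gradient
    (e.g. oxygen) decreases.
    """
    beta = result.coefficients[result.selected]
    if len(beta) < 2:
        raise StatsError("need at least 2 selected coefficients to z-scale")
    sd = beta.std(ddof=ddof)
    if sd == 0:
        raise StatsError("selected coefficients are all equal: zero sd")
    z = (beta - beta.mean()) / sd
    out = pd.DataFrame({"coefficient": beta, "z": z})
    out["abs_z_negative"] = np.where(out["coefficient"] < 0, np.abs(out["z"]), np.nan)
    return out
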