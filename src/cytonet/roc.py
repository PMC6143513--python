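"""Day-1 prognostic ROC analysis with ridge-penalized logistic models.

Models are logistic regressions fitted by penalized maximum likelihood with
a Gaussian prior on the slopes (ridge): the maximiser of
``loglik(beta) - (lambda/2) * ||beta_slopes||^2`` with an unpenalised
intercept, on internally standardised features. The penalty weight is
selected by corrected AIC over a log-spaced grid, with the effective degrees
of freedom tr[(X'WX + lambda*P)^-1 X'WX]. Discrimination is the
Mann-Whitney AUC of the linear predictor (in-sample), and SOFA-only vs
SOFA-plus-marker models are compared with DeLong's paired correlated-ROC
test (a seeded-bootstrap alternative is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from cytonet.errors import FitError, ValidationError

#: Default penalty grid for AICc selection (on standardised features).
LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-2, 3, 11))


@dataclass
class PenalizedLogisticFit:
    """Ridge logistic fit; coefficients live on the standardised scale."""

    predictors: tuple[str, ...]
    lam: float
    intercept: float
    coef: np.ndarray  # slopes per standardised feature
    linear_predictor: np.ndarray
    converged: bool
    df_effective: float
    loglik: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    separation_flagged: bool = False

    @property
    def aicc(self) -> float:
        n = len(self.linear_predictor)
        k = self.df_effective + 1  # + intercept
        denom = n - k - 1
        if denom <= 0:
            return np.inf
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / denom

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return self.intercept + Z @ self.coef


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def ridge_logistic(
    features,
    outcome,
    lam: float,
    predictors: tuple[str, ...] | None = None,
) -> PenalizedLogisticFit:
    """Maximise the slope-penalised Bernoulli log-likelihood.

    ``features`` is (n, p); columns are standardised internally (the penalty
    is scale-dependent). The intercept is never penalised. Deterministic:
    Newton iterations from the zero vector.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise FitError("single-class outcome: logistic fit impossible")
    if lam < 0:
        raise ValidationError("penalty weight must be non-negative")
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise FitError("constant feature column: no variation to fit")
    Z = (X - mu) / sd
    Z1 = np.column_stack([np.ones(n), Z])
    pen = np.diag([0.0] + [lam] * p)

    def negobj(b):
        eta = Z1 @ b
        return -_loglik(eta, y) + 0.5 * b @ pen @ b

    def grad(b):
        eta = Z1 @ b
        mu_hat = 1.0 / (1.0 + np.exp(-eta))
        return -(Z1.T @ (y - mu_hat)) + pen @ b

    def hess(b):
        eta = Z1 @ b
        mu_hat = 1.0 / (1.0 + np.exp(-eta))
        w = mu_hat * (1.0 - mu_hat)
        return (Z1 * w[:, None]).T @ Z1 + pen

    res = optimize.minimize(
        negobj, np.zeros(p + 1), jac=grad, hess=hess, method="trust-ncg",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    b = res.x
    converged = bool(res.success) and float(np.linalg.norm(grad(b))) < 1e-5
    separation = False
    if lam == 0 and (not converged or np.max(np.abs(b)) > 30):
        separation = True  # monotone likelihood: MLE diverges
    eta = Z1 @ b
    H = hess(b) - pen  # X'WX including intercept column
    df = float(np.trace(np.linalg.solve(H + pen, H))) - 1.0  # slopes only
    return PenalizedLogisticFit(
        predictors=tuple(predictors or (f"x{j}" for j in range(p))),
        lam=float(lam),
        intercept=float(b[0]),
        coef=b[1:],
        linear_predictor=eta,
        converged=converged,
        df_effective=df,
        loglik=_loglik(eta, y),
        feature_means=mu,
        feature_sds=sd,
        separation_flagged=separation,
    )


def select_lambda(
    features, outcome, grid: tuple[float, ...] = LAMBDA_GRID,
    predictors: tuple[str, ...] | None = None,
) -> PenalizedLogisticFit:
    """Fit at each grid penalty and keep the corrected-AIC minimiser."""
    fits = [ridge_logistic(features, outcome, lam, predictors) for lam in grid]
    return min(fits, key=lambda f: f.aicc)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # mid-ranks handle ties
    r_pos = ranks[y == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = scores[y == 1]
    neg = scores[y == 0]
    # structural components via mid-rank placements
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg])
    return v10, v01, float(v10.mean())


@dataclass
class RocComparison:
    """Paired comparison of two ROC curves on the same subjects."""

    auc_a: float
    auc_b: float
    delta: float
    p: float
    n_pos: int
    n_neg: int
    method: str = "delong"
    var_delta: float = np.nan


def compare_auc_paired(
    scores_a,
    scores_b,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocComparison:
    """Two-sided test of AUC_A = AUC_B for correlated ROC curves.

    ``delong`` uses the asymptotic normal z-test on the paired structural
    components; ``bootstrap`` resamples subjects (stratified by class) with a
    seeded generator. Identical score vectors give delta 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValidationError("paired comparison needs equal-length score/label vectors")
    auc_a_, auc_b_ = auc(a, y), auc(b, y)
    delta = auc_b_ - auc_a_
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())

    if np.array_equal(a, b):
        return RocComparison(auc_a_, auc_b_, 0.0, 1.0, n_pos, n_neg, method)

    if method == "delong":
        va10, va01, _ = _delong_components(a, y)
        vb10, vb01, _ = _delong_components(b, y)
        d10 = vb10 - va10
        d01 = vb01 - va01
        var = d10.var(ddof=1) / n_pos + d01.var(ddof=1) / n_neg
        if var <= 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            z = delta / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        return RocComparison(auc_a_, auc_b_, float(delta), p, n_pos, n_neg, "delong", float(var))

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        deltas = np.empty(n_boot)
        for i in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx_pos, n_pos), rng.choice(idx_neg, n_neg)]
            )
            deltas[i] = auc(b[take], y[take]) - auc(a[take], y[take])
        se = deltas.std(ddof=1)
        if se == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(delta) / se))
        return RocComparison(
            auc_a_, auc_b_, float(delta), p, n_pos, n_neg, "bootstrap", float(se**2)
        )

    raise ValidationError(f"unknown method {method!r}")


def roc_comparison_table(
    features: pd.DataFrame,
    outcome: pd.Series,
    base_predictor: str = "sofa",
    add_predictors: tuple[str, ...] = (),
    grid: tuple[float, ...] = LAMBDA_GRID,
) -> pd.DataFrame:
    """Tidy AUC-comparison table for one day (typically day 1).

    Rows: each single predictor's AUC; the base (SOFA-only) model; and each
    base+marker model with its paired DeLong p-value against the base model.
    Subjects with any missing involved predictor are dropped per model pair
    (base and augmented models always share the same subjects).
    """
    rows = []
    y_all = outcome.astype(float)

    def fit_on(cols: list[str], mask: pd.Series) -> tuple[PenalizedLogisticFit, np.ndarray]:
        X = features.loc[mask, cols].to_numpy(dtype=float)
        yv = y_all[mask].to_numpy()
        fit = select_lambda(X, yv, grid, predictors=tuple(cols))
        return fit, yv

    for pred in (base_predictor, *add_predictors):
        mask = features[pred].notna() & y_all.notna()
        try:
            fit, yv = fit_on([pred], mask)
            rows.append(
                {
                    "model": pred,
                    "predictors": pred,
                    "auc": auc(fit.linear_predictor, yv),
                    "comparison_vs_sofa_p": np.nan,
                    "lambda": fit.lam,
                    "n": int(mask.sum()),
                }
            )
        except (FitError, ValidationError) as exc:
            rows.append(
                {
                    "model": pred,
                    "predictors": pred,
                    "auc": np.nan,
                    "comparison_vs_sofa_p": np.nan,
                    "lambda": np.nan,
                    "n": int(mask.sum()),
                    "note": str(exc),
                }
            )

    for pred in add_predictors:
        mask = features[base_predictor].notna() & features[pred].notna() & y_all.notna()
        try:
            base_fit, yv = fit_on([base_predictor], mask)
            full_fit, _ = fit_on([base_predictor, pred], mask)
            cmp = compare_auc_paired(base_fit.linear_predictor, full_fit.linear_predictor, yv)
            rows.append(
                {
                    "model": f"{base_predictor}+{pred}",
                    "predictors": f"{base_predictor},{pred}",
                    "auc": cmp.auc_b,
                    "comparison_vs_sofa_p": cmp.p,
                    "lambda": full_fit.lam,
                    "n": int(mask.sum()),
                }
            )
        except (FitError, ValidationError) as exc:
            rows.append(
                {
                    "model": f"{base_predictor}+{pred}",
                    "predictors": f"{base_predictor},{pred}",
                    "auc": np.nan,
                    "comparison_vs_sofa_p": np.nan,
                    "lambda": np.nan,
                    "n": int(mask.sum()),
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)
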