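"""Multinomial association of trajectory groups with baseline covariates.

The modal trajectory assignment (group 1, the least active, as reference)
is regressed on covariates — sex (reference girls), school type (reference
control), and composite-score tertiles (reference low) — by multinomial
logistic regression.  Exponentiated coefficients are relative risk ratios
(RRR).  Because children are clustered in schools and classes, a
cluster-robust sandwich covariance is used for inference, with the usual
M/(M-1) small-sample factor for M clusters.  With a single categorical
predictor the fitted RRRs coincide with the directly calculable
contingency-table cross-ratios, a property used as a correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationFit",
    "SeparationError",
    "fit_multinomial",
    "cluster_robust_vcov",
    "rrr_table",
    "overall_test",
]


class SeparationError(RuntimeError):
    """Raised when (quasi-)complete separation prevents finite estimates."""


@dataclass
class AssociationFit:
    """A fitted multinomial logit with bookkeeping for robust inference."""

    result: object                   # statsmodels MNLogitResults
    outcome_levels: np.ndarray       # sorted group labels; first is reference
    exog_names: list
    endog: np.ndarray
    exog: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    @property
    def params(self) -> pd.DataFrame:
        """(n_exog, n_levels-1) coefficients; columns labelled by outcome."""
        p = np.asarray(self.result.params)
        return pd.DataFrame(
            p, index=self.exog_names,
            columns=[f"group_{g}" for g in self.outcome_levels[1:]],
        )

    @property
    def df_model(self) -> int:
        return int(np.asarray(self.result.params).size)


def _build_design(design: pd.DataFrame) -> tuple[np.ndarray, list]:
    X = design.copy()
    X.insert(0, "const", 1.0)
    return X.to_numpy(dtype=float), list(X.columns)


def fit_multinomial(outcome, design: pd.DataFrame, maxiter: int = 200) -> AssociationFit:
    """Maximum-likelihood multinomial logit of group on covariates.

    ``outcome`` holds group labels (the smallest label is the reference);
    ``design`` holds numeric/indicator covariates (an intercept is added).
    Perfect separation or rank deficiency raises.
    """
    y = np.asarray(outcome)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("need at least 2 outcome categories")
    X, names = _build_design(design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    codes = np.searchsorted(levels, y)
    model = sm.MNLogit(codes, X)
    try:
        res = model.fit(method="newton", maxiter=maxiter, disp=False)
    except np.linalg.LinAlgError:
        # singular information along the separation direction; refit with a
        # gradient method so the diverging coefficient can be identified
        res = model.fit(method="bfgs", maxiter=maxiter, disp=False)
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 20:
        j, g = np.unravel_index(np.nanargmax(np.abs(params)), params.shape)
        raise SeparationError(
            f"separation detected on covariate {names[j]!r} "
            f"(outcome level {levels[g + 1]})"
        )
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("multinomial fit did not converge")
    return AssociationFit(result=res, outcome_levels=levels, exog_names=names,
                          endog=codes, exog=X)


def _score_obs(fit: AssociationFit) -> np.ndarray:
    """Per-observation score of the multinomial log-likelihood, flattened
    in the same (Fortran) order as the packed parameter vector."""
    res = fit.result
    X = fit.exog
    n, K = X.shape
    J = len(fit.outcome_levels)
    probs = np.asarray(res.predict())          # (n, J)
    indic = np.zeros((n, J))
    indic[np.arange(n), fit.endog] = 1.0
    resid = (indic - probs)[:, 1:]             # reference level dropped
    # score for coefficient (k, j): x_k * (1{y=j} - p_j)
    s = X[:, :, None] * resid[:, None, :]      # (n, K, J-1)
    return s.reshape(n, K * (J - 1), order="F")


def cluster_robust_vcov(fit: AssociationFit, cluster_ids) -> np.ndarray:
    """Cluster-robust sandwich covariance A^-1 (sum_c s_c s_c') A^-1.

    ``A`` is the observed information, ``s_c`` the within-cluster summed
    scores; the meat carries the M/(M-1) small-sample factor for M
    clusters.  Each child its own cluster recovers the heteroskedasticity-
    robust sandwich (times n/(n-1)).
    """
    clusters = np.asarray(cluster_ids)
    if len(clusters) != len(fit.endog):
        raise ValueError("cluster ids must match the number of observations")
    uniq = np.unique(clusters)
    M = len(uniq)
    if M < 2:
        raise ValueError("need at least 2 clusters")
    s = _score_obs(fit)
    params_flat = np.asarray(fit.result.params).ravel(order="F")
    H = fit.result.model.hessian(params_flat)
    A_inv = np.linalg.inv(-H)
    S = np.zeros((M, s.shape[1]))
    idx = np.searchsorted(uniq, clusters)
    np.add.at(S, idx, s)
    meat = (S.T @ S) * M / (M - 1)
    V = A_inv @ meat @ A_inv
    return 0.5 * (V + V.T)


def _vcov_as_table(fit: AssociationFit, vcov: np.ndarray) -> np.ndarray:
    """Standard errors reshaped to match ``fit.params`` (K, J-1)."""
    K = len(fit.exog_names)
    Jm1 = len(fit.outcome_levels) - 1
    se = np.sqrt(np.diag(vcov))
    return se.reshape(K, Jm1, order="F")


def rrr_table(fit: AssociationFit, vcov: np.ndarray | None = None,
              level: float = 0.95) -> pd.DataFrame:
    """Relative risk ratios with Wald confidence intervals and stars.

    RRR = exp(b), CI = exp(b +/- z * se).  With no covariance supplied the
    model-based one is used.  A zero standard error yields a degenerate
    (zero-width) interval, flagged in the ``degenerate`` column.
    """
    if vcov is None:
        vcov = np.asarray(fit.result.cov_params())
    se = _vcov_as_table(fit, vcov)
    b = np.asarray(fit.result.params)
    zq = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for g_idx, g in enumerate(fit.outcome_levels[1:]):
        for k, name in enumerate(fit.exog_names):
            bb, ss = float(b[k, g_idx]), float(se[k, g_idx])
            z = bb / ss if ss > 0 else np.inf * np.sign(bb) if bb else 0.0
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
            stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append({
                "group": g, "term": name, "coef": bb, "se": ss,
                "RRR": float(np.exp(bb)),
                "ci_low": float(np.exp(bb - zq * ss)),
                "ci_high": float(np.exp(bb + zq * ss)),
                "p": float(p), "stars": stars,
                "degenerate": ss == 0,
            })
    return pd.DataFrame(rows)


def overall_test(fit: AssociationFit, null_fit: AssociationFit) -> float:
    """Likelihood-ratio p-value of the full against a nested null model."""
    if len(fit.endog) != len(null_fit.endog) or not np.array_equal(
        fit.outcome_levels, null_fit.outcome_levels
    ):
        raise ValueError("models must be fitted on identical data")
    df = fit.df_model - null_fit.df_model
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    if df == 0:
        return 1.0
    lr = 2.0 * (fit.loglik - null_fit.loglik)
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df))
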