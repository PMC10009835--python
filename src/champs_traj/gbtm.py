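"""Censored-normal group-based trajectory model (GBTM).

A finite mixture in which each latent group ``j`` follows its own polynomial
mean curve over age, and the weekly-participation outcome ``y`` is a normal
variable censored below at ``y_min`` (0 sessions) and above at ``y_max``
(8, standing for "more than seven").  Group membership probabilities are
parameterised by multinomial logits with group 1 as reference.  Estimation
is maximum likelihood via a generalised EM algorithm: the E-step computes
posterior membership probabilities per child, the M-step refits the
posterior-weighted censored-normal (Tobit-type) regression with a
quasi-Newton inner optimiser and updates the membership probabilities in
closed form.

The panel consumed by the model is long format with one row per
child-month: columns ``child_id``, ``age`` (years) and ``y`` (average
weekly sessions in [y_min, y_max]; NaN rows are dropped, which is valid
under the missing-completely-at-random assumption).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp, ndtr
from scipy.optimize import minimize

__all__ = [
    "TrajectorySpec",
    "GbtmParams",
    "GbtmFit",
    "FitError",
    "cnorm_log_density",
    "cnorm_expected_observed",
    "child_group_loglik",
    "mixture_loglik",
    "posterior_probs",
    "fit_gbtm",
    "predict_trajectory",
    "count_parameters",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Raised when no EM start converges; carries the best partial fit."""

    def __init__(self, message: str, best_fit: "GbtmFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class TrajectorySpec:
    """Model definition: number of groups, polynomial order, censoring limits.

    ``age_center``/``age_scale`` define the affine transform
    ``t = (age - age_center) / age_scale`` applied before building the
    polynomial design; they are filled in from the data at fit time so the
    observed age range maps onto [-1, 1] (good conditioning for cubics).
    """

    n_groups: int
    order: int = 3
    y_min: float = 0.0
    y_max: float = 8.0
    age_center: float | None = None
    age_scale: float | None = None

    def __post_init__(self):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not (0 <= self.order <= 3):
            raise ValueError("polynomial order must be in 0..3")
        if not self.y_min < self.y_max:
            raise ValueError("y_min must be < y_max")
        if self.age_scale is not None and self.age_scale <= 0:
            raise ValueError("age_scale must be positive")

    def with_age_transform(self, ages: np.ndarray) -> "TrajectorySpec":
        """Return a spec whose age transform maps observed ages to [-1, 1]."""
        lo, hi = float(np.min(ages)), float(np.max(ages))
        center = 0.5 * (lo + hi)
        scale = 0.5 * (hi - lo) if hi > lo else 1.0
        return replace(self, age_center=center, age_scale=scale)

    def scale_age(self, age) -> np.ndarray:
        if self.age_center is None or self.age_scale is None:
            raise ValueError("age transform not set; call with_age_transform first")
        return (np.asarray(age, dtype=float) - self.age_center) / self.age_scale


@dataclass
class GbtmParams:
    """Parameters: per-group polynomial coefficients on scaled age, one
    shared residual SD, and G-1 membership logits (group 1 reference)."""

    beta: np.ndarray  # (G, order+1)
    sigma: float
    theta: np.ndarray  # (G-1,)

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.theta.shape != (self.beta.shape[0] - 1,):
            raise ValueError("theta must have length n_groups - 1")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("membership logits must be finite")

    @property
    def n_groups(self) -> int:
        return self.beta.shape[0]

    @property
    def pi(self) -> np.ndarray:
        """Membership probabilities softmax(0, theta_2, ..., theta_G)."""
        logits = np.concatenate([[0.0], self.theta])
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum()

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "sigma": float(self.sigma),
            "theta": self.theta.tolist(),
            "pi": self.pi.tolist(),
        }


@dataclass
class GbtmFit:
    """A fitted trajectory model: parameters, log-likelihood, posteriors."""

    spec: TrajectorySpec
    params: GbtmParams
    loglik: float
    child_ids: np.ndarray
    posterior: np.ndarray  # (n_children, G)
    assignment: np.ndarray  # modal group per child, 1-based labels
    converged: bool
    n_iter: int
    loglik_history: list = field(default_factory=list)
    n_obs: int = 0
    n_children: int = 0
    seed: int | None = None

    @property
    def pi_hat(self) -> np.ndarray:
        return self.params.pi

    def assignment_series(self) -> pd.Series:
        return pd.Series(self.assignment, index=self.child_ids, name="group")

    def to_json(self, path=None) -> str:
        payload = {
            "spec": {
                "n_groups": self.spec.n_groups,
                "order": self.spec.order,
                "y_min": self.spec.y_min,
                "y_max": self.spec.y_max,
                "age_center": self.spec.age_center,
                "age_scale": self.spec.age_scale,
            },
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "n_children": self.n_children,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# censored-normal building blocks
# ---------------------------------------------------------------------------

def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI


def cnorm_log_density(y, mu, sigma, y_min=0.0, y_max=8.0):
    """Log density/mass of the censored normal observation model.

    Observations at the limits carry the tail mass:
    ``log Phi((y_min - mu)/sigma)`` at the floor,
    ``log(1 - Phi((y_max - mu)/sigma))`` at the ceiling; interior points the
    normal log density.  Computed through ``log_ndtr`` so it stays accurate
    far into the tails (|z| of 40 and beyond).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < y_min) or np.any(y > y_max):
        raise ValueError("y outside censoring limits")
    y_b, mu_b = np.broadcast_arrays(y, mu)
    z = (y_b - mu_b) / sigma
    interior = _norm_logpdf(z) - np.log(sigma)
    left = log_ndtr((y_min - mu_b) / sigma)
    right = log_ndtr(-(y_max - mu_b) / sigma)  # log survival
    out = np.where(y_b <= y_min, left, np.where(y_b >= y_max, right, interior))
    return out if out.shape else float(out)


def cnorm_expected_observed(mu, sigma, y_min=0.0, y_max=8.0):
    """Expected value of the observed (clipped-to-limits) outcome.

    E[y] = y_min Phi(a) + y_max (1 - Phi(b)) + mu (Phi(b) - Phi(a))
           - sigma (phi(b) - phi(a)),   a=(y_min-mu)/sigma, b=(y_max-mu)/sigma.
    ``sigma = 0`` degenerates to clip(mu, y_min, y_max).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    mu = np.asarray(mu, dtype=float)
    if sigma == 0:
        out = np.clip(mu, y_min, y_max)
        return out if out.shape else float(out)
    a = (y_min - mu) / sigma
    b = (y_max - mu) / sigma
    phi_a = np.exp(_norm_logpdf(a))
    phi_b = np.exp(_norm_logpdf(b))
    Fa, Fb = ndtr(a), ndtr(b)
    out = y_min * Fa + y_max * (1.0 - Fb) + mu * (Fb - Fa) - sigma * (phi_b - phi_a)
    out = np.clip(out, y_min, y_max)
    return out if out.shape else float(out)


def _design_matrix(t: np.ndarray, order: int) -> np.ndarray:
    """Polynomial design [1, t, t^2, ...] on scaled age."""
    return np.vander(np.asarray(t, dtype=float), order + 1, increasing=True)


def count_parameters(spec: TrajectorySpec) -> int:
    """Free parameters: G(order+1) coefficients + (G-1) logits + one sigma."""
    return spec.n_groups * (spec.order + 1) + (spec.n_groups - 1) + 1


# ---------------------------------------------------------------------------
# panel plumbing
# ---------------------------------------------------------------------------

@dataclass
class _PanelData:
    """Sorted, validated arrays extracted from a long panel."""

    child_ids: np.ndarray      # unique ids, sorted
    idx: np.ndarray            # child index per observation
    starts: np.ndarray         # reduceat boundaries into obs arrays
    y: np.ndarray
    X: np.ndarray              # design on scaled age
    left_mask: np.ndarray
    right_mask: np.ndarray
    spec: TrajectorySpec

    @property
    def n_children(self):
        return len(self.child_ids)

    @property
    def n_obs(self):
        return len(self.y)


def _prepare_panel(panel: pd.DataFrame, spec: TrajectorySpec) -> _PanelData:
    if len(panel) == 0:
        raise ValueError("empty panel")
    df = panel.loc[:, ["child_id", "age", "y"]].dropna(subset=["y"]).copy()
    if len(df) == 0:
        raise ValueError("panel has no non-missing observations")
    if (df["y"] < spec.y_min).any() or (df["y"] > spec.y_max).any():
        raise ValueError("observed y outside censoring limits")
    if spec.age_center is None:
        spec = spec.with_age_transform(df["age"].to_numpy())
    df = df.sort_values("child_id", kind="mergesort")
    codes, uniques = pd.factorize(df["child_id"].to_numpy(), sort=False)
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    y = df["y"].to_numpy(dtype=float)
    t = spec.scale_age(df["age"].to_numpy())
    X = _design_matrix(t, spec.order)
    return _PanelData(
        child_ids=np.asarray(uniques),
        idx=codes,
        starts=starts,
        y=y,
        X=X,
        left_mask=y <= spec.y_min,
        right_mask=y >= spec.y_max,
        spec=spec,
    )


def _obs_log_density(data: _PanelData, beta: np.ndarray, sigma: float):
    """(n_obs, G) censored-normal log density of every observation under
    every group's mean curve."""
    spec = data.spec
    MU = data.X @ beta.T  # (n_obs, G)
    z = (data.y[:, None] - MU) / sigma
    interior = _norm_logpdf(z) - np.log(sigma)
    left = log_ndtr((spec.y_min - MU) / sigma)
    right = log_ndtr(-(spec.y_max - MU) / sigma)
    ld = np.where(
        data.left_mask[:, None], left, np.where(data.right_mask[:, None], right, interior)
    )
    return ld, MU


def _child_log_lik_matrix(data: _PanelData, beta: np.ndarray, sigma: float) -> np.ndarray:
    """(n_children, G) log L_ij: per-child sum over non-missing months."""
    ld, _ = _obs_log_density(data, beta, sigma)
    return np.add.reduceat(ld, data.starts, axis=0)


def child_group_loglik(y, ages, beta_j, sigma, spec: TrajectorySpec) -> float:
    """Log-likelihood of one child's observed months under one group's curve.

    Missing (NaN) months contribute nothing (MCAR).
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = ~np.isnan(y)
    if not keep.any():
        raise ValueError("child has no non-missing observations")
    t = spec.scale_age(ages[keep])
    mu = _design_matrix(t, spec.order) @ np.asarray(beta_j, dtype=float)
    return float(
        np.sum(cnorm_log_density(y[keep], mu, sigma, spec.y_min, spec.y_max))
    )


def mixture_loglik(params: GbtmParams, panel: pd.DataFrame, spec: TrajectorySpec) -> float:
    """Total mixture log-likelihood sum_i log sum_j pi_j L_ij (log-sum-exp)."""
    data = _prepare_panel(panel, spec)
    logL = _child_log_lik_matrix(data, params.beta, params.sigma)
    return float(np.sum(logsumexp(logL + np.log(params.pi)[None, :], axis=1)))


def posterior_probs(params: GbtmParams, panel: pd.DataFrame, spec: TrajectorySpec) -> pd.DataFrame:
    """Posterior membership probabilities w_ij per child (rows sum to 1)."""
    data = _prepare_panel(panel, spec)
    logL = _child_log_lik_matrix(data, params.beta, params.sigma)
    logw = logL + np.log(params.pi)[None, :]
    w = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return pd.DataFrame(
        w, index=pd.Index(data.child_ids, name="child_id"),
        columns=[f"group_{j + 1}" for j in range(params.n_groups)],
    )


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _e_step(data: _PanelData, beta, sigma, pi):
    logL = _child_log_lik_matrix(data, beta, sigma)
    logw = logL + np.log(pi)[None, :]
    norm = logsumexp(logw, axis=1)
    w = np.exp(logw - norm[:, None])
    return float(norm.sum()), w


def _weighted_cnorm_objective(x, data: _PanelData, W_obs: np.ndarray, G: int, p: int):
    """Negative posterior-weighted Tobit log-likelihood and its gradient.

    ``x`` packs [beta.ravel(), log sigma]; W_obs is (n_obs, G) with each
    observation carrying its child's posterior weight for each group.
    """
    beta = x[: G * p].reshape(G, p)
    log_sigma = x[-1]
    sigma = np.exp(log_sigma)
    spec = data.spec
    MU = data.X @ beta.T
    y = data.y[:, None]
    z = (y - MU) / sigma

    a = (spec.y_min - MU) / sigma
    b = (spec.y_max - MU) / sigma
    log_cdf_a = log_ndtr(a)
    log_sf_b = log_ndtr(-b)

    interior = _norm_logpdf(z) - log_sigma
    ld = np.where(
        data.left_mask[:, None], log_cdf_a,
        np.where(data.right_mask[:, None], log_sf_b, interior),
    )
    f = -np.sum(W_obs * ld)

    # gradients of the log density wrt mu and log sigma, by censoring status
    r = np.exp(_norm_logpdf(a) - log_cdf_a)          # phi/Phi at the floor
    s = np.exp(_norm_logpdf(b) - log_sf_b)           # phi/(1-Phi) at the ceiling
    dmu = np.where(
        data.left_mask[:, None], -r / sigma,
        np.where(data.right_mask[:, None], s / sigma, z / sigma),
    )
    dls = np.where(
        data.left_mask[:, None], -a * r,
        np.where(data.right_mask[:, None], b * s, z * z - 1.0),
    )
    gbeta = -(data.X.T @ (W_obs * dmu)).T  # (G, p)
    gls = -np.sum(W_obs * dls)
    return f, np.concatenate([gbeta.ravel(), [gls]])


def _m_step(data: _PanelData, w: np.ndarray, beta0, sigma0, maxiter=100):
    G, p = beta0.shape
    W_obs = w[data.idx]
    x0 = np.concatenate([beta0.ravel(), [np.log(sigma0)]])
    res = minimize(
        _weighted_cnorm_objective, x0,
        args=(data, W_obs, G, p), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[: G * p].reshape(G, p)
    sigma = float(np.exp(res.x[-1]))
    return beta, sigma


def _init_from_assignment(data: _PanelData, hard: np.ndarray, G: int):
    """Initial (beta, sigma) from a hard child partition via weighted OLS,
    ignoring censoring (adequate as a starting point)."""
    p = data.spec.order + 1
    beta = np.zeros((G, p))
    resid_ss, n_tot = 0.0, 0
    w_obs = hard[data.idx]
    for j in range(G):
        mask = w_obs == j
        if mask.sum() < p:
            beta[j, 0] = np.mean(data.y)
            continue
        Xj, yj = data.X[mask], data.y[mask]
        coef, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        beta[j] = coef
        r = yj - Xj @ coef
        resid_ss += float(r @ r)
        n_tot += mask.sum()
    sigma = np.sqrt(resid_ss / max(n_tot, 1)) if n_tot else 1.0
    sigma = max(sigma, 0.1)
    counts = np.bincount(hard, minlength=G).astype(float)
    pi = np.clip(counts / counts.sum(), 1e-3, None)
    pi = pi / pi.sum()
    return beta, sigma, pi


def _kmeans_partition(data: _PanelData, G: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    means = np.add.reduceat(data.y, data.starts) / np.diff(
        np.r_[data.starts, data.n_obs]
    )
    if G == 1:
        return np.zeros(data.n_children, dtype=int)
    km = KMeans(n_clusters=min(G, len(np.unique(means))), n_init=1, random_state=seed)
    labels = km.fit_predict(means[:, None])
    # order clusters by mean so the initial labelling is already sorted
    order = np.argsort([means[labels == c].mean() for c in np.unique(labels)])
    remap = {c: r for r, c in enumerate(np.unique(labels)[order])}
    # groups left empty by a degenerate partition get a pooled-mean init later
    return np.array([remap[c] for c in labels])


def _relabel_ascending(data: _PanelData, beta, sigma, pi, w):
    """Relabel groups in increasing order of the mean fitted trajectory."""
    grid_mu = data.X @ beta.T
    curve_mean = np.array([
        np.mean(cnorm_expected_observed(grid_mu[:, j], sigma,
                                        data.spec.y_min, data.spec.y_max))
        for j in range(beta.shape[0])
    ])
    order = np.argsort(curve_mean, kind="mergesort")
    return beta[order], pi[order], w[:, order]


def fit_gbtm(
    panel: pd.DataFrame,
    spec: TrajectorySpec,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GbtmFit:
    """Maximum-likelihood fit by generalised EM with multiple seeded starts.

    The first start partitions children by k-means on their mean outcome;
    remaining starts are random partitions.  The best converged start is
    returned with groups relabelled in increasing order of mean fitted
    trajectory.  The log-likelihood is non-decreasing across EM iterations.
    """
    data = _prepare_panel(panel, spec)
    spec = data.spec  # now carries the age transform
    G, p = spec.n_groups, spec.order + 1
    rng = np.random.default_rng(seed)

    best = None
    any_converged = False
    for start in range(max(n_starts, 1)):
        if start == 0:
            hard = _kmeans_partition(data, G, seed)
        else:
            hard = rng.integers(0, G, size=data.n_children)
        beta, sigma, pi = _init_from_assignment(data, hard, G)

        history = []
        prev_ll = -np.inf
        stable = 0
        converged = False
        w = None
        for it in range(max_iter):
            ll, w = _e_step(data, beta, sigma, pi)
            history.append(ll)
            if ll + 1e-8 < prev_ll:
                warnings.warn("EM log-likelihood decreased; numerical issue")
            if abs(ll - prev_ll) < tol:
                stable += 1
                if stable >= 3:
                    converged = True
                    break
            else:
                stable = 0
            prev_ll = ll
            pi = np.clip(w.mean(axis=0), 1e-12, None)
            pi = pi / pi.sum()
            beta, sigma = _m_step(data, w, beta, sigma)
        ll, w = _e_step(data, beta, sigma, pi)
        history.append(ll)

        if best is None or ll > best[0]:
            best = (ll, beta, sigma, pi, w, converged, len(history), history)
        any_converged = any_converged or converged

    ll, beta, sigma, pi, w, converged, n_iter, history = best
    beta, pi, w = _relabel_ascending(data, beta, sigma, pi, w)
    theta = np.log(pi[1:] / pi[0]) if G > 1 else np.zeros(0)
    params = GbtmParams(beta=beta, sigma=sigma, theta=theta)
    assignment = np.argmax(w, axis=1) + 1  # ties: lowest index wins (argmax)
    fit = GbtmFit(
        spec=spec,
        params=params,
        loglik=float(ll),
        child_ids=data.child_ids,
        posterior=w,
        assignment=assignment,
        converged=converged,
        n_iter=n_iter,
        loglik_history=[float(v) for v in history],
        n_obs=data.n_obs,
        n_children=data.n_children,
        seed=seed,
    )
    if not any_converged:
        raise FitError("no EM start converged within max_iter", best_fit=fit)
    return fit


# ---------------------------------------------------------------------------
# prediction with point-wise bands
# ---------------------------------------------------------------------------

def _mixture_grad(data: _PanelData, params: GbtmParams) -> np.ndarray:
    """Analytic gradient of the mixture log-likelihood wrt
    [beta.ravel(), log sigma, theta]."""
    G, p = params.beta.shape
    ll, w = _e_step(data, params.beta, params.sigma, params.pi)
    W_obs = w[data.idx]
    f, g = _weighted_cnorm_objective(
        np.concatenate([params.beta.ravel(), [np.log(params.sigma)]]),
        data, W_obs, G, p,
    )
    g_beta_sigma = -g  # objective was negated
    g_theta = np.sum(w - params.pi[None, :], axis=0)[1:]
    return np.concatenate([g_beta_sigma, g_theta])


def _observed_information(data: _PanelData, params: GbtmParams, step=1e-5) -> np.ndarray:
    """Observed information of the full mixture likelihood by central
    finite differences of the analytic gradient."""
    G, p = params.beta.shape
    x0 = np.concatenate([params.beta.ravel(), [np.log(params.sigma)], params.theta])
    k = len(x0)

    def grad_at(x):
        beta = x[: G * p].reshape(G, p)
        sigma = float(np.exp(x[G * p]))
        theta = x[G * p + 1:]
        return _mixture_grad(data, GbtmParams(beta=beta, sigma=sigma, theta=theta))

    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = step
        H[i] = (grad_at(x0 + e) - grad_at(x0 - e)) / (2 * step)
    H = 0.5 * (H + H.T)
    return -H


def predict_trajectory(
    fit: GbtmFit,
    ages,
    level: float = 0.95,
    compute_bands: bool = True,
    _panel: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group expected observed trajectory with delta-method point-wise
    confidence bands on the censored (0-8) scale.

    Bands require the observed information of the fitted likelihood, which
    needs the fitted panel; pass it via ``_panel`` or call with
    ``compute_bands=False`` for curves only.
    """
    from scipy.stats import norm as _norm

    spec = fit.spec
    ages = np.asarray(ages, dtype=float)
    t = spec.scale_age(ages)
    if np.any(np.abs(t) > 1.0 + 1e-9):
        warnings.warn("ages outside the fitted scaled-age range; extrapolating")
    Xg = _design_matrix(t, spec.order)
    G, p = fit.params.beta.shape

    rows = []
    cov = None
    if compute_bands and _panel is not None:
        data = _prepare_panel(_panel, spec)
        info = _observed_information(data, fit.params)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)

    zq = _norm.ppf(0.5 + level / 2)
    for j in range(G):
        mu = Xg @ fit.params.beta[j]
        curve = cnorm_expected_observed(mu, fit.params.sigma, spec.y_min, spec.y_max)
        lo = hi = np.full_like(np.atleast_1d(curve), np.nan)
        if cov is not None:
            # delta method on (beta_j, log sigma); numerical curve gradient
            idx = list(range(j * p, (j + 1) * p)) + [G * p]
            sub = cov[np.ix_(idx, idx)]
            se = np.empty(len(ages))
            h = 1e-6
            for m, a_row in enumerate(Xg):
                gvec = np.zeros(p + 1)
                base_mu = float(a_row @ fit.params.beta[j])
                for q in range(p):
                    gvec[q] = (
                        cnorm_expected_observed(
                            base_mu + h * a_row[q], fit.params.sigma, spec.y_min, spec.y_max
                        )
                        - cnorm_expected_observed(
                            base_mu - h * a_row[q], fit.params.sigma, spec.y_min, spec.y_max
                        )
                    ) / (2 * h)
                s_hi = fit.params.sigma * np.exp(h)
                s_lo = fit.params.sigma * np.exp(-h)
                gvec[p] = (
                    cnorm_expected_observed(base_mu, s_hi, spec.y_min, spec.y_max)
                    - cnorm_expected_observed(base_mu, s_lo, spec.y_min, spec.y_max)
                ) / (2 * h)
                var = float(gvec @ sub @ gvec)
                se[m] = np.sqrt(max(var, 0.0))
            lo = np.clip(np.atleast_1d(curve) - zq * se, spec.y_min, spec.y_max)
            hi = np.clip(np.atleast_1d(curve) + zq * se, spec.y_min, spec.y_max)
        for m, a in enumerate(ages):
            rows.append({
                "group": j + 1,
                "age": a,
                "curve": float(np.atleast_1d(curve)[m]),
                "lower": float(np.atleast_1d(lo)[m]),
                "upper": float(np.atleast_1d(hi)[m]),
            })
    return pd.DataFrame(rows)
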