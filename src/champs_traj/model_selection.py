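"""Diagnostics for choosing the number of trajectory groups.

Reports, per candidate group count G: the parameter count, AIC and BIC
(the latter on both the observation count and the child count, following
the trajectory-modelling reporting convention in which the criteria are
``loglik - k`` and ``loglik - (k/2) ln n`` and larger is better), the
average posterior probability of assignment (APPA, adequacy threshold
0.7), the odds of correct classification (OCC, threshold 5), the smallest
modal group, and child-level cross-validated prediction distances
(k = 2, 10, 50 and leave-one-out in the original analysis).

The cross-validation distance is the posterior-weighted mean absolute
difference between each held-out observation and the trained group curves
on the observed 0-8 scale; posteriors come from the held-out child's own
data under the trained model.  Modal-assignment and marginal (mixture-
weighted) variants are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gbtm import (
    GbtmFit,
    TrajectorySpec,
    cnorm_expected_observed,
    count_parameters,
    fit_gbtm,
    posterior_probs,
    _design_matrix,
)

__all__ = [
    "SelectionReport",
    "information_criteria",
    "appa",
    "occ",
    "kfold_cv",
    "loo_cv",
    "selection_table",
    "recommend_groups",
]


def information_criteria(loglik: float, k: int, n_obs: int, n_children: int):
    """(AIC, BIC_obs, BIC_children) in the larger-is-better convention:
    AIC = loglik - k, BIC_n = loglik - (k/2) ln n."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if not (n_obs >= n_children >= 1):
        raise ValueError("need n_obs >= n_children >= 1")
    aic = loglik - k
    bic_obs = loglik - 0.5 * k * math.log(n_obs)
    bic_children = loglik - 0.5 * k * math.log(n_children)
    return aic, bic_obs, bic_children


def appa(fit: GbtmFit) -> np.ndarray:
    """Average posterior probability of assignment per group: the mean
    posterior membership among children modally assigned to the group.
    Groups with no assigned children yield NaN."""
    G = fit.spec.n_groups
    out = np.full(G, np.nan)
    for j in range(G):
        mask = fit.assignment == j + 1
        if mask.any():
            out[j] = float(fit.posterior[mask, j].mean())
    return out


def occ(fit: GbtmFit, appa_values: np.ndarray | None = None) -> np.ndarray:
    """Odds of correct classification per group:
    [APPA_j/(1-APPA_j)] / [pi_j/(1-pi_j)] with estimated membership
    probabilities pi_j.  Undefined (all-NaN) for a one-group model; an
    APPA of exactly 1 yields +inf."""
    G = fit.spec.n_groups
    if G == 1:
        return np.array([np.nan])
    a = appa(fit) if appa_values is None else np.asarray(appa_values, float)
    pi = fit.pi_hat
    out = np.full(G, np.nan)
    for j in range(G):
        if np.isnan(a[j]):
            continue
        prior_odds = pi[j] / (1.0 - pi[j])
        if a[j] >= 1.0:
            out[j] = np.inf
        else:
            out[j] = (a[j] / (1.0 - a[j])) / prior_odds
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _holdout_distance(fit: GbtmFit, held_panel: pd.DataFrame, scheme: str):
    """(total absolute distance, n observations) of a held-out set under a
    trained model."""
    spec = fit.spec
    df = held_panel.dropna(subset=["y"])
    if len(df) == 0:
        return 0.0, 0
    w = posterior_probs(fit.params, df, spec)  # (children, G), index child_id
    t = spec.scale_age(df["age"].to_numpy())
    mu = _design_matrix(t, spec.order) @ fit.params.beta.T  # (n_obs, G)
    curves = cnorm_expected_observed(mu, fit.params.sigma, spec.y_min, spec.y_max)
    abs_err = np.abs(df["y"].to_numpy()[:, None] - curves)  # (n_obs, G)
    if scheme == "posterior":
        W = w.loc[df["child_id"]].to_numpy()
    elif scheme == "modal":
        modal = w.to_numpy().argmax(axis=1)
        W = np.zeros_like(w.to_numpy())
        W[np.arange(len(W)), modal] = 1.0
        W = pd.DataFrame(W, index=w.index).loc[df["child_id"]].to_numpy()
    elif scheme == "marginal":
        W = np.broadcast_to(fit.params.pi, abs_err.shape)
    else:
        raise ValueError(f"unknown CV weighting scheme {scheme!r}")
    return float(np.sum(W * abs_err)), len(df)


def kfold_cv(
    panel: pd.DataFrame,
    spec: TrajectorySpec,
    k: int,
    seed: int = 0,
    scheme: str = "posterior",
    fit_options: dict | None = None,
) -> float:
    """Mean held-out prediction distance over one random child-level
    k-fold split.  Deterministic given the seed; ``k`` equal to the number
    of children reduces to leave-one-out."""
    if k < 2:
        raise ValueError("k must be >= 2")
    fit_options = dict(fit_options or {})
    fit_options.setdefault("n_starts", 1)
    # the split seed shuffles children only; fold fits are seeded separately
    # so that k = n_children coincides with leave-one-out for any seed
    fit_options.setdefault("seed", 0)
    children = np.asarray(sorted(panel["child_id"].unique()))
    if k > len(children):
        raise ValueError("more folds than children")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(children))
    folds = [children[perm[i::k]] for i in range(k)]
    if any(len(f) == 0 for f in folds):
        raise ValueError("a fold has zero children")

    total, n_total = 0.0, 0
    for fold in folds:
        held = panel[panel["child_id"].isin(fold)]
        train = panel[~panel["child_id"].isin(fold)]
        fit = fit_gbtm(train, spec, **fit_options)
        d, m = _holdout_distance(fit, held, scheme)
        total += d
        n_total += m
    if n_total == 0:
        raise ValueError("no held-out observations")
    return total / n_total


def loo_cv(
    panel: pd.DataFrame,
    spec: TrajectorySpec,
    scheme: str = "posterior",
    fit_options: dict | None = None,
) -> float:
    """Leave-one-out cross-validation: each child held out in turn.
    Deterministic (no random split is involved)."""
    children = sorted(panel["child_id"].unique())
    fit_options = dict(fit_options or {})
    fit_options.setdefault("n_starts", 1)
    fit_options.setdefault("seed", 0)
    total, n_total = 0.0, 0
    for cid in children:
        held = panel[panel["child_id"] == cid]
        train = panel[panel["child_id"] != cid]
        fit = fit_gbtm(train, spec, **fit_options)
        d, m = _holdout_distance(fit, held, scheme)
        total += d
        n_total += m
    return total / n_total


# ---------------------------------------------------------------------------
# the selection table
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Model-choice diagnostics for a range of candidate group counts."""

    table: pd.DataFrame
    appa_threshold: float = 0.7
    occ_threshold: float = 5.0
    min_group_size: int = 25
    fits: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def recommended(self, cv_column: str | None = None, rel_tol: float = 0.05) -> int:
        return recommend_groups(self, cv_column=cv_column, rel_tol=rel_tol)


def selection_table(
    panel: pd.DataFrame,
    spec_template: TrajectorySpec | None = None,
    g_range=range(1, 6),
    cv_schemes=(2,),
    seed: int = 0,
    order: int = 3,
    fit_options: dict | None = None,
    appa_threshold: float = 0.7,
    occ_threshold: float = 5.0,
    min_group_size: int = 25,
) -> SelectionReport:
    """Fit every candidate G and assemble all diagnostics in one table.

    ``cv_schemes`` is an iterable of fold counts (integers) and/or the
    string ``"loo"``.  A fit failure for one G is recorded and does not
    abort the rest of the table.
    """
    fit_options = dict(fit_options or {})
    fit_options.setdefault("seed", seed)
    rows, fits, errors = [], {}, {}
    n_children = panel.dropna(subset=["y"])["child_id"].nunique()
    n_obs = int(panel["y"].notna().sum())

    for G in g_range:
        spec = (
            TrajectorySpec(n_groups=G, order=order)
            if spec_template is None
            else TrajectorySpec(
                n_groups=G, order=spec_template.order,
                y_min=spec_template.y_min, y_max=spec_template.y_max,
            )
        )
        row = {"G": G, "k": count_parameters(spec)}
        try:
            fit = fit_gbtm(panel, spec, **fit_options)
        except Exception as exc:  # propagate per-G failures into the table
            errors[G] = str(exc)
            row.update({"error": str(exc)})
            rows.append(row)
            continue
        fits[G] = fit
        aic, bic_obs, bic_children = information_criteria(
            fit.loglik, row["k"], n_obs, n_children
        )
        a = appa(fit)
        o = occ(fit, a)
        sizes = np.bincount(fit.assignment, minlength=G + 1)[1:]
        row.update({
            "loglik": fit.loglik, "AIC": aic, "BIC_obs": bic_obs,
            "BIC_children": bic_children,
            "APPA_min": float(np.nanmin(a)),
            "OCC_min": float(np.nanmin(o)) if G > 1 else np.nan,
            "min_group_n": int(sizes.min()),
            "appa_ok": bool(np.nanmin(a) > appa_threshold),
            "occ_ok": bool(G == 1 or np.nanmin(o) > occ_threshold),
            "size_ok": bool(sizes.min() >= min_group_size),
        })
        for scheme in cv_schemes:
            if scheme == "loo":
                row["CV_loo"] = loo_cv(panel, spec, fit_options=fit_options)
            else:
                row[f"CV_{int(scheme)}"] = kfold_cv(
                    panel, spec, int(scheme), seed=seed, fit_options=fit_options
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    return SelectionReport(
        table=table, appa_threshold=appa_threshold, occ_threshold=occ_threshold,
        min_group_size=min_group_size, fits=fits, errors=errors,
    )


def recommend_groups(report: SelectionReport, cv_column: str | None = None,
                     rel_tol: float = 0.05) -> int:
    """Smallest adequate G whose CV distance is within ``rel_tol`` (relative)
    of the best CV distance — the 'decrease has stabilised' reading of the
    CV curve, subject to the APPA/OCC/minimum-size adequacy rules."""
    t = report.table
    ok = t[t.get("appa_ok", True) & t.get("occ_ok", True) & t.get("size_ok", True)]
    if len(ok) == 0:
        ok = t.dropna(subset=["loglik"]) if "loglik" in t else t
    if cv_column is None:
        cv_cols = [c for c in t.columns if c.startswith("CV_")]
        if not cv_cols:
            return int(ok.loc[ok["BIC_children"].idxmax(), "G"])
        cv_column = cv_cols[0]
    best = ok[cv_column].min()
    adequate = ok[ok[cv_column] <= best * (1 + rel_tol)]
    return int(adequate["G"].min())
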