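"""Motor-performance scoring: orientation, stratified z-scores, composites.

Six baseline tests are scored: backward balance (points), precision throw
(points), hand grip (kg), vertical jump (cm), shuttle run (seconds — lower
is better), and the Andersen intermittent running test (metres).  Each test
is oriented so that larger is better (the shuttle-run value is multiplied
by -1), standardised to a z-score within sex x age-category strata, and
combined into three composites: a health-related score (hand grip,
Andersen), a coordination-related score (vertical jump, shuttle run,
backward balance, precision throw) and a total score over all six.  Each
composite is the arithmetic mean of its member z-scores and is split into
tertiles low / middle / high.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "TEST_DIRECTIONS",
    "HEALTH_TESTS",
    "COORDINATION_TESTS",
    "DEFAULT_AGE_BINS",
    "orient_scores",
    "assign_age_category",
    "stratified_zscores",
    "composite_scores",
    "tertile_assign",
    "score_motor_tests",
]

logger = logging.getLogger(__name__)

# +1: higher raw value is better; -1: lower is better
TEST_DIRECTIONS = {
    "backward_balance": 1,
    "precision_throw": 1,
    "hand_grip": 1,
    "vertical_jump": 1,
    "shuttle_run": -1,
    "andersen": 1,
}

HEALTH_TESTS = ("hand_grip", "andersen")
COORDINATION_TESTS = ("vertical_jump", "shuttle_run", "backward_balance", "precision_throw")

# two-year age bands; the last band is open-ended upwards
DEFAULT_AGE_BINS = ((6, 7), (8, 9), (10, 11), (12, 14))


def orient_scores(raw: pd.DataFrame, directions: dict | None = None) -> pd.DataFrame:
    """Sign-flip tests for which a lower raw value means better performance.

    Applying the orientation twice returns the original values.
    """
    overrides = {} if directions is None else dict(directions)
    unknown = [c for c in overrides if c not in TEST_DIRECTIONS]
    if unknown:
        raise KeyError(f"unknown test name(s): {unknown}")
    directions = {**TEST_DIRECTIONS, **overrides}
    tests = [c for c in raw.columns if c in directions]
    out = raw.copy()
    for c in tests:
        if directions[c] not in (-1, 1):
            raise ValueError(f"direction for {c} must be +1 or -1")
        out[c] = raw[c] * directions[c]
    return out


def assign_age_category(age, bins=DEFAULT_AGE_BINS) -> pd.Series:
    """Label ages with their band, e.g. '6-7'; ages below the first band
    fall into it and ages above the last band into the last."""
    age = pd.Series(age, dtype=float)
    labels = [f"{lo}-{hi}" for lo, hi in bins]

    def _one(a):
        if np.isnan(a):
            return None
        for (lo, hi), lab in zip(bins, labels):
            if a < hi + 1:  # band covers [lo, hi+1)
                return lab
        return labels[-1]

    return age.map(_one)


def stratified_zscores(
    oriented: pd.DataFrame,
    sex: pd.Series,
    age_category: pd.Series,
    tests=None,
) -> pd.DataFrame:
    """z = (x - stratum mean) / stratum SD within each sex x age stratum.

    Sample SD (denominator n-1).  Singleton or zero-variance strata give
    missing z-scores with a logged warning.
    """
    tests = [c for c in oriented.columns if c in TEST_DIRECTIONS] if tests is None else list(tests)
    strata = pd.DataFrame({"sex": np.asarray(sex), "age_cat": np.asarray(age_category)},
                          index=oriented.index)
    out = pd.DataFrame(index=oriented.index, columns=tests, dtype=float)
    for key, idx in strata.groupby(["sex", "age_cat"]).groups.items():
        block = oriented.loc[idx, tests]
        n = block.notna().sum()
        sd = block.std(ddof=1)
        bad = (n < 2) | (sd == 0) | sd.isna()
        if bad.any():
            logger.warning("stratum %s: %d test(s) with <2 values or zero SD", key, int(bad.sum()))
        z = (block - block.mean()) / sd
        z.loc[:, bad[bad].index] = np.nan
        out.loc[idx, tests] = z
    return out.add_prefix("z_")


def composite_scores(z: pd.DataFrame, require_complete: bool = False) -> pd.DataFrame:
    """Health, coordination and total composites as means of member z-scores.

    With ``require_complete`` a composite is missing unless every member is
    present; otherwise it averages the available members and reports the
    number missing per child.
    """
    zh = z[[f"z_{t}" for t in HEALTH_TESTS]]
    zc = z[[f"z_{t}" for t in COORDINATION_TESTS]]
    za = z[[f"z_{t}" for t in TEST_DIRECTIONS]]
    skipna = not require_complete
    out = pd.DataFrame(index=z.index)
    out["health"] = zh.mean(axis=1, skipna=skipna)
    out["coordination"] = zc.mean(axis=1, skipna=skipna)
    out["total"] = za.mean(axis=1, skipna=skipna)
    out["n_tests_missing"] = za.isna().sum(axis=1)
    return out


def tertile_assign(values) -> pd.Series:
    """Split values at the empirical 1/3 and 2/3 order-statistic quantiles.

    Values at or below the lower cut are 'low', at or below the upper cut
    'middle', else 'high' (ties assigned downward).  With distinct values
    and n divisible by 3 the groups are equal-sized; with all values equal
    everything is 'low'.  Missing values stay missing.
    """
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values for tertiles")
    lower = np.quantile(obs, 1 / 3, method="inverted_cdf")
    upper = np.quantile(obs, 2 / 3, method="inverted_cdf")
    out = pd.Series(index=s.index, dtype=object)
    out[s <= lower] = "low"
    out[(s > lower) & (s <= upper)] = "middle"
    out[s > upper] = "high"
    out[s.isna()] = None
    return out


def score_motor_tests(
    motor: pd.DataFrame,
    age_bins=DEFAULT_AGE_BINS,
    require_complete: bool = False,
) -> pd.DataFrame:
    """End-to-end scoring: orient, stratify, standardise, compose, cut.

    ``motor`` needs the six test columns plus ``sex`` and ``age_at_test``.
    Returns one row per child with z-scores, composites and tertiles.
    """
    oriented = orient_scores(motor)
    age_cat = assign_age_category(motor["age_at_test"], age_bins)
    z = stratified_zscores(oriented, motor["sex"], age_cat)
    comp = composite_scores(z, require_complete=require_complete)
    out = pd.concat(
        [motor[["child_id"]].reset_index(drop=True) if "child_id" in motor else pd.DataFrame(),
         pd.DataFrame({"sex": motor["sex"].values, "age_category": age_cat.values}),
         z.reset_index(drop=True), comp.reset_index(drop=True)],
        axis=1,
    )
    for comp_name in ("health", "coordination", "total"):
        out[f"{comp_name}_tertile"] = tertile_assign(out[comp_name]).values
    return out
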