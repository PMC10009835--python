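"""Synthetic cohort generator emulating a Danish school-based open cohort.

Two fidelity levels are provided:

* :func:`generate_cohort` produces raw weekly SMS-style responses (integer
  session counts 0-8, sport-type codes), an open-cohort roster with entry
  at ages 5-13, staggered entry/dropout, holiday-suspended prompt weeks and
  non-response — realistic enough to exercise the aggregation rules.
* :func:`generate_model_faithful_panel` draws monthly outcomes exactly from
  the censored-normal trajectory model, with no rounding, for clean
  parameter-recovery experiments.

Defaults mirror the study conditions the analysis assumes: ~1,500 children,
five latent trajectory groups with shares of roughly 14/27/29/22/9 percent,
a study span of Aug-2009 to Jun-2014 with ~44 prompt weeks per year (two
Christmas weeks and six summer weeks suspended), and six baseline motor
tests whose group gradient is induced by a single latent fitness factor.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gbtm import GbtmParams, TrajectorySpec, _design_matrix

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "HolidaySpec",
    "NO_HOLIDAYS",
    "build_study_calendar",
    "generate_cohort",
    "generate_model_faithful_panel",
    "default_group_curves",
]

SPORT_CODES = {
    1: "soccer", 2: "handball", 3: "basketball", 4: "volleyball",
    5: "rhythmic_gymnastics", 6: "tumbling_gymnastics", 7: "swimming",
    8: "horse_riding", 9: "dancing", 10: "other",
}

# local-community popularity weights used when assigning sport repertoires
_SPORT_POPULARITY = np.array([0.30, 0.21, 0.02, 0.07, 0.03, 0.02, 0.08, 0.09, 0.03, 0.15])

MOTOR_TESTS = (
    "backward_balance", "precision_throw", "hand_grip",
    "vertical_jump", "shuttle_run", "andersen",
)


@dataclass(frozen=True)
class HolidaySpec:
    """Weeks in which the weekly prompt is suspended."""

    christmas: bool = True          # the ISO weeks containing Dec 24 and Dec 31
    summer_weeks: int = 6
    summer_start_week: int = 27     # first suspended ISO week of the summer break


NO_HOLIDAYS = HolidaySpec(christmas=False, summer_weeks=0)


def _parse_month(m) -> dt.date:
    if isinstance(m, dt.date):
        return dt.date(m.year, m.month, 1)
    y, mo = str(m).split("-")[:2]
    return dt.date(int(y), int(mo), 1)


def _month_end(d: dt.date) -> dt.date:
    if d.month == 12:
        return dt.date(d.year, 12, 31)
    return dt.date(d.year, d.month + 1, 1) - dt.timedelta(days=1)


def build_study_calendar(start, end, holidays: HolidaySpec = HolidaySpec()):
    """Ordered prompt weeks between two months, excluding holiday weeks.

    Weeks are ISO weeks identified by ``(iso_year, iso_week)``; a week is in
    the span if its Monday falls between the first day of ``start`` and the
    last day of ``end``.  Default holidays: the two ISO weeks containing
    Christmas Eve and New Year's Eve, plus six consecutive summer weeks.
    """
    start_d = _parse_month(start)
    end_d = _month_end(_parse_month(end))
    if start_d > end_d:
        raise ValueError("start month after end month")

    excluded: set[tuple[int, int]] = set()
    for year in range(start_d.year - 1, end_d.year + 2):
        if holidays.christmas:
            for day in (dt.date(year, 12, 24), dt.date(year, 12, 31)):
                iso = day.isocalendar()
                excluded.add((iso[0], iso[1]))
        for k in range(holidays.summer_weeks):
            excluded.add((year, holidays.summer_start_week + k))

    weeks = []
    monday = start_d + dt.timedelta(days=(7 - start_d.weekday()) % 7)
    while monday <= end_d:
        iso = monday.isocalendar()
        wk = (iso[0], iso[1])
        if wk not in excluded:
            weeks.append(wk)
        monday += dt.timedelta(days=7)
    return weeks


def default_group_curves(n_groups: int = 5) -> np.ndarray:
    """Cubic coefficients (on age scaled to [-1, 1] over 6-16 years) for the
    default latent group curves: a flat non-participating group, a low
    decreasing group, and three increasing groups peaking around age 13-14.

    Curves are anchored at ages 6, 9.5, 13 and 16 and interpolated exactly.
    """
    anchors_t = np.array([-1.0, -0.3, 0.4, 1.0])
    anchor_values = {
        5: np.array([
            [-0.6, -0.6, -0.6, -0.6],   # little/no participation
            [1.1, 0.5, 0.0, -0.5],      # low decreasing
            [1.0, 1.5, 1.9, 1.4],       # slight increase, late slight decrease
            [1.5, 2.3, 3.1, 2.6],       # moderate increasing
            [1.0, 2.8, 4.5, 3.6],       # rapid increase to ~4.4, then decline
        ]),
        3: np.array([
            [0.3, 0.5, 0.7, 0.5],
            [3.2, 3.5, 3.8, 3.6],
            [5.8, 6.3, 6.8, 6.5],
        ]),
    }
    if n_groups not in anchor_values:
        raise ValueError("default curves defined for 3 or 5 groups")
    V = _design_matrix(anchors_t, order=3)
    return np.linalg.solve(V, anchor_values[n_groups].T).T


def _default_logits() -> tuple[float, ...]:
    # log(pi_j / pi_1) for shares approx (.135, .270, .290, .220, .085)
    pi = np.array([0.135, 0.270, 0.290, 0.220, 0.085])
    return tuple(np.log(pi[1:] / pi[0]))


@dataclass
class CohortConfig:
    """Generative settings; defaults emulate the study conditions."""

    n_children: int = 1500
    entry_age_range: tuple[float, float] = (5.0, 13.0)
    start_month: str = "2009-08"
    end_month: str = "2014-06"
    n_groups: int = 5
    membership_logits: tuple[float, ...] = field(default_factory=_default_logits)
    beta: np.ndarray | None = None          # (G, 4) on scaled age; None -> defaults
    sigma: float = 1.0
    weekly_response_rate: float = 0.75
    dropout_hazard: float = 0.005           # per-month leaving probability
    motor_effects: tuple[float, ...] = (-0.5, -0.2, 0.0, 0.25, 0.5)
    age_center: float = 11.0                # scaled-age transform for beta
    age_scale: float = 5.0
    holidays: HolidaySpec = field(default_factory=HolidaySpec)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_children < 0:
            raise ValueError("n_children must be non-negative")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.weekly_response_rate <= 1.0):
            raise ValueError("weekly_response_rate must be in [0, 1]")
        logits = np.asarray(self.membership_logits, dtype=float)
        if logits.shape != (self.n_groups - 1,):
            raise ValueError("membership_logits must have length n_groups - 1")
        if not np.all(np.isfinite(logits)):
            raise ValueError("membership logits must be finite")
        if self.beta is None:
            self.beta = default_group_curves(self.n_groups)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.shape[0] != self.n_groups:
            raise ValueError("beta must have one row per group")
        if len(self.motor_effects) != self.n_groups:
            raise ValueError("motor_effects must have one entry per group")

    @property
    def pi(self) -> np.ndarray:
        logits = np.concatenate([[0.0], np.asarray(self.membership_logits, float)])
        e = np.exp(logits - logits.max())
        return e / e.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = self.beta.tolist()
        d["holidays"] = asdict(self.holidays)
        return d


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for recovery experiments."""

    group: pd.Series            # per-child true group label, 1-based
    config: dict
    seed: int

    def to_json(self, path=None) -> str:
        payload = {
            "group": {str(k): int(v) for k, v in self.group.items()},
            "config": self.config,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _latent_mean(config: CohortConfig, group: int, age_years: np.ndarray) -> np.ndarray:
    t = (np.asarray(age_years, float) - config.age_center) / config.age_scale
    return _design_matrix(t, order=config.beta.shape[1] - 1) @ config.beta[group]


# baselines for the six motor tests: (intercept at age 6, slope per year,
# male offset, factor loading, residual SD).  Shuttle run is in seconds and
# loads negatively: fitter children are faster.
_MOTOR_BASELINES = {
    "backward_balance": (28.0, 2.0, -1.0, 6.0, 6.0),
    "precision_throw": (10.0, 1.2, 1.0, 2.5, 2.5),
    "hand_grip": (10.0, 2.2, 1.0, 2.0, 2.5),
    "vertical_jump": (20.0, 1.6, 1.5, 3.5, 3.0),
    "shuttle_run": (25.0, -0.7, -0.4, -1.6, 1.2),
    "andersen": (850.0, 25.0, 30.0, 55.0, 50.0),
}

_MOTOR_RANGES = {"backward_balance": (0, 72), "precision_throw": (0, 30)}


def generate_cohort(config: CohortConfig):
    """Simulate an open cohort: roster, weekly responses, motor tests, truth.

    Children enter at ages 5-13, either at study start or later (open
    cohort); each prompt week inside a child's enrolment is answered with
    probability ``weekly_response_rate``; the weekly count is the latent
    group polynomial plus normal noise, rounded and clipped to 0-8 (8 also
    standing for "more than seven").  Motor tests are generated at entry
    from sex- and age-dependent baselines plus a latent fitness factor
    shifted by group.  Fully reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    calendar = build_study_calendar(config.start_month, config.end_month, config.holidays)
    week_mondays = np.array(
        [dt.date.fromisocalendar(y, w, 1).toordinal() for y, w in calendar]
    )
    start_d = _parse_month(config.start_month)
    end_d = _month_end(_parse_month(config.end_month))
    n_months_span = (end_d.year - start_d.year) * 12 + end_d.month - start_d.month + 1

    empty_roster = pd.DataFrame(
        columns=["child_id", "sex", "school", "school_type", "dob", "entry_month", "exit_month"]
    )
    empty_weekly = pd.DataFrame(
        columns=["child_id", "iso_year", "iso_week", "sessions", "sports"]
    )
    empty_motor = pd.DataFrame(columns=["child_id", "sex", "age_at_test", *MOTOR_TESTS])
    if config.n_children == 0:
        truth = TruthRecord(group=pd.Series(dtype=int), config=config.to_dict(),
                            seed=config.rng_seed)
        return empty_roster, empty_weekly, empty_motor, truth

    n = config.n_children
    ids = np.array([f"c{i:05d}" for i in range(1, n + 1)])
    sex = np.where(rng.random(n) < 0.516, "girl", "boy")
    # ten schools: six sports schools, four control, uneven sizes
    school_ids = np.arange(10)
    school_type = np.where(school_ids < 6, "sports", "control")
    school = rng.choice(school_ids, size=n, p=np.r_[np.full(6, 0.095), np.full(4, 0.1075)])

    groups = rng.choice(config.n_groups, size=n, p=config.pi) + 1

    # entry: 60% at study start, the rest uniformly over the first 4 years
    late = rng.random(n) < 0.4
    entry_offset = np.where(late, rng.integers(1, max(n_months_span - 12, 2), size=n), 0)
    entry_age = rng.uniform(*config.entry_age_range, size=n)
    # dropout: geometric in months after entry
    stay = rng.geometric(max(config.dropout_hazard, 1e-9), size=n)

    roster_rows, weekly_rows, motor_rows = [], [], []
    group_series = {}
    for i in range(n):
        e_off = int(entry_offset[i])
        entry_month = start_d + pd.DateOffset(months=e_off)
        entry_month = dt.date(entry_month.year, entry_month.month, 1)
        exit_off = min(e_off + int(stay[i]), n_months_span - 1)
        exit_month = start_d + pd.DateOffset(months=exit_off)
        exit_month = _month_end(dt.date(exit_month.year, exit_month.month, 1))
        dob_ord = entry_month.toordinal() - int(round(entry_age[i] * 365.25))
        dob = dt.date.fromordinal(dob_ord)

        roster_rows.append({
            "child_id": ids[i], "sex": sex[i], "school": int(school[i]),
            "school_type": school_type[school[i]], "dob": dob.isoformat(),
            "entry_month": f"{entry_month.year}-{entry_month.month:02d}",
            "exit_month": f"{exit_month.year}-{exit_month.month:02d}",
        })
        group_series[ids[i]] = int(groups[i])

        in_window = (week_mondays >= entry_month.toordinal()) & (
            week_mondays <= exit_month.toordinal()
        )
        wk_idx = np.flatnonzero(in_window)
        responded = wk_idx[rng.random(len(wk_idx)) < config.weekly_response_rate]
        if len(responded):
            ages = (week_mondays[responded] - dob_ord) / 365.25
            latent = _latent_mean(config, groups[i] - 1, ages) + rng.normal(
                0.0, config.sigma, size=len(responded)
            )
            counts = np.clip(np.rint(latent), 0, 8).astype(int)
            # static per-child sport repertoire of 1-3 sports
            n_sports = rng.integers(1, 4)
            repertoire = rng.choice(
                np.arange(1, 11), size=n_sports, replace=False,
                p=_SPORT_POPULARITY / _SPORT_POPULARITY.sum(),
            )
            for k, widx in enumerate(responded):
                iso_y, iso_w = calendar[widx]
                c = int(counts[k])
                if c >= 1:
                    m = int(rng.integers(1, n_sports + 1))
                    codes = ";".join(str(s) for s in sorted(rng.choice(repertoire, m, replace=False)))
                else:
                    codes = ""
                weekly_rows.append({
                    "child_id": ids[i], "iso_year": iso_y, "iso_week": iso_w,
                    "sessions": c, "sports": codes,
                })

        # motor tests at entry
        factor = rng.normal() + config.motor_effects[groups[i] - 1]
        age_t = entry_age[i]
        male = 1.0 if sex[i] == "boy" else 0.0
        row = {"child_id": ids[i], "sex": sex[i], "age_at_test": round(age_t, 2)}
        for test, (b0, slope, male_off, loading, sd) in _MOTOR_BASELINES.items():
            val = b0 + slope * (age_t - 6.0) + male_off * male + loading * factor + rng.normal(0, sd)
            if test in _MOTOR_RANGES:
                lo, hi = _MOTOR_RANGES[test]
                val = float(np.clip(val, lo, hi))
            row[test] = round(float(val), 2)
        motor_rows.append(row)

    roster = pd.DataFrame(roster_rows) if roster_rows else empty_roster
    weekly = pd.DataFrame(weekly_rows) if weekly_rows else empty_weekly
    motor = pd.DataFrame(motor_rows) if motor_rows else empty_motor
    truth = TruthRecord(
        group=pd.Series(group_series, name="group"),
        config=config.to_dict(),
        seed=config.rng_seed,
    )
    return roster, weekly, motor, truth


def generate_model_faithful_panel(
    params: GbtmParams,
    spec: TrajectorySpec,
    ages,
    n_children: int,
    seed: int = 0,
    missing_rate: float = 0.0,
):
    """Draw a monthly panel exactly from the censored-normal mixture.

    Each child gets a group from ``params.pi``; at every design age the
    outcome is a normal draw around the group polynomial, clipped to the
    censoring limits (no rounding).  Observations are removed completely at
    random with probability ``missing_rate``.
    """
    if spec.age_center is None or spec.age_scale is None:
        raise ValueError("spec must carry an age transform")
    ages = np.asarray(ages, dtype=float)
    t = spec.scale_age(ages)
    if np.any(np.abs(t) > 1.0 + 1e-9):
        raise ValueError("design ages outside the spec's scaled-age range")
    rng = np.random.default_rng(seed)
    G = params.n_groups
    X = _design_matrix(t, spec.order)
    mu = X @ params.beta.T  # (n_ages, G)

    groups = rng.choice(G, size=n_children, p=params.pi) + 1
    latent = mu[:, groups - 1].T + (
        rng.normal(0.0, params.sigma, size=(n_children, len(ages)))
        if params.sigma > 0 else 0.0
    )
    y = np.clip(latent, spec.y_min, spec.y_max)
    ids = np.array([f"c{i:05d}" for i in range(1, n_children + 1)])
    panel = pd.DataFrame({
        "child_id": np.repeat(ids, len(ages)),
        "age": np.tile(ages, n_children),
        "y": y.ravel(),
    })
    if missing_rate > 0:
        panel = panel[rng.random(len(panel)) >= missing_rate].reset_index(drop=True)
    truth = TruthRecord(
        group=pd.Series(groups, index=ids, name="group"),
        config={"params": params.to_dict(), "ages": ages.tolist(),
                "missing_rate": missing_rate},
        seed=seed,
    )
    return panel, truth
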