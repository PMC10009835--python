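"""End-to-end orchestration: simulate -> aggregate -> select/fit -> scores
-> associate -> report, driven by one configuration mapping.

Every stage writes plain CSV/JSON so any stage can also be run standalone;
a manifest records the seed, package versions, timings and a checksum per
artifact, making a rerun with the same configuration byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariate_scores import score_motor_tests
from .gbtm import TrajectorySpec, fit_gbtm, predict_trajectory
from .group_association import cluster_robust_vcov, fit_multinomial, overall_test, rrr_table
from .model_selection import recommend_groups, selection_table
from .sms_aggregation import (
    aggregate_weekly_to_monthly,
    exclude_sparse_children,
    sport_type_summary,
)
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Settings for one pipeline run (simulation mode)."""

    seed: int = 0
    outdir: str = "champs_run"
    cohort: dict = dataclasses.field(default_factory=dict)
    g_min: int = 1
    g_max: int = 5
    cv_schemes: tuple = (2,)
    order: int = 3
    n_starts: int = 2
    age_bins: tuple = ((6, 7), (8, 9), (10, 11), (12, 14))
    cluster_level: str = "school"
    make_plots: bool = True
    min_group_size: int | None = None  # None: 2% of children, capped at 25

    @classmethod
    def from_mapping(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": {},
        "artifacts": {},
    }

    def _save(df_or_text, name):
        path = out / name
        if isinstance(df_or_text, pd.DataFrame):
            df_or_text.to_csv(path, index=False)
        else:
            path.write_text(df_or_text)
        manifest["artifacts"][name] = _sha256(path)
        return path

    def _stage(name):
        manifest["stages"][name] = round(time.time() - t0, 2)

    try:
        # 1. simulate ----------------------------------------------------
        cohort_kwargs = dict(config.cohort)
        cohort_kwargs.setdefault("rng_seed", config.seed)
        cc = CohortConfig(**cohort_kwargs)
        roster, weekly, motor, truth = generate_cohort(cc)
        _save(roster, "roster.csv")
        _save(weekly, "weekly_responses.csv")
        _save(motor, "motor_tests.csv")
        _save(truth.to_json(), "truth.json")
        _stage("simulate")

        # 2. aggregate ---------------------------------------------------
        panel = aggregate_weekly_to_monthly(weekly, roster=roster)
        panel, excluded = exclude_sparse_children(panel)
        _save(panel, "monthly_panel.csv")
        _save(json.dumps({"excluded_children": excluded}, indent=2), "exclusions.json")
        _stage("aggregate")

        # 3. model selection --------------------------------------------
        n_kids = panel["child_id"].nunique()
        min_size = (
            config.min_group_size
            if config.min_group_size is not None
            else min(25, max(2, n_kids // 50))
        )
        report = selection_table(
            panel,
            g_range=range(config.g_min, config.g_max + 1),
            cv_schemes=config.cv_schemes,
            seed=config.seed,
            order=config.order,
            fit_options={"n_starts": config.n_starts, "seed": config.seed},
            min_group_size=min_size,
        )
        _save(report.table, "selection_table.csv")
        best_g = recommend_groups(report)
        _stage("select")

        # 4. final fit + trajectory curves ------------------------------
        fit = report.fits.get(best_g) or fit_gbtm(
            panel, TrajectorySpec(n_groups=best_g, order=config.order),
            n_starts=config.n_starts, seed=config.seed,
        )
        _save(fit.to_json(), "fit.json")
        assignments = fit.assignment_series()
        _save(
            assignments.rename_axis("child_id").reset_index(),
            "assignments.csv",
        )
        ages = np.linspace(
            fit.spec.age_center - fit.spec.age_scale,
            fit.spec.age_center + fit.spec.age_scale,
            41,
        )
        curves = predict_trajectory(fit, ages, _panel=panel)
        _save(curves, "trajectories.csv")
        _stage("fit")

        if config.make_plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            cv_cols = [c for c in report.table.columns if c.startswith("CV_")]
            if cv_cols:
                figa, ax = plt.subplots()
                for c in cv_cols:
                    ax.plot(report.table["G"], report.table[c], marker="o", label=c)
                ax.set_xlabel("number of groups")
                ax.set_ylabel("mean CV distance")
                ax.legend()
                figa.savefig(out / "cv_distance.png", dpi=100)
                plt.close(figa)
                manifest["artifacts"]["cv_distance.png"] = _sha256(out / "cv_distance.png")
            figb, ax = plt.subplots()
            for g, sub in curves.groupby("group"):
                ax.plot(sub["age"], sub["curve"], label=f"group {g}")
                ax.fill_between(sub["age"], sub["lower"], sub["upper"], alpha=0.2)
            ax.set_xlabel("age (years)")
            ax.set_ylabel("weekly sports sessions")
            ax.set_ylim(0, 8)
            ax.legend()
            figb.savefig(out / "trajectories.png", dpi=100)
            plt.close(figb)
            manifest["artifacts"]["trajectories.png"] = _sha256(out / "trajectories.png")
        _stage("plots")

        # 5. group descriptives (sport types) ---------------------------
        sports = sport_type_summary(weekly, assignments)
        _save(sports, "sport_type_summary.csv")
        _stage("descriptives")

        # 6. motor scores ------------------------------------------------
        scored = score_motor_tests(motor, age_bins=config.age_bins)
        _save(scored, "motor_scores.csv")
        _stage("scores")

        # 7. association -------------------------------------------------
        merged = scored.merge(
            assignments.rename("group").rename_axis("child_id").reset_index(),
            on="child_id",
        ).merge(roster[["child_id", "school", "school_type", "sex"]], on="child_id",
                suffixes=("", "_roster"))
        merged = merged.dropna(subset=["total_tertile"])
        design = pd.DataFrame({
            "boy": (merged["sex"] == "boy").astype(float),
            "sports_school": (merged["school_type"] == "sports").astype(float),
            "total_middle": (merged["total_tertile"] == "middle").astype(float),
            "total_high": (merged["total_tertile"] == "high").astype(float),
        })
        fit_assoc = fit_multinomial(merged["group"], design)
        cluster = merged["school"] if config.cluster_level == "school" else merged["school"]
        vcov = cluster_robust_vcov(fit_assoc, cluster)
        table = rrr_table(fit_assoc, vcov)
        null_fit = fit_multinomial(merged["group"], design[[]])
        table.attrs["overall_p"] = overall_test(fit_assoc, null_fit)
        _save(table, "rrr_table.csv")
        _save(json.dumps({
            "overall_p": table.attrs["overall_p"],
            "vcov": vcov.tolist(),
            "recommended_groups": best_g,
        }, indent=2), "association.json")
        _stage("associate")
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(
            f"pipeline failed after stages {list(manifest['stages'])}: {exc}"
        ) from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["recommended_groups"] = best_g
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
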