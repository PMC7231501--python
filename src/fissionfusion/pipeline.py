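"""Desk-scale orchestration of the whole density-manipulation study.

Given a 12-6-12 treatment set (ingested or synthetic), the pipeline

1. estimates the Markov social-state probabilities per treatment (and pooled
   over the two high-density treatments),
2. summarises group geometry (hull metrics, grid area usage, polarisation),
3. calibrates the independent random-walk null model to the high-density
   social time and predicts the low-density treatment,
4. compares observation and prediction by confidence-interval overlap,
5. runs the paired-swap randomisation tests on focal swimming distances,
6. tests the observed polygon reduction against the simulation null, and
7. sweeps counterfactual arena restrictions to find the area reduction that
   would reproduce the observed low-density social time.

Each stage is isolated: a failure marks the stage and the rest still runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .trajectories import TrackTable, mean_individual_distance, path_length
from .social_states import (
    MarkovEstimates,
    SamplingSpec,
    build_state_sequences,
    estimate_probabilities,
)
from .group_geometry import (
    mean_hull_metrics,
    polygon_reduction,
    summarise_geometry,
)
from .random_walk import (
    CalibrationError,
    WalkConfig,
    calibrate,
    density_experiment,
    social_time,
)
from .resampling_stats import (
    null_polygon_reductions,
    paired_swap_test,
    polygon_percentile_test,
)
from .synthetic import TreatmentSet

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "counterfactual_area_sweep",
    "AreaSweepResult",
    "load_study_config",
]

_PROB_NAMES = ("p_leave_nn", "p_s_to_a", "p_a_to_s", "p_switch_nn")


@dataclass
class StudyConfig:
    """Tunable knobs of one pipeline run."""

    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    step: float = 0.5
    heading_change_prob: float = 0.03
    calibration_replicates: int = 20
    probability_replicates: int = 20
    geometry_replicates: int = 100
    swap_test_reps: int = 100_000
    percentile_reps: int = 1_000
    counterfactual_reductions: tuple = tuple(np.round(np.arange(0.0, 0.85, 0.07), 3))
    counterfactual_replicates: int = 20
    halve_ci: bool = True
    seed: int = 0


@dataclass
class StudyReport:
    """Structured results of one study run; JSON-serialisable."""

    population: str
    seed: int
    treatments: dict = field(default_factory=dict)
    pooled_g12: dict | None = None
    null_model: dict | None = None
    comparison: dict | None = None
    swimming_tests: dict | None = None
    polygon_tests: dict | None = None
    counterfactual: dict | None = None
    failures: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _estimates_dict(est: MarkovEstimates) -> dict:
    out = {}
    for name in _PROB_NAMES + ("social_time_fraction",):
        e = getattr(est, name)
        lo, hi = e.ci if e.ci else (None, None)
        out[name] = {
            "estimate": e.value,
            "numerator": e.numerator,
            "denominator": e.denominator,
            "ci_low": lo,
            "ci_high": hi,
        }
    return out


def _ci_overlap(obs: dict, sim: dict) -> dict:
    """Interval-overlap comparison for each probability."""
    out = {}
    for name in _PROB_NAMES + ("social_time_fraction",):
        o, s = obs[name], sim[name]
        if None in (o["ci_low"], s["ci_low"]):
            out[name] = None
        else:
            out[name] = bool(
                o["ci_low"] <= s["ci_high"] and s["ci_low"] <= o["ci_high"]
            )
    return out


@dataclass
class AreaSweepResult:
    """Counterfactual social-time curve over arena-area reductions."""

    reductions: list[float]
    social_time: list[float]
    social_time_se: list[float]
    target: float
    required_reduction: float | None
    monotone: bool
    replicates: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def counterfactual_area_sweep(
    config_low: WalkConfig,
    reductions: Sequence[float],
    target_social_time: float,
    replicates: int = 20,
    seed: int = 0,
    spec: SamplingSpec | None = None,
) -> AreaSweepResult:
    """Simulate the low-density group under shrinking arenas.

    ``reductions`` are fractions of the (already effective) area removed;
    reduction 0 reproduces the unrestricted simulation.  The required
    reduction is the smallest one whose mean social time reaches the target,
    linearly interpolated between grid points; None when the target is not
    reached on the grid.
    """
    reductions = sorted(float(r) for r in reductions)
    if reductions and not 0.0 <= reductions[0] <= reductions[-1] <= 0.9:
        raise ValueError("reductions must lie within [0, 0.9]")
    spec = spec or SamplingSpec()
    base_scale = config_low.arena.area_scale
    means, ses = [], []
    for i, r in enumerate(reductions):
        cfg = config_low.with_area_scale(base_scale * (1.0 - r))
        m, se = social_time(cfg, replicates, seed + 131 * (i + 1), spec)
        means.append(m)
        ses.append(se)
    monotone = all(b >= a - 0.02 for a, b in zip(means, means[1:]))
    required = None
    for i, m in enumerate(means):
        if m >= target_social_time:
            if i == 0:
                required = reductions[0]
            else:
                lo_r, hi_r = reductions[i - 1], reductions[i]
                lo_m, hi_m = means[i - 1], means[i]
                frac = (target_social_time - lo_m) / (hi_m - lo_m)
                required = lo_r + frac * (hi_r - lo_r)
            break
    return AreaSweepResult(
        reductions=list(reductions),
        social_time=means,
        social_time_se=ses,
        target=target_social_time,
        required_reduction=required,
        monotone=monotone,
        replicates=replicates,
    )


def run_study(treatments: TreatmentSet, config: StudyConfig | None = None) -> StudyReport:
    """Run the full analysis on one treatment set."""
    config = config or StudyConfig()
    report = StudyReport(population=treatments.population, seed=config.seed)
    spec = config.sampling
    seqs_by_label = {}

    # 1+2: per-treatment estimation and geometry
    for label, table in sorted(treatments.recordings.items()):
        entry = {}
        try:
            seqs = build_state_sequences(table, spec)
            seqs_by_label[label] = seqs
            est = estimate_probabilities(seqs, halve_ci=config.halve_ci)
            entry["estimates"] = _estimates_dict(est)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report.failures[f"estimates:{label}"] = str(exc)
        try:
            geom = summarise_geometry(table, focal_ids=treatments.focal_ids)
            entry["geometry"] = geom.to_dict()
            entry["mean_swimming_distance_cm"] = mean_individual_distance(
                table, treatments.focal_ids
            )
        except Exception as exc:  # noqa: BLE001
            report.failures[f"geometry:{label}"] = str(exc)
        report.treatments[label] = entry

    # pooled high-density estimates
    try:
        pooled = seqs_by_label["G12a"] + seqs_by_label["G12b"]
        report.pooled_g12 = _estimates_dict(
            estimate_probabilities(pooled, halve_ci=config.halve_ci)
        )
    except Exception as exc:  # noqa: BLE001
        report.failures["pooled_g12"] = str(exc)

    # 3: null-model calibration to the pooled high-density social time
    calibrated = None
    try:
        target = report.pooled_g12["social_time_fraction"]["estimate"]
        result = calibrate(
            target,
            n_agents=12,
            step=config.step,
            heading_change_prob=config.heading_change_prob,
            spec=spec,
            seed=config.seed,
            replicates=config.calibration_replicates,
            arena=treatments.recordings["G12a"].arena,
        )
        calibrated = result.config
        comparison = density_experiment(
            calibrated,
            n_low=6,
            replicates_probabilities=config.probability_replicates,
            replicates_geometry=config.geometry_replicates,
            seed=config.seed + 1,
            spec=spec,
        )
        report.null_model = {
            "calibration": {
                "target": result.target,
                "achieved": result.achieved,
                "area_scale": calibrated.arena.area_scale,
                "step": calibrated.step,
                "heading_change_prob": calibrated.heading_change_prob,
                "replicates": result.replicates,
            },
            "predicted_g12": _estimates_dict(comparison.estimates_high),
            "predicted_g6": _estimates_dict(comparison.estimates_low),
            "social_time_g12": comparison.social_time_high,
            "social_time_g6": comparison.social_time_low,
            "perimeter_reduction": comparison.perimeter_reduction,
            "area_reduction": comparison.area_reduction,
            "replicates_geometry": comparison.replicates_geometry,
        }
        # 4: CI-overlap comparison of observed G6 against predicted G6
        report.comparison = {
            "g6_observed_vs_null": _ci_overlap(
                report.treatments["G6"]["estimates"],
                report.null_model["predicted_g6"],
            )
        }
    except CalibrationError as exc:
        report.failures["null_model"] = f"calibration failed: {exc}"
    except Exception as exc:  # noqa: BLE001
        report.failures["null_model"] = str(exc)

    # 5: randomisation tests on focal swimming distances
    try:
        dists = {
            label: np.array(
                [
                    path_length(treatments.recordings[label].trajectory(i))
                    for i in treatments.focal_ids
                ]
            )
            for label in ("G12a", "G6", "G12b")
        }
        tests = {}
        for a_label, b_label in (("G12a", "G12b"), ("G12a", "G6"), ("G12b", "G6")):
            res = paired_swap_test(
                dists[a_label],
                dists[b_label],
                reps=config.swap_test_reps,
                seed=config.seed + 17,
            )
            tests[f"{a_label}-{b_label}"] = {
                "statistic": res.observed_stat,
                "p_value": res.p_value,
                "repetitions": res.repetitions,
            }
        report.swimming_tests = tests
    except Exception as exc:  # noqa: BLE001
        report.failures["swimming_tests"] = str(exc)

    # 6: polygon reductions against the simulation null
    try:
        per = {l: mean_hull_metrics(treatments.recordings[l]) for l in
               ("G12a", "G6", "G12b")}
        base_per = 0.5 * (per["G12a"][0] + per["G12b"][0])
        base_area = 0.5 * (per["G12a"][1] + per["G12b"][1])
        obs_per_red = polygon_reduction(base_per, per["G6"][0])
        obs_area_red = polygon_reduction(base_area, per["G6"][1])
        entry = {
            "observed_perimeter_reduction": obs_per_red,
            "observed_area_reduction": obs_area_red,
        }
        if calibrated is not None:
            null = null_polygon_reductions(
                calibrated, n_low=6, reps=config.percentile_reps,
                seed=config.seed + 23,
            )
            for metric, observed in (
                ("perimeter", obs_per_red),
                ("area", obs_area_red),
            ):
                res = polygon_percentile_test(
                    observed, calibrated, metric=metric, null_reductions=null
                )
                entry[metric] = {
                    "critical_value": res.critical_value,
                    "significant": res.significant,
                    "repetitions": res.repetitions,
                }
        report.polygon_tests = entry
    except Exception as exc:  # noqa: BLE001
        report.failures["polygon_tests"] = str(exc)

    # 7: counterfactual area sweep toward the observed G6 social time
    try:
        target = report.treatments["G6"]["estimates"]["social_time_fraction"][
            "estimate"
        ]
        if calibrated is None:
            raise RuntimeError("no calibrated null model")
        sweep = counterfactual_area_sweep(
            calibrated.with_agents(6),
            config.counterfactual_reductions,
            target,
            replicates=config.counterfactual_replicates,
            seed=config.seed + 29,
            spec=spec,
        )
        report.counterfactual = sweep.to_dict()
    except Exception as exc:  # noqa: BLE001
        report.failures["counterfactual"] = str(exc)

    return report


def write_report_tables(report: StudyReport, out_dir: str | Path) -> None:
    """Emit the report as delimited tables plus the JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, entry in report.treatments.items():
        if "estimates" not in entry:
            continue
        for name, rec in entry["estimates"].items():
            rows.append({"treatment": label, "probability": name, **rec})
    pd.DataFrame(rows).to_csv(out / "estimates.csv", index=False)
    rows = []
    for label, entry in report.treatments.items():
        if "geometry" in entry:
            rows.append(
                {
                    "treatment": label,
                    **entry["geometry"],
                    "mean_swimming_distance_cm": entry.get(
                        "mean_swimming_distance_cm"
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(out / "geometry.csv", index=False)
    if report.null_model is not None:
        rows = []
        for tag in ("predicted_g12", "predicted_g6"):
            for name, rec in report.null_model[tag].items():
                rows.append({"prediction": tag, "probability": name, **rec})
        pd.DataFrame(rows).to_csv(out / "null_model.csv", index=False)
    if report.counterfactual is not None:
        pd.DataFrame(
            {
                "area_reduction": report.counterfactual["reductions"],
                "social_time": report.counterfactual["social_time"],
                "social_time_se": report.counterfactual["social_time_se"],
            }
        ).to_csv(out / "counterfactual.csv", index=False)
    report.to_json(out / "report.json")


def load_study_config(path: str | Path) -> StudyConfig:
    """Study configuration from a YAML mapping (keys as in StudyConfig)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    sampling = data.pop("sampling", None)
    config = StudyConfig(**data)
    if sampling:
        config.sampling = SamplingSpec(**sampling)
    return config
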