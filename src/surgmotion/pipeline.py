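"""End-to-end orchestration: ingest -> metrics -> statistics -> reports.

``run_analysis`` consumes either a directory of trial files or a synthetic
cohort spec, computes per-trial motion metrics, builds the three report
tables (GRS by skill with Spearman; metrics mean±SD by skill; pairwise
Mann-Whitney p-values with Pearson-vs-GRS columns), exports trajectory and
scatter CSVs, and records every effective parameter in a JSON manifest so
a run is fully reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .io_jigsaws import (
    DEFAULT_SAMPLE_RATE_HZ,
    EXERCISES,
    ColumnLayout,
    KinematicStream,
    TrialRecord,
    load_dataset,
)
from .kinematics import (
    DEFAULT_MANIPULATORS,
    DEFAULT_MIN_PEAK_HEIGHT_FRACTION,
    DEFAULT_SIGMA_SAMPLES,
    MotionMetrics,
    compute_metrics,
    trajectory_export,
)
from .stats import (
    DEFAULT_ALPHA,
    SKILL_PAIRS,
    ExerciseStats,
    linear_trend,
    skill_comparison_table,
)
from .synthetic import CohortSpec, SkillProfile, generate_cohort

logger = logging.getLogger(__name__)

_REFERENCE_CSV = Path(__file__).parent / "data" / "reference_tables.csv"


@dataclass
class RunConfig:
    """Fully explicit configuration of one analysis run.

    Exactly one of ``input_dir`` (a directory of trial files) or
    ``cohort`` (a synthetic cohort spec) must be set.
    """

    input_dir: Path | None = None
    cohort: CohortSpec | None = None
    exercises: tuple[str, ...] = EXERCISES
    manipulators: tuple[str, ...] = DEFAULT_MANIPULATORS
    layout: ColumnLayout = field(default_factory=ColumnLayout)
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    sigma_samples: float = DEFAULT_SIGMA_SAMPLES
    min_peak_height_fraction: float = DEFAULT_MIN_PEAK_HEIGHT_FRACTION
    min_peak_separation: float | None = None  # default: 2 * sigma
    alpha: float = DEFAULT_ALPHA
    out_dir: Path | None = None
    seed: int = 0
    strict: bool = False
    n_trajectory_exports: int = 2  # per exercise

    def validate(self) -> None:
        if (self.input_dir is None) == (self.cohort is None):
            raise ConfigurationError(
                "exactly one of input_dir or cohort must be given"
            )
        for ex in self.exercises:
            if ex not in EXERCISES:
                raise ConfigurationError(f"unknown exercise {ex!r}")
        if self.sigma_samples <= 0:
            raise ConfigurationError("sigma_samples must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @property
    def effective_peak_separation(self) -> float:
        if self.min_peak_separation is not None:
            return self.min_peak_separation
        return 2.0 * self.sigma_samples


@dataclass
class AnalysisReport:
    """In-memory analysis result; the CSV/JSON files mirror these frames."""

    metrics: pd.DataFrame
    table1_grs: pd.DataFrame
    table2_metrics: pd.DataFrame
    table3_comparisons: pd.DataFrame
    scatter: pd.DataFrame
    trends: pd.DataFrame
    manifest: dict
    exercise_stats: dict[str, ExerciseStats]


_HAND_NAME = {"master_left": "left", "master_right": "right",
              "slave_left": "slave_left", "slave_right": "slave_right"}

_SKILL_ORDER = ("novice", "intermediate", "expert")


def _metrics_frame(
    metrics: list[MotionMetrics], records: list[TrialRecord]
) -> pd.DataFrame:
    rows = []
    for m, r in zip(metrics, records):
        row = {
            "trial_id": m.trial_id,
            "exercise": r.exercise,
            "participant": r.participant,
            "repetition": r.repetition,
            "skill_level": r.skill_level,
            "grs_total": r.grs_total,
            "time_s": m.time_s,
        }
        for manip, mm in m.per_manipulator.items():
            hand = _HAND_NAME.get(manip, manip)
            row[f"{hand}_path_length_m"] = mm.path_length_m
            row[f"{hand}_movements"] = mm.movements
        rows.append(row)
    return pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)


def _table1(stats_by_ex: dict[str, ExerciseStats]) -> pd.DataFrame:
    rows = []
    for ex, st in stats_by_ex.items():
        grs = st.tables.get("grs")
        sp = st.skill_grs_spearman
        for skill in _SKILL_ORDER:
            g = grs.groups.get(skill) if grs else None
            if g is None:
                continue
            rows.append({
                "exercise": ex,
                "n_trials_total": st.n_trials,
                "skill_level": skill,
                "n": g.n,
                "grs_mean": g.mean,
                "grs_sd": g.sd,
                "spearman_r_skill_grs": sp.r if sp else None,
                "spearman_p_skill_grs": sp.p if sp else None,
            })
    return pd.DataFrame(rows)


def _table2(stats_by_ex: dict[str, ExerciseStats]) -> pd.DataFrame:
    rows = []
    for ex, st in stats_by_ex.items():
        for param, table in st.tables.items():
            if param == "grs":
                continue
            for skill in _SKILL_ORDER:
                g = table.groups.get(skill)
                if g is None:
                    continue
                rows.append({
                    "exercise": ex,
                    "skill_level": skill,
                    "n": g.n,
                    "parameter": param,
                    "mean": g.mean,
                    "sd": g.sd,
                })
    return pd.DataFrame(rows)


def _table3(stats_by_ex: dict[str, ExerciseStats], alpha: float) -> pd.DataFrame:
    rows = []
    for ex, st in stats_by_ex.items():
        for param, table in st.tables.items():
            row: dict = {"exercise": ex, "parameter": param}
            for g1, g2 in SKILL_PAIRS:
                p = table.pairwise_p.get((g1, g2))
                row[f"p_{g1}_{g2}"] = p
                row[f"sig_{g1}_{g2}"] = None if p is None else bool(p < alpha)
            corr = st.grs_pearson.get(param) if param != "grs" else None
            row["pearson_r_grs"] = corr.r if corr else None
            row["pearson_p_grs"] = corr.p if corr else None
            row["pearson_strength"] = corr.strength if corr else None
            rows.append(row)
    return pd.DataFrame(rows)


def _scatter_and_trends(
    metrics_df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    scatter_rows = []
    trend_rows = []
    params = [c for c in metrics_df.columns
              if c == "time_s" or c.endswith("_path_length_m") or c.endswith("_movements")]
    for ex, grp in metrics_df.groupby("exercise"):
        grp = grp.dropna(subset=["grs_total"])
        if grp.empty:
            continue
        for param in params:
            x = grp[param].astype(float).to_numpy()
            y = grp["grs_total"].astype(float).to_numpy()
            for tid, xv, yv in zip(grp["trial_id"], x, y):
                scatter_rows.append({
                    "exercise": ex, "parameter": param, "trial_id": tid,
                    "value": xv, "grs_total": yv,
                })
            if len(x) >= 2 and np.ptp(x) > 0:
                slope, intercept = linear_trend(x, y)
                trend_rows.append({
                    "exercise": ex, "parameter": param,
                    "slope": slope, "intercept": intercept, "n": len(x),
                })
    return pd.DataFrame(scatter_rows), pd.DataFrame(trend_rows)


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline described by ``config``.

    Returns the in-memory report; when ``config.out_dir`` is set, also
    writes metrics/tables/scatter/trajectory CSVs and ``manifest.json``.
    Deterministic: same config and seed give byte-identical outputs.
    """
    config.validate()
    skipped: list[str] = []
    if config.input_dir is not None:
        streams, records, skipped = load_dataset(
            config.input_dir,
            layout=config.layout,
            sample_rate_hz=config.sample_rate_hz,
            strict=config.strict,
        )
        streams = {r.trial_id: streams[r.trial_id] for r in records}
        input_mode = {"mode": "directory", "path": str(config.input_dir)}
    else:
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        streams, records, _ = generate_cohort(cohort)
        input_mode = {"mode": "synthetic", "cohort_seed": cohort.seed}

    pairs = [(r, streams[r.trial_id]) for r in records
             if r.exercise in config.exercises]
    if not pairs:
        raise FileNotFoundError(
            f"no trials for exercises {config.exercises} "
            f"(input: {input_mode})"
        )
    for ex in config.exercises:
        if not any(r.exercise == ex for r, _ in pairs):
            logger.warning("no trials found for exercise %s", ex)

    metrics: list[MotionMetrics] = []
    recs: list[TrialRecord] = []
    for record, stream in sorted(pairs, key=lambda p: p[0].trial_id):
        m = compute_metrics(
            stream,
            manipulators=config.manipulators,
            sigma_samples=config.sigma_samples,
            min_peak_separation=config.min_peak_separation,
            trial_id=record.trial_id,
        )
        logger.info("processed %s: %.1f s", record.trial_id, m.time_s)
        metrics.append(m)
        recs.append(record)

    stats_by_ex = skill_comparison_table(metrics, recs, alpha=config.alpha)
    metrics_df = _metrics_frame(metrics, recs)
    table1 = _table1(stats_by_ex)
    table2 = _table2(stats_by_ex)
    table3 = _table3(stats_by_ex, config.alpha)
    scatter, trends = _scatter_and_trends(metrics_df)

    manifest = {
        "package_version": __version__,
        "input": input_mode,
        "seed": config.seed,
        "exercises": list(config.exercises),
        "manipulators": list(config.manipulators),
        "manipulator_order": list(config.layout.manipulator_order),
        "sample_rate_hz": config.sample_rate_hz,
        "sigma_samples": config.sigma_samples,
        "min_peak_height_fraction": config.min_peak_height_fraction,
        "min_peak_separation_samples": config.effective_peak_separation,
        "alpha": config.alpha,
        "sd_convention": "sample (n-1)",
        "skill_ordinal_coding": {"novice": 1, "intermediate": 2, "expert": 3},
        "strict": config.strict,
        "n_trials_analyzed": len(recs),
        "skipped_trials": skipped,
    }

    report = AnalysisReport(
        metrics=metrics_df,
        table1_grs=table1,
        table2_metrics=table2,
        table3_comparisons=table3,
        scatter=scatter,
        trends=trends,
        manifest=manifest,
        exercise_stats=stats_by_ex,
    )
    if config.out_dir is not None:
        _write_report(report, config, streams, recs)
    return report


def _write_report(
    report: AnalysisReport,
    config: RunConfig,
    streams: dict[str, KinematicStream],
    records: list[TrialRecord],
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    report.metrics.to_csv(out / "metrics.csv", index=False, float_format=fmt)
    report.table1_grs.to_csv(out / "table1_grs.csv", index=False, float_format=fmt)
    report.table2_metrics.to_csv(out / "table2_metrics.csv", index=False, float_format=fmt)
    report.table3_comparisons.to_csv(out / "table3_comparisons.csv", index=False, float_format=fmt)
    report.scatter.to_csv(out / "scatter.csv", index=False, float_format=fmt)
    report.trends.to_csv(out / "trends.csv", index=False, float_format=fmt)
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True) + "\n"
    )
    # trajectory exports: first N trials per exercise, every analyzed hand
    traj_dir = out / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    per_ex: dict[str, int] = {}
    for record in sorted(records, key=lambda r: r.trial_id):
        k = per_ex.get(record.exercise, 0)
        if k >= config.n_trajectory_exports:
            continue
        per_ex[record.exercise] = k + 1
        stream = streams[record.trial_id]
        for manip in config.manipulators:
            pts = trajectory_export(stream, manip)
            t = np.arange(pts.shape[0]) / stream.sample_rate_hz
            df = pd.DataFrame({"t_s": t, "x_m": pts[:, 0],
                               "y_m": pts[:, 1], "z_m": pts[:, 2]})
            df.to_csv(traj_dir / f"{record.trial_id}_{manip}.csv",
                      index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# comparison against published reference values
# ---------------------------------------------------------------------------


def _printed_tolerance(printed: str) -> float:
    """Half a unit in the last printed decimal place."""
    printed = printed.strip()
    if "." in printed:
        decimals = len(printed.split(".")[1])
        return 0.5 * 10.0 ** (-decimals)
    return 0.5


def diff_report(
    report_dir: str | Path,
    reference_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Compare a written report against published reference values.

    The reference CSV has columns table, exercise, skill_level, parameter,
    value, policy.  Policy ``exact`` rows (trial counts, time means, GRS
    means — parameter-free quantities) get a pass/fail verdict at the
    printed rounding; policy ``informational`` rows (path length, movement
    counts — dependent on unpublished smoothing parameters) are listed
    with deltas but not judged.  Reference rows absent from the report are
    listed as uncomparable.
    """
    report_dir = Path(report_dir)
    ref_path = Path(reference_csv) if reference_csv else _REFERENCE_CSV
    ref = pd.read_csv(ref_path, dtype={"value": str})
    table1 = pd.read_csv(report_dir / "table1_grs.csv")
    table2 = pd.read_csv(report_dir / "table2_metrics.csv")

    rows = []
    for _, r in ref.iterrows():
        computed = _lookup_computed(table1, table2, r)
        printed = float(r["value"])
        row = {
            "table": r["table"],
            "exercise": r["exercise"],
            "skill_level": r["skill_level"],
            "parameter": r["parameter"],
            "printed": printed,
            "computed": computed,
        }
        if computed is None or (isinstance(computed, float) and math.isnan(computed)):
            row.update(computed=None, abs_delta=None, rel_delta=None,
                       status="uncomparable")
        else:
            delta = computed - printed
            row["abs_delta"] = delta
            row["rel_delta"] = delta / printed if printed else None
            if r["policy"] == "informational":
                row["status"] = "parameter-dependent, informational"
            else:
                tol = _printed_tolerance(r["value"])
                row["status"] = "pass" if abs(delta) <= tol else "fail"
        rows.append(row)
    return pd.DataFrame(rows)


def _lookup_computed(table1: pd.DataFrame, table2: pd.DataFrame, ref_row) -> float | None:
    ex = ref_row["exercise"]
    skill = ref_row["skill_level"]
    param = ref_row["parameter"]
    if ref_row["table"] == "table1":
        sub = table1[table1["exercise"] == ex]
        if sub.empty:
            return None
        if param == "n_trials":
            return float(sub["n_trials_total"].iloc[0])
        if param == "spearman_r":
            return float(sub["spearman_r_skill_grs"].iloc[0])
        sub = sub[sub["skill_level"] == skill]
        if sub.empty:
            return None
        if param == "grs_mean":
            return float(sub["grs_mean"].iloc[0])
        if param == "grs_sd":
            return float(sub["grs_sd"].iloc[0])
        return None
    if ref_row["table"] == "table2":
        stat = "mean"
        name = param
        if param.endswith("_sd"):
            stat, name = "sd", param[:-3]
        elif param.endswith("_mean"):
            name = param[:-5]
        if name == "n":
            stat = "n"
            name = "time"  # group sizes identical across parameters
        sub = table2[
            (table2["exercise"] == ex)
            & (table2["skill_level"] == skill)
            & (table2["parameter"] == name)
        ]
        if sub.empty:
            return None
        return float(sub[stat].iloc[0])
    return None


# ---------------------------------------------------------------------------
# cohort spec loading (YAML/JSON)
# ---------------------------------------------------------------------------


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Load a :class:`CohortSpec` from a YAML (or JSON) mapping.

    Top-level keys mirror the dataclass fields; ``skill_profiles`` maps
    skill level to :class:`SkillProfile` fields.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: cohort spec must be a mapping")
    kwargs = dict(raw)
    if "exercises" in kwargs:
        kwargs["exercises"] = tuple(kwargs["exercises"])
    if "skill_profiles" in kwargs:
        kwargs["skill_profiles"] = {
            skill: SkillProfile(**params)
            for skill, params in kwargs["skill_profiles"].items()
        }
    try:
        return CohortSpec(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from None
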