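"""Group summaries, Mann-Whitney comparisons, correlations and trend lines.

Conventions: two-sided tests, significance at alpha = 0.05, sample (n-1)
standard deviations, correlation strength banded on |r| with strict
thresholds (>0.7 strong, >0.5 moderate, >0.3 weak, else negligible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError
from .io_jigsaws import SKILL_ORDINAL, TrialRecord
from .kinematics import MotionMetrics

DEFAULT_ALPHA = 0.05

#: Pairs reported in the comparison tables, in display order.
SKILL_PAIRS = (
    ("novice", "intermediate"),
    ("intermediate", "expert"),
    ("novice", "expert"),
)


@dataclass(frozen=True)
class GroupSummary:
    """Mean and sample SD of one parameter within one skill group."""

    group: str
    n: int
    mean: float
    sd: float | None  # None when n == 1 (sample SD undefined)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int
    strength: str


@dataclass
class ComparisonTable:
    """Per-parameter group summaries plus pairwise Mann-Whitney p-values."""

    parameter: str
    groups: dict[str, GroupSummary]
    pairwise_p: dict[tuple[str, str], float | None]
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> dict[tuple[str, str], bool | None]:
        return {
            pair: (None if p is None else bool(p < self.alpha))
            for pair, p in self.pairwise_p.items()
        }


def group_summary(values: Sequence[float], labels: Sequence[str]) -> list[GroupSummary]:
    """Per-group mean and sample (n-1) standard deviation.

    Groups appear in first-seen label order; an empty group is simply not
    reported.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(labels):
        raise DomainError("values and labels must have equal length")
    out: list[GroupSummary] = []
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        vals = values[np.asarray(labels) == lab]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else None
        out.append(GroupSummary(group=lab, n=int(vals.size), mean=float(vals.mean()), sd=sd))
    return out


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U = min(U_a, U_b) under midrank tie handling.  The
    p-value uses the exact null distribution when both samples have at most
    8 observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


def classify_correlation(r: float) -> str:
    """Band |r|: >0.7 strong, >0.5 moderate, >0.3 weak, else negligible.

    Thresholds are strict, so |r| = 0.70 is moderate.
    """
    mag = abs(r)
    if mag > 1 + 1e-12:
        raise DomainError(f"|r| must be <= 1, got {r}")
    if mag > 0.7:
        return "strong"
    if mag > 0.5:
        return "moderate"
    if mag > 0.3:
        return "weak"
    return "negligible"


def _check_corr_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError(f"need n >= 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined: zero variance in an input")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_corr_inputs(x, y)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        method="pearson", r=r, p=float(res.pvalue), n=int(x.size),
        strength=classify_correlation(r),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_corr_inputs(x, y)
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        method="spearman", r=r, p=float(res.pvalue), n=int(x.size),
        strength=classify_correlation(r),
    )


def linear_trend(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares line for scatter-plot annotation.

    Returns (slope, intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise DomainError("need n >= 2 paired observations")
    if np.ptp(x) == 0:
        raise DomainError("trend undefined: x has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# joined comparison tables (per exercise, per parameter)
# ---------------------------------------------------------------------------

#: Parameter display names for the two default (master) manipulators.
_HAND_NAME = {"master_left": "left", "master_right": "right",
              "slave_left": "slave_left", "slave_right": "slave_right"}


@dataclass
class ExerciseStats:
    """Everything the comparison/correlation reports need for one exercise."""

    exercise: str
    tables: dict[str, ComparisonTable] = field(default_factory=dict)
    grs_pearson: dict[str, CorrelationResult | None] = field(default_factory=dict)
    skill_grs_spearman: CorrelationResult | None = None
    n_trials: int = 0


def _parameter_columns(metrics: Sequence[MotionMetrics]) -> list[str]:
    manips: list[str] = []
    for m in metrics:
        for name in m.per_manipulator:
            if name not in manips:
                manips.append(name)
    cols = ["time"]
    for manip in manips:
        hand = _HAND_NAME.get(manip, manip)
        cols.append(f"{hand}_path_length")
        cols.append(f"{hand}_movements")
    return cols


def _parameter_value(m: MotionMetrics, rec: TrialRecord, column: str) -> float | None:
    if column == "time":
        return m.time_s
    if column == "grs":
        return None if rec.grs_total is None else float(rec.grs_total)
    for manip, mm in m.per_manipulator.items():
        hand = _HAND_NAME.get(manip, manip)
        if column == f"{hand}_path_length":
            return mm.path_length_m
        if column == f"{hand}_movements":
            return float(mm.movements)
    return None


def skill_comparison_table(
    metrics: Sequence[MotionMetrics],
    records: Sequence[TrialRecord],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, ExerciseStats]:
    """Build the full statistical report from joined metrics and records.

    For each exercise and parameter (time, per-hand path length and
    movements, GRS total): group summaries per skill level, the three
    pairwise Mann-Whitney tests with significance flags at ``alpha``,
    Pearson correlation of each kinematic parameter with the GRS total,
    and Spearman correlation of ordinal skill with GRS.  A pair whose
    group is absent is reported as not computable (None).

    ``metrics`` and ``records`` are joined by position and must align.
    """
    if len(metrics) != len(records):
        raise DomainError("metrics and records must align one-to-one")
    by_exercise: dict[str, list[tuple[MotionMetrics, TrialRecord]]] = {}
    for m, r in zip(metrics, records):
        by_exercise.setdefault(r.exercise, []).append((m, r))

    out: dict[str, ExerciseStats] = {}
    for exercise, pairs in by_exercise.items():
        ex = ExerciseStats(exercise=exercise, n_trials=len(pairs))
        columns = _parameter_columns([m for m, _ in pairs]) + ["grs"]
        for col in columns:
            vals: list[float] = []
            labels: list[str] = []
            for m, r in pairs:
                v = _parameter_value(m, r, col)
                if v is not None:
                    vals.append(v)
                    labels.append(r.skill_level)
            if not vals:
                continue
            summaries = {
                s.group: s
                for s in group_summary(vals, labels)
            }
            pairwise: dict[tuple[str, str], float | None] = {}
            arr = np.asarray(vals)
            lab_arr = np.asarray(labels)
            for g1, g2 in SKILL_PAIRS:
                a = arr[lab_arr == g1]
                b = arr[lab_arr == g2]
                if a.size == 0 or b.size == 0:
                    pairwise[(g1, g2)] = None
                else:
                    pairwise[(g1, g2)] = mann_whitney_u(a, b)[1]
            ex.tables[col] = ComparisonTable(
                parameter=col, groups=summaries, pairwise_p=pairwise, alpha=alpha
            )
            # Pearson of each kinematic parameter against GRS (pooled over
            # all skill levels within the exercise)
            if col != "grs":
                xy = [
                    (v, float(r.grs_total))
                    for (m, r) in pairs
                    if r.grs_total is not None
                    and (v := _parameter_value(m, r, col)) is not None
                ]
                if len(xy) >= 3:
                    x, y = zip(*xy)
                    try:
                        ex.grs_pearson[col] = pearson_r(x, y)
                    except DomainError:
                        ex.grs_pearson[col] = None
                else:
                    ex.grs_pearson[col] = None
        # Spearman: ordinal skill vs GRS total
        sk = [
            (SKILL_ORDINAL[r.skill_level], float(r.grs_total))
            for _, r in pairs
            if r.grs_total is not None
        ]
        if len(sk) >= 3:
            x, y = zip(*sk)
            try:
                ex.skill_grs_spearman = spearman_rho(x, y)
            except DomainError:
                ex.skill_grs_spearman = None
        out[exercise] = ex
    return out


def holm_correction(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
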