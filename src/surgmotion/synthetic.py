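"""Synthetic kinematic trials and cohorts with known ground truth.

Trials are sequences of discrete point-to-point movements with bell-shaped
velocity profiles (minimum-jerk), separated by stationary pauses, sampled
on a fixed clock and corrupted by isotropic Gaussian position noise.  The
generator reports the exact ground truth (movement count, noiseless path
length, trial time, peak times), which downstream metric extraction must
recover.

Cohorts mimic the dataset's structure: participants B-I with the standard
skill mapping, up to five repetitions per exercise, skill-dependent motion
parameters and a truncated discrete GRS model, written out in the same
76-column dialect the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .io_jigsaws import (
    DEFAULT_SAMPLE_RATE_HZ,
    PARTICIPANT_SKILL,
    KinematicStream,
    TrialRecord,
    write_jigsaws_kinematics,
)


def minimum_jerk_displacement(amplitude: float, duration: float, t):
    """Displacement along a minimum-jerk point-to-point movement.

    x(t) = A * (10 tau^3 - 15 tau^4 + 6 tau^5) with tau = t/T; the speed
    profile is bell-shaped, zero at both ends, with a single interior
    maximum of 1.875*A/T at tau = 0.5.  Accepts scalar or array ``t``
    (values clipped to [0, T]).
    """
    if duration <= 0:
        raise DomainError(f"duration must be > 0, got {duration}")
    if amplitude < 0:
        raise DomainError(f"amplitude must be >= 0, got {amplitude}")
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    x = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return x if x.ndim else float(x)


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Ground-truth movement structure for one synthetic trial.

    ``amplitudes_m``/``durations_s`` may be scalars (broadcast over all
    movements) or per-movement sequences.  ``pauses_s`` gives the
    stationary gaps between consecutive movements (scalar or length
    ``n_movements - 1``); ``lead_in_s``/``lead_out_s`` are stationary
    margins at either end so boundary peaks are well defined.
    """

    n_movements: int
    amplitudes_m: float | Sequence[float] = 0.1
    durations_s: float | Sequence[float] = 1.0
    pauses_s: float | Sequence[float] = 1.0
    lead_in_s: float = 0.5
    lead_out_s: float = 0.5
    noise_sd_m: float = 0.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    seed: int = 0
    directions: str = "random_sphere"  # or "fixed_x"

    def _expand(self, value, n: int, name: str) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.full(n, float(arr[0]))
        if arr.size != n:
            raise ConfigurationError(f"{name}: expected {n} values, got {arr.size}")
        return arr

    def validate(self) -> None:
        if self.n_movements < 0:
            raise ConfigurationError("n_movements must be >= 0")
        if self.noise_sd_m < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be > 0")
        if self.lead_in_s < 0 or self.lead_out_s < 0:
            raise ConfigurationError("lead margins must be >= 0")
        if self.n_movements:
            amps = self._expand(self.amplitudes_m, self.n_movements, "amplitudes_m")
            durs = self._expand(self.durations_s, self.n_movements, "durations_s")
            if np.any(durs <= 0):
                raise ConfigurationError("durations must be > 0")
            if np.any(amps < 0):
                raise ConfigurationError("amplitudes must be >= 0")
        if self.n_movements > 1:
            pauses = self._expand(self.pauses_s, self.n_movements - 1, "pauses_s")
            if np.any(pauses <= 0):
                raise ConfigurationError("pauses must be > 0")

    @property
    def noiseless_path_length_m(self) -> float:
        """Each movement is monotone along its own line, so the noiseless
        path length equals the amplitude sum."""
        if not self.n_movements:
            return 0.0
        return float(self._expand(self.amplitudes_m, self.n_movements, "amplitudes_m").sum())


@dataclass(frozen=True)
class TrialGroundTruth:
    n_movements: int
    path_length_m: float  # noiseless
    time_s: float
    peak_times_s: tuple[float, ...]  # instants of maximum speed


def _unit_directions(n: int, rng: np.random.Generator, scheme: str) -> np.ndarray:
    if scheme == "fixed_x":
        d = np.zeros((n, 3))
        d[:, 0] = 1.0
        return d
    if scheme == "random_sphere":
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    raise ConfigurationError(f"unknown direction scheme {scheme!r}")


def _single_hand_trajectory(
    spec: SyntheticTrialSpec, rng: np.random.Generator
) -> tuple[np.ndarray, TrialGroundTruth]:
    n = spec.n_movements
    amps = spec._expand(spec.amplitudes_m, n, "amplitudes_m") if n else np.empty(0)
    durs = spec._expand(spec.durations_s, n, "durations_s") if n else np.empty(0)
    pauses = (
        spec._expand(spec.pauses_s, n - 1, "pauses_s") if n > 1 else np.empty(0)
    )
    total = spec.lead_in_s + durs.sum() + pauses.sum() + spec.lead_out_s
    n_samples = int(round(total * spec.sample_rate_hz)) + 1
    t = np.arange(n_samples) / spec.sample_rate_hz

    directions = _unit_directions(n, rng, spec.directions)
    pos = np.zeros((n_samples, 3))
    origin = np.zeros(3)
    t0 = spec.lead_in_s
    peak_times = []
    for k in range(n):
        local = minimum_jerk_displacement(amps[k], durs[k], t - t0)
        pos += np.outer(local, directions[k])
        peak_times.append(t0 + durs[k] / 2.0)
        t0 += durs[k] + (pauses[k] if k < n - 1 else 0.0)
    pos += origin
    if spec.noise_sd_m > 0:
        pos = pos + rng.normal(scale=spec.noise_sd_m, size=pos.shape)
    truth = TrialGroundTruth(
        n_movements=n,
        path_length_m=spec.noiseless_path_length_m,
        time_s=n_samples / spec.sample_rate_hz,
        peak_times_s=tuple(peak_times),
    )
    return pos, truth


def generate_trial(
    spec: SyntheticTrialSpec,
    hands: Sequence[str] = ("master_left", "master_right"),
    slave_scale: float = 1.0,
) -> tuple[KinematicStream, dict[str, TrialGroundTruth]]:
    """Generate one synthetic trial.

    Each requested master hand gets an independent realization of the same
    movement structure (its own directions and noise); the corresponding
    slave channels mirror the masters scaled by ``slave_scale``.
    Deterministic for a given spec (the seed covers all randomness).

    Returns the stream plus per-hand ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    positions: dict[str, np.ndarray] = {}
    truths: dict[str, TrialGroundTruth] = {}
    for hand in hands:
        pos, truth = _single_hand_trajectory(spec, rng)
        positions[hand] = pos
        truths[hand] = truth
        slave = hand.replace("master", "slave")
        if slave != hand:
            positions[slave] = pos * slave_scale
    stream = KinematicStream(positions=positions, sample_rate_hz=spec.sample_rate_hz)
    return stream, truths


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkillProfile:
    """Distribution parameters for trials of one skill group.

    Movement counts are uniform on [n_movements_min, n_movements_max];
    amplitudes, durations and pauses are per-movement lognormal around the
    given medians; the GRS total is a rounded normal truncated to [6, 30].
    """

    n_movements_min: int
    n_movements_max: int
    amplitude_m: float = 0.05
    duration_s: float = 0.8
    pause_s: float = 0.8
    jitter: float = 0.15  # lognormal sigma for amplitudes/durations/pauses
    noise_sd_m: float = 0.0005
    grs_mean: float = 18.0
    grs_sd: float = 4.0


#: Calibrated so novices take longer, travel farther and move more than
#: experts, with intermediates in between.
DEFAULT_SKILL_PROFILES: Mapping[str, SkillProfile] = {
    "novice": SkillProfile(
        n_movements_min=28, n_movements_max=40, amplitude_m=0.07,
        duration_s=1.0, pause_s=1.0, grs_mean=14.0, grs_sd=4.0,
    ),
    "intermediate": SkillProfile(
        n_movements_min=18, n_movements_max=28, amplitude_m=0.06,
        duration_s=0.9, pause_s=0.8, grs_mean=18.0, grs_sd=4.0,
    ),
    "expert": SkillProfile(
        n_movements_min=10, n_movements_max=18, amplitude_m=0.05,
        duration_s=0.8, pause_s=0.6, grs_mean=24.0, grs_sd=3.0,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification for a dataset-shaped synthetic cohort.

    Defaults reproduce the dataset's shape: eight participants (4 novice,
    2 intermediate, 2 expert), up to five repetitions of each exercise,
    hence at most 40 trials per exercise.
    """

    exercises: tuple[str, ...] = ("suturing", "knot_tying", "needle_passing")
    trials_per_participant: int = 5
    skill_profiles: Mapping[str, SkillProfile] = field(
        default_factory=lambda: dict(DEFAULT_SKILL_PROFILES)
    )
    participants: Mapping[str, str] = field(
        default_factory=lambda: dict(PARTICIPANT_SKILL)
    )
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    slave_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.trials_per_participant <= 5:
            raise ConfigurationError("trials_per_participant must be 1-5")
        for skill in set(self.participants.values()):
            if skill not in self.skill_profiles:
                raise ConfigurationError(f"no profile for skill {skill!r}")


def _draw_grs(rng: np.random.Generator, profile: SkillProfile) -> tuple[int, tuple[int, ...]]:
    total = int(np.clip(round(rng.normal(profile.grs_mean, profile.grs_sd)), 6, 30))
    items = [1] * 6
    remaining = total - 6
    while remaining > 0:
        open_slots = [i for i in range(6) if items[i] < 5]
        items[open_slots[rng.integers(len(open_slots))]] += 1
        remaining -= 1
    return total, tuple(items)


def _draw_trial_spec(
    rng: np.random.Generator, profile: SkillProfile, rate: float
) -> SyntheticTrialSpec:
    n = int(rng.integers(profile.n_movements_min, profile.n_movements_max + 1))
    jitter = profile.jitter
    amps = profile.amplitude_m * rng.lognormal(0.0, jitter, size=n)
    durs = profile.duration_s * rng.lognormal(0.0, jitter, size=n)
    pauses = profile.pause_s * rng.lognormal(0.0, jitter, size=max(n - 1, 0))
    return SyntheticTrialSpec(
        n_movements=n,
        amplitudes_m=tuple(amps),
        durations_s=tuple(durs),
        pauses_s=tuple(pauses) if n > 1 else profile.pause_s,
        noise_sd_m=profile.noise_sd_m,
        sample_rate_hz=rate,
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, KinematicStream], list[TrialRecord], dict[str, dict[str, TrialGroundTruth]]]:
    """Generate a full cohort of synthetic trials.

    Returns (streams by trial id, trial records, ground truth by trial id).
    With ``out_dir`` set, also writes one 76-column kinematics file per
    trial under ``<out_dir>/<Exercise>/kinematics/`` and one metadata file
    per exercise, so the directory is readable by the standard loaders.
    Deterministic for a given spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    streams: dict[str, KinematicStream] = {}
    records: list[TrialRecord] = []
    truths: dict[str, dict[str, TrialGroundTruth]] = {}
    meta_lines: dict[str, list[str]] = {ex: [] for ex in spec.exercises}

    for exercise in spec.exercises:
        for participant in sorted(spec.participants):
            skill = spec.participants[participant]
            profile = spec.skill_profiles[skill]
            for rep in range(1, spec.trials_per_participant + 1):
                tspec = _draw_trial_spec(rng, profile, spec.sample_rate_hz)
                stream, truth = generate_trial(tspec, slave_scale=spec.slave_scale)
                total, items = _draw_grs(rng, profile)
                record = TrialRecord(
                    exercise=exercise,
                    participant=participant,
                    repetition=rep,
                    skill_level=skill,
                    grs_items=items,
                    grs_total=total,
                )
                trial_id = record.trial_id
                streams[trial_id] = stream
                records.append(record)
                truths[trial_id] = truth
                skill_letter = skill[0].upper()
                meta_lines[exercise].append(
                    f"{trial_id}.txt {skill_letter} {total} "
                    + " ".join(map(str, items))
                )

    if out_dir is not None:
        out_dir = Path(out_dir)
        for record in records:
            ex_token = record.trial_id.rsplit("_", 1)[0]
            kin_dir = out_dir / ex_token / "kinematics"
            kin_dir.mkdir(parents=True, exist_ok=True)
            write_jigsaws_kinematics(streams[record.trial_id], kin_dir / f"{record.trial_id}.txt")
        for exercise, lines in meta_lines.items():
            ex_token = {
                "suturing": "Suturing",
                "knot_tying": "Knot_Tying",
                "needle_passing": "Needle_Passing",
            }[exercise]
            meta_path = out_dir / ex_token / f"meta_file_{ex_token}.txt"
            meta_path.parent.mkdir(parents=True, exist_ok=True)
            meta_path.write_text("\n".join(lines) + "\n")

    return streams, records, truths
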