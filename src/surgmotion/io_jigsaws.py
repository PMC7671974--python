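"""Reading and writing JIGSAWS-style kinematic trial files and metadata.

The kinematics dialect is plain text: one frame per row, 76 whitespace
separated floats (4 manipulators x 19 variables each), sampled at 30 Hz.
Per-manipulator block layout: 3 position, 9 rotation-matrix, 3 linear
velocity, 3 angular velocity, 1 gripper angle.  Only the position triplets
are consumed by the analysis; the rest of each block is carried for
format completeness.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    DomainError,
    FormatError,
    ParseError,
    UnknownParticipantError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MANIPULATORS = ("master_left", "master_right", "slave_left", "slave_right")
EXERCISES = ("suturing", "knot_tying", "needle_passing")
SKILL_LEVELS = ("novice", "intermediate", "expert")

#: Ordinal coding used for rank correlation of skill with other scores.
SKILL_ORDINAL = {"novice": 1, "intermediate": 2, "expert": 3}

#: Self-declared skill of each dataset participant.
PARTICIPANT_SKILL = {
    "B": "novice",
    "G": "novice",
    "H": "novice",
    "I": "novice",
    "C": "intermediate",
    "F": "intermediate",
    "D": "expert",
    "E": "expert",
}

DEFAULT_SAMPLE_RATE_HZ = 30.0

_BLOCK_SIZE = 19  # 3 pos + 9 rot + 3 lin vel + 3 ang vel + 1 gripper

_EXERCISE_TOKENS = {
    "suturing": "suturing",
    "knot_tying": "knot_tying",
    "knottying": "knot_tying",
    "needle_passing": "needle_passing",
    "needlepassing": "needle_passing",
}

_SKILL_TOKENS = {
    "n": "novice",
    "i": "intermediate",
    "e": "expert",
    "novice": "novice",
    "intermediate": "intermediate",
    "expert": "expert",
}

_TRIAL_ID_RE = re.compile(
    r"^(?P<exercise>[A-Za-z_]+?)_(?P<participant>[A-Z])(?P<repetition>\d{3})$"
)


@dataclass(frozen=True)
class ColumnLayout:
    """Maps manipulator identifiers onto 19-column blocks of a 76-column row.

    ``manipulator_order`` gives the block order left to right; positions are
    the first three columns of each block.  The default follows the
    dataset's documented convention, but any permutation of the four ids
    can be supplied.
    """

    manipulator_order: tuple[str, ...] = MANIPULATORS
    block_size: int = _BLOCK_SIZE

    def __post_init__(self) -> None:
        if sorted(self.manipulator_order) != sorted(MANIPULATORS):
            raise ValidationError(
                "manipulator_order must be a permutation of "
                f"{MANIPULATORS}, got {self.manipulator_order}"
            )
        if self.block_size < 3:
            raise ValidationError("block_size must hold at least x, y, z")

    @property
    def n_columns(self) -> int:
        return self.block_size * len(self.manipulator_order)

    def position_columns(self, manipulator: str) -> slice:
        """Column slice holding (x, y, z) for one manipulator."""
        try:
            block = self.manipulator_order.index(manipulator)
        except ValueError:
            raise ValidationError(f"unknown manipulator {manipulator!r}") from None
        start = block * self.block_size
        return slice(start, start + 3)


DEFAULT_LAYOUT = ColumnLayout()


@dataclass
class KinematicStream:
    """Per-trial time series of 3-D tool-tip positions.

    ``positions`` maps manipulator id to an (n_samples, 3) float array in
    meters.  All manipulators share one sample clock.
    """

    positions: dict[str, np.ndarray]
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise DomainError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        counts = set()
        for name, arr in self.positions.items():
            if name not in MANIPULATORS:
                raise ValidationError(f"unknown manipulator {name!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(
                    f"{name}: positions must be (n, 3), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name}: non-finite coordinate")
            self.positions[name] = arr
            counts.add(arr.shape[0])
        if len(counts) > 1:
            raise ValidationError(f"manipulators disagree on sample count: {counts}")

    @property
    def manipulators(self) -> tuple[str, ...]:
        return tuple(self.positions)

    @property
    def n_samples(self) -> int:
        for arr in self.positions.values():
            return int(arr.shape[0])
        return 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(frozen=True)
class TrialRecord:
    """Identity plus observer scores for one trial.

    ``grs_items`` are the six 1-5 item scores of the global rating scale;
    ``grs_total`` is their sum (range 6-30).  Either may be absent.
    """

    exercise: str
    participant: str
    repetition: int
    skill_level: str
    grs_items: tuple[int, ...] | None = None
    grs_total: int | None = None

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValidationError(f"unknown exercise {self.exercise!r}")
        if self.participant not in PARTICIPANT_SKILL:
            raise UnknownParticipantError(f"unknown participant {self.participant!r}")
        if not 1 <= self.repetition <= 5:
            raise ValidationError(f"repetition must be 1-5, got {self.repetition}")
        if self.skill_level not in SKILL_LEVELS:
            raise ValidationError(f"unknown skill level {self.skill_level!r}")
        expected = PARTICIPANT_SKILL[self.participant]
        if self.skill_level != expected:
            raise ValidationError(
                f"participant {self.participant} is {expected}, "
                f"record says {self.skill_level}"
            )
        if self.grs_items is not None:
            if len(self.grs_items) != 6:
                raise ValidationError(
                    f"expected 6 GRS items, got {len(self.grs_items)}"
                )
            for v in self.grs_items:
                if not 1 <= v <= 5:
                    raise ValidationError(f"GRS item {v} outside 1-5")
            if self.grs_total is not None and self.grs_total != sum(self.grs_items):
                raise ValidationError(
                    f"grs_total {self.grs_total} != item sum {sum(self.grs_items)}"
                )
        if self.grs_total is not None and not 6 <= self.grs_total <= 30:
            raise ValidationError(f"grs_total {self.grs_total} outside 6-30")

    @property
    def trial_id(self) -> str:
        token = {
            "suturing": "Suturing",
            "knot_tying": "Knot_Tying",
            "needle_passing": "Needle_Passing",
        }[self.exercise]
        return f"{token}_{self.participant}{self.repetition:03d}"


def participant_skill(participant: str) -> str:
    """Self-declared skill level of a dataset participant (letters B-I)."""
    try:
        return PARTICIPANT_SKILL[participant]
    except KeyError:
        raise UnknownParticipantError(
            f"unknown participant {participant!r}; expected one of "
            f"{sorted(PARTICIPANT_SKILL)}"
        ) from None


def skill_from_hours(hours: float) -> str:
    """Classify robotic-experience hours: <10 novice, 10-100 intermediate
    (inclusive at both ends), >100 expert."""
    if hours < 0:
        raise DomainError(f"hours must be >= 0, got {hours}")
    if hours < 10:
        return "novice"
    if hours <= 100:
        return "intermediate"
    return "expert"


def parse_trial_id(stem: str) -> tuple[str, str, int]:
    """Split a trial identifier like ``Suturing_B001`` into
    (exercise, participant, repetition)."""
    m = _TRIAL_ID_RE.match(stem)
    if m is None:
        raise ParseError(f"cannot parse trial identifier {stem!r}")
    token = m.group("exercise").lower()
    if token not in _EXERCISE_TOKENS:
        raise ParseError(f"unknown exercise token {m.group('exercise')!r} in {stem!r}")
    return (
        _EXERCISE_TOKENS[token],
        m.group("participant"),
        int(m.group("repetition")),
    )


def read_kinematics(
    path: str | Path,
    layout: ColumnLayout = DEFAULT_LAYOUT,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> KinematicStream:
    """Read a 76-column kinematics file into a :class:`KinematicStream`.

    Every non-empty line must hold exactly ``layout.n_columns`` finite
    floats.  An empty file yields a valid 0-sample stream (with a warning).
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != layout.n_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected {layout.n_columns} columns, "
                    f"got {len(tokens)}"
                )
            try:
                row = np.array(tokens, dtype=float)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric token ({exc})") from None
            if not np.all(np.isfinite(row)):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            rows.append(row)
    if not rows:
        logger.warning("%s: empty kinematics file (0 samples)", path)
        data = np.empty((0, layout.n_columns))
    else:
        data = np.vstack(rows)
    positions = {
        m: np.ascontiguousarray(data[:, layout.position_columns(m)])
        for m in layout.manipulator_order
    }
    return KinematicStream(positions=positions, sample_rate_hz=sample_rate_hz)


def write_jigsaws_kinematics(
    stream: KinematicStream,
    path: str | Path,
    layout: ColumnLayout = DEFAULT_LAYOUT,
) -> None:
    """Write a stream in the 76-column dialect that :func:`read_kinematics`
    consumes.

    Position columns carry the stream data; the remaining 16 columns of
    each block are valid placeholders (identity rotation, finite-difference
    linear velocity, zero angular velocity and gripper angle).
    """
    n = stream.n_samples
    data = np.zeros((n, layout.n_columns))
    identity = np.eye(3).ravel()
    for manip in layout.manipulator_order:
        pos = stream.positions.get(manip)
        if pos is None:  # manipulator absent from stream: static at origin
            pos = np.zeros((n, 3))
        block = layout.manipulator_order.index(manip) * layout.block_size
        data[:, block : block + 3] = pos
        data[:, block + 3 : block + 12] = identity
        if n > 1:
            vel = np.gradient(pos, 1.0 / stream.sample_rate_hz, axis=0)
            data[:, block + 12 : block + 15] = vel
    np.savetxt(path, data, fmt="%.10g")


def read_meta(path: str | Path) -> list[TrialRecord]:
    """Read a trial metadata file into :class:`TrialRecord` objects.

    Each non-comment line holds a trial identifier (``Suturing_B001``,
    optionally with a file extension), an optional skill designator
    (``N``/``I``/``E`` or the full word) and GRS scores: either the six
    1-5 item scores, the total alone, or total followed by the six items.
    A declared skill letter that contradicts the participant mapping is a
    hard error.
    """
    path = Path(path)
    records: list[TrialRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            stem = tokens[0]
            for ext in (".txt", ".csv"):
                if stem.endswith(ext):
                    stem = stem[: -len(ext)]
            try:
                exercise, participant, repetition = parse_trial_id(stem)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None

            declared_skill: str | None = None
            ints: list[int] = []
            for tok in tokens[1:]:
                low = tok.lower()
                if low in _SKILL_TOKENS:
                    declared_skill = _SKILL_TOKENS[low]
                elif re.fullmatch(r"[+-]?\d+", tok):
                    ints.append(int(tok))
                elif re.fullmatch(r"[A-Z]\d{3}", tok):
                    continue  # redundant participant+repetition token
                else:
                    raise ParseError(f"{path}:{lineno}: unexpected token {tok!r}")

            skill = participant_skill(participant)
            if declared_skill is not None and declared_skill != skill:
                raise ValidationError(
                    f"{path}:{lineno}: declared skill {declared_skill!r} "
                    f"contradicts participant mapping ({skill!r})"
                )

            items: tuple[int, ...] | None = None
            total: int | None = None
            if len(ints) == 6:
                items = tuple(ints)
                total = sum(items)
            elif len(ints) == 7:
                total, items = ints[0], tuple(ints[1:])
            elif len(ints) == 1:
                total = ints[0]
            elif ints:
                raise ParseError(
                    f"{path}:{lineno}: expected 1, 6 or 7 GRS integers, "
                    f"got {len(ints)}"
                )
            try:
                records.append(
                    TrialRecord(
                        exercise=exercise,
                        participant=participant,
                        repetition=repetition,
                        skill_level=skill,
                        grs_items=items,
                        grs_total=total,
                    )
                )
            except (ValidationError, UnknownParticipantError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# interchange format: CSV body with a commented self-describing header
# ---------------------------------------------------------------------------

_INTERCHANGE_MAGIC = "surgmotion-interchange v1"


def write_interchange(
    stream: KinematicStream,
    trial: TrialRecord | None,
    path: str | Path,
) -> None:
    """Write a self-describing CSV that round-trips losslessly.

    Header lines (prefixed ``#``) carry the trial identity, sample rate and
    manipulator list; the body has one row per frame with one x,y,z triplet
    per manipulator at full float precision.
    """
    path = Path(path)
    manips = list(stream.positions)
    lines = [f"# {_INTERCHANGE_MAGIC}"]
    if trial is not None:
        lines.append(f"# exercise: {trial.exercise}")
        lines.append(f"# participant: {trial.participant}")
        lines.append(f"# repetition: {trial.repetition}")
        lines.append(f"# skill_level: {trial.skill_level}")
        if trial.grs_total is not None:
            lines.append(f"# grs_total: {trial.grs_total}")
        if trial.grs_items is not None:
            lines.append(f"# grs_items: {','.join(map(str, trial.grs_items))}")
    lines.append(f"# sample_rate_hz: {stream.sample_rate_hz!r}")
    lines.append(f"# manipulators: {','.join(manips)}")
    header = ["frame"] + [f"{m}_{ax}" for m in manips for ax in "xyz"]
    lines.append(",".join(header))
    for i in range(stream.n_samples):
        row = [str(i)]
        for m in manips:
            row.extend(format(v, ".17g") for v in stream.positions[m][i])
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_interchange(path: str | Path) -> tuple[KinematicStream, TrialRecord | None]:
    """Inverse of :func:`write_interchange`."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    with path.open() as fh:
        first = fh.readline().strip()
        if first != f"# {_INTERCHANGE_MAGIC}":
            raise FormatError(f"{path}: not a {_INTERCHANGE_MAGIC} file")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.append(line)
    if "manipulators" not in meta or "sample_rate_hz" not in meta:
        raise FormatError(f"{path}: missing header fields")
    manips = meta["manipulators"].split(",") if meta["manipulators"] else []
    rate = float(meta["sample_rate_hz"])
    rows = body[1:]  # body[0] is the column-name row
    n = len(rows)
    positions = {m: np.empty((n, 3)) for m in manips}
    for i, line in enumerate(rows):
        vals = line.split(",")
        if len(vals) != 1 + 3 * len(manips):
            raise FormatError(f"{path}: malformed body row {i}")
        for j, m in enumerate(manips):
            positions[m][i] = [float(v) for v in vals[1 + 3 * j : 4 + 3 * j]]
    stream = KinematicStream(positions=positions, sample_rate_hz=rate)

    trial: TrialRecord | None = None
    if "exercise" in meta:
        items = None
        if "grs_items" in meta:
            items = tuple(int(v) for v in meta["grs_items"].split(","))
        total = int(meta["grs_total"]) if "grs_total" in meta else None
        trial = TrialRecord(
            exercise=meta["exercise"],
            participant=meta["participant"],
            repetition=int(meta["repetition"]),
            skill_level=meta["skill_level"],
            grs_items=items,
            grs_total=total,
        )
    return stream, trial


# ---------------------------------------------------------------------------
# dataset discovery
# ---------------------------------------------------------------------------

_KINEMATICS_FILE_RE = re.compile(
    r"^(Suturing|Knot_Tying|Needle_Passing)_[B-I]\d{3}\.txt$", re.IGNORECASE
)


def find_trial_files(root: str | Path) -> dict[str, Path]:
    """Recursively locate kinematics files named like ``Suturing_B001.txt``.

    Returns a mapping from trial identifier (file stem) to path.  Files in
    transcription/annotation directories are ignored.
    """
    root = Path(root)
    out: dict[str, Path] = {}
    for p in sorted(root.rglob("*.txt")):
        if not _KINEMATICS_FILE_RE.match(p.name):
            continue
        if any(part.lower() in {"transcriptions", "video"} for part in p.parts):
            continue
        out.setdefault(p.stem, p)
    return out


def find_meta_files(root: str | Path) -> list[Path]:
    """Locate metadata files (``meta_file*.txt``) under ``root``."""
    root = Path(root)
    return sorted(p for p in root.rglob("meta_file*.txt") if p.is_file())


def load_dataset(
    root: str | Path,
    layout: ColumnLayout = DEFAULT_LAYOUT,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    strict: bool = False,
) -> tuple[dict[str, KinematicStream], list[TrialRecord], list[str]]:
    """Load every trial under ``root``.

    Returns (streams by trial id, trial records, skipped trial ids).
    Unreadable trials are skipped with a warning unless ``strict``.
    Records without a metadata entry are synthesised from the file name
    (identity + mapped skill, no GRS).
    """
    files = find_trial_files(root)
    if not files:
        raise FileNotFoundError(f"no kinematics files found under {root}")
    records_by_id: dict[str, TrialRecord] = {}
    for meta_path in find_meta_files(root):
        for rec in read_meta(meta_path):
            records_by_id[rec.trial_id] = rec

    streams: dict[str, KinematicStream] = {}
    records: list[TrialRecord] = []
    skipped: list[str] = []
    for trial_id, path in files.items():
        try:
            stream = read_kinematics(path, layout=layout, sample_rate_hz=sample_rate_hz)
        except (FormatError, ParseError) as exc:
            if strict:
                raise
            logger.warning("skipping corrupt trial %s: %s", trial_id, exc)
            skipped.append(trial_id)
            continue
        rec = records_by_id.get(trial_id)
        if rec is None:
            exercise, participant, repetition = parse_trial_id(trial_id)
            rec = TrialRecord(
                exercise=exercise,
                participant=participant,
                repetition=repetition,
                skill_level=participant_skill(participant),
            )
        streams[trial_id] = stream
        records.append(rec)
    return streams, records, skipped
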