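"""Raw tap-event trial logs: domain types, JSON (de)serialisation, integrity checks.

Every downstream biomarker is a function of the tap-event stream recorded
while a participant takes one of four memory test stages on a smartphone:

* ``verbal_immediate`` / ``verbal_delayed`` — paired-associates recall: ten
  cue words, each answered by selecting one of four options; an imperfect
  attempt triggers a repeat of the whole attempt.
* ``spatial_static`` / ``spatial_dynamic`` — checkerboard patterns of 4-8
  squares on a 4x4 grid, reproduced by tapping cells (the dynamic stage also
  requires the original serial order); a failed attempt repeats the same
  difficulty level, with at most five attempts in total.

Logs store every tap — selections *and* deselections — with integer
millisecond timestamps relative to trial start. Inter-tap intervals are
reported in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterator, Sequence, Union

__all__ = [
    "STAGES",
    "VERBAL_STAGES",
    "SPATIAL_STAGES",
    "DIAGNOSES",
    "TapEvent",
    "VerbalPair",
    "VerbalAttempt",
    "SpatialAttempt",
    "TrialRecord",
    "SubjectRecord",
    "IntegrityConfig",
    "LogParseError",
    "LogIntegrityError",
    "read_log",
    "write_log",
    "to_json_dict",
    "from_json_dict",
    "validate_trial",
    "inter_tap_intervals",
    "all_intervals",
    "read_subjects",
]

SCHEMA_VERSION = "1.0"

STAGES = ("verbal_immediate", "verbal_delayed", "spatial_static", "spatial_dynamic")
VERBAL_STAGES = ("verbal_immediate", "verbal_delayed")
SPATIAL_STAGES = ("spatial_static", "spatial_dynamic")

#: Diagnostic vocabulary. HD = healthy donor; NIND/OIND = non-inflammatory /
#: other inflammatory neurological disease; RIS/CIS = radiologically /
#: clinically isolated syndrome; RR/SP/PP-MS = relapsing-remitting /
#: secondary-progressive / primary-progressive multiple sclerosis.
DIAGNOSES = ("HD", "NIND", "OIND", "RIS", "CIS", "RR-MS", "SP-MS", "PP-MS")


class LogParseError(ValueError):
    """A trial log does not conform to the published schema."""


class LogIntegrityError(ValueError):
    """A trial log is schema-valid but violates a stream invariant."""


@dataclass(frozen=True)
class TapEvent:
    """One screen tap.

    Parameters
    ----------
    t : int
        Milliseconds since trial start; non-negative, non-decreasing within
        an attempt's event stream.
    action : str
        ``"select"`` or ``"deselect"``.
    target : int
        Grid cell index 0-15 (spatial) or option index 0-3 (verbal).
    correct : bool
        Whether the selection matches the expected answer. For deselect
        events this flags whether the removal was appropriate (i.e. the
        removed cell was wrong).
    """

    t: int
    action: str
    target: int
    correct: bool

    def __post_init__(self) -> None:
        if self.t < 0 or int(self.t) != self.t:
            raise LogIntegrityError(f"tap timestamp must be a non-negative integer, got {self.t!r}")
        if self.action not in ("select", "deselect"):
            raise LogParseError(f"unknown tap action {self.action!r}")


@dataclass(frozen=True)
class VerbalPair:
    """One cue word answered by choosing among four options."""

    cue: str
    options: tuple[str, str, str, str]
    chosen: str
    event: TapEvent

    def __post_init__(self) -> None:
        if len(self.options) != 4:
            raise LogParseError(f"cue {self.cue!r}: expected 4 options, got {len(self.options)}")
        if self.chosen not in self.options:
            raise LogParseError(f"cue {self.cue!r}: chosen option not among the 4 displayed")


@dataclass(frozen=True)
class VerbalAttempt:
    """One pass through all ten cue words; passed iff all ten correct."""

    pairs: tuple[VerbalPair, ...]

    N_PAIRS = 10

    def __post_init__(self) -> None:
        if len(self.pairs) != self.N_PAIRS:
            raise LogIntegrityError(
                f"verbal attempt must contain exactly {self.N_PAIRS} cue records, got {len(self.pairs)}"
            )
        _check_tap_stream(self.taps)

    @property
    def passed(self) -> bool:
        return all(p.event.correct for p in self.pairs)

    @property
    def taps(self) -> tuple[TapEvent, ...]:
        return tuple(p.event for p in self.pairs)


@dataclass(frozen=True)
class SpatialAttempt:
    """One reproduction attempt of a checkerboard pattern.

    ``pattern`` is the set of highlighted cells (|pattern| == level); every
    cell beyond the first touches at least one other pattern cell by edge or
    corner (Chebyshev distance 1). ``passed`` is stored rather than derived:
    correctness in the dynamic stage depends on serial order, which only the
    app (or the simulator) can adjudicate from the displayed sequence.
    """

    level: int
    pattern: frozenset[int]
    taps: tuple[TapEvent, ...]
    passed: bool

    def __post_init__(self) -> None:
        if not 4 <= self.level <= 8:
            raise LogIntegrityError(f"spatial level must be 4-8, got {self.level}")
        if len(self.pattern) != self.level:
            raise LogIntegrityError(
                f"pattern has {len(self.pattern)} cells but level is {self.level}"
            )
        if any(c < 0 or c > 15 for c in self.pattern):
            raise LogIntegrityError("pattern cells must lie on the 4x4 grid (0-15)")
        if not _pattern_connected(self.pattern):
            raise LogIntegrityError("pattern cells must be adjacent by at least a corner")
        for tap in self.taps:
            if not 0 <= tap.target <= 15:
                raise LogIntegrityError(f"tap target {tap.target} outside the 4x4 grid")
        _check_tap_stream(self.taps)


def _pattern_connected(pattern: frozenset[int]) -> bool:
    """Every cell (beyond the first) within Chebyshev distance 1 of another."""
    if len(pattern) <= 1:
        return True
    coords = {c: (c // 4, c % 4) for c in pattern}
    for c, (r, k) in coords.items():
        if not any(
            max(abs(r - r2), abs(k - k2)) == 1
            for c2, (r2, k2) in coords.items()
            if c2 != c
        ):
            return False
    return True


Attempt = Union[VerbalAttempt, SpatialAttempt]


@dataclass
class TrialRecord:
    """One administration of a test stage: ordered attempts of tap events."""

    subject_id: str
    stage: str
    session_time: datetime
    attempts: tuple[Attempt, ...]
    valid: bool = True
    reasons: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)

    MAX_SPATIAL_ATTEMPTS = 5

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise LogParseError(f"unknown stage {self.stage!r}")
        self.attempts = tuple(self.attempts)
        spatial = self.stage in SPATIAL_STAGES
        for a in self.attempts:
            if spatial and not isinstance(a, SpatialAttempt):
                raise LogParseError(f"stage {self.stage}: expected spatial attempts")
            if not spatial and not isinstance(a, VerbalAttempt):
                raise LogParseError(f"stage {self.stage}: expected verbal attempts")
        if spatial:
            if len(self.attempts) > self.MAX_SPATIAL_ATTEMPTS:
                raise LogIntegrityError(
                    f"spatial trials allow at most {self.MAX_SPATIAL_ATTEMPTS} attempts,"
                    f" got {len(self.attempts)}"
                )
            _check_level_progression(self.attempts)

    def iter_taps(self) -> Iterator[TapEvent]:
        for a in self.attempts:
            yield from a.taps


def _check_level_progression(attempts: Sequence[SpatialAttempt]) -> None:
    """Levels non-decreasing; a failed attempt is only followed by the same level."""
    for prev, nxt in zip(attempts, attempts[1:]):
        if nxt.level < prev.level:
            raise LogIntegrityError(
                f"attempt levels must be non-decreasing ({prev.level} -> {nxt.level})"
            )
        if not prev.passed and nxt.level != prev.level:
            raise LogIntegrityError(
                f"a failed level-{prev.level} attempt must be retried at the same level"
            )


def _check_tap_stream(taps: Sequence[TapEvent]) -> None:
    """Timestamps non-decreasing; deselect only after an open select of the target."""
    selected: set[int] = set()
    last_t = -1
    for tap in taps:
        if tap.t < last_t:
            raise LogIntegrityError(
                f"timestamp regression at t={tap.t} (previous {last_t})"
            )
        last_t = tap.t
        if tap.action == "select":
            selected.add(tap.target)
        else:
            if tap.target not in selected:
                raise LogIntegrityError(
                    f"deselect of target {tap.target} without a prior select"
                )
            selected.discard(tap.target)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata: diagnosis group and optional clinical anchors."""

    subject_id: str
    diagnosis: str
    age: float
    sdmt: float | None = None
    edss: float | None = None
    neurex: float | None = None
    fss7: float | None = None
    neurex1: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")


# ---------------------------------------------------------------------------
# Integrity checks (trial-level exclusion; no subject-level imputation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrityConfig:
    """Thresholds for trial-level integrity screening.

    Defaults: a per-interval floor of 150 ms (anticipatory tapping), a
    per-interval ceiling of 300 s (abandonment mid-trial), and a total trial
    duration cap of 30 min.
    """

    interval_floor_s: float = 0.150
    interval_ceiling_s: float = 300.0
    max_duration_s: float = 1800.0
    min_duration_s: float = 0.0


def validate_trial(trial: TrialRecord, rules: IntegrityConfig = IntegrityConfig()) -> TrialRecord:
    """Screen a parsed trial against integrity rules.

    Returns a copy with ``valid`` and machine-readable ``reasons`` set.
    This is a verdict, never an exception: structurally broken logs are
    rejected earlier, at parse time.
    """
    reasons: list[str] = []
    if not trial.attempts:
        reasons.append("missing data: no attempts recorded")
    taps = list(trial.iter_taps())
    if taps:
        duration = (taps[-1].t - taps[0].t) / 1000.0
        if duration > rules.max_duration_s or duration < rules.min_duration_s:
            reasons.append(f"completion time: trial duration {duration:.1f}s outside bounds")
    for intervals in inter_tap_intervals(trial):
        for dt in intervals:
            if dt < rules.interval_floor_s:
                reasons.append(f"completion time: inter-tap interval {dt:.3f}s below floor")
                break
            if dt > rules.interval_ceiling_s:
                reasons.append(f"completion time: inter-tap interval {dt:.1f}s above ceiling")
                break
    return replace(trial, valid=not reasons, reasons=tuple(reasons))


def inter_tap_intervals(trial: TrialRecord) -> list[list[float]]:
    """Consecutive inter-tap intervals, in seconds, one list per attempt.

    The interval stream includes *all* tap events (selections and
    deselections) and starts at the first tap — the latency from stimulus
    onset to the first tap is not part of the stream. Attempts with fewer
    than two taps contribute an empty list.
    """
    out: list[list[float]] = []
    for attempt in trial.attempts:
        taps = attempt.taps
        out.append([(b.t - a.t) / 1000.0 for a, b in zip(taps, taps[1:])])
    return out


def all_intervals(trial: TrialRecord) -> list[float]:
    """All inter-tap intervals of a trial, pooled across attempts."""
    return [dt for intervals in inter_tap_intervals(trial) for dt in intervals]


# ---------------------------------------------------------------------------
# JSON serialisation — canonical, byte-stable
# ---------------------------------------------------------------------------

def _event_to_dict(e: TapEvent) -> dict:
    return {"t": e.t, "action": e.action, "target": e.target, "correct": e.correct}


def _event_from_dict(d: dict, where: str) -> TapEvent:
    for key in ("t", "action", "target", "correct"):
        if key not in d:
            raise LogParseError(f"{where}: event missing field {key!r}")
    return TapEvent(t=d["t"], action=d["action"], target=d["target"], correct=d["correct"])


def to_json_dict(trial: TrialRecord) -> dict:
    attempts = []
    for a in trial.attempts:
        if isinstance(a, SpatialAttempt):
            attempts.append(
                {
                    "level": a.level,
                    "pattern": sorted(a.pattern),
                    "passed": a.passed,
                    "events": [_event_to_dict(e) for e in a.taps],
                }
            )
        else:
            attempts.append(
                {
                    "pairs": [
                        {
                            "cue": p.cue,
                            "options": list(p.options),
                            "chosen": p.chosen,
                            "event": _event_to_dict(p.event),
                        }
                        for p in a.pairs
                    ]
                }
            )
    d = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": trial.subject_id,
        "stage": trial.stage,
        "session_time": trial.session_time.isoformat(),
        "attempts": attempts,
    }
    d.update(trial.extras)
    return d


def from_json_dict(d: dict) -> TrialRecord:
    known = {"schema_version", "subject_id", "stage", "session_time", "attempts"}
    for key in ("subject_id", "stage", "session_time", "attempts"):
        if key not in d:
            raise LogParseError(f"trial log missing field {key!r}")
    stage = d["stage"]
    if stage not in STAGES:
        raise LogParseError(f"field 'stage': unknown value {stage!r}")
    try:
        session_time = datetime.fromisoformat(d["session_time"])
    except (TypeError, ValueError) as exc:
        raise LogParseError(f"field 'session_time': not ISO-8601 ({exc})") from None
    attempts: list[Attempt] = []
    for i, a in enumerate(d["attempts"]):
        where = f"attempts[{i}]"
        if stage in SPATIAL_STAGES:
            for key in ("level", "pattern", "passed", "events"):
                if key not in a:
                    raise LogParseError(f"{where}: spatial attempt missing field {key!r}")
            attempts.append(
                SpatialAttempt(
                    level=a["level"],
                    pattern=frozenset(a["pattern"]),
                    taps=tuple(_event_from_dict(e, where) for e in a["events"]),
                    passed=a["passed"],
                )
            )
        else:
            if "pairs" not in a:
                raise LogParseError(f"{where}: verbal attempt missing field 'pairs'")
            pairs = tuple(
                VerbalPair(
                    cue=p["cue"],
                    options=tuple(p["options"]),
                    chosen=p["chosen"],
                    event=_event_from_dict(p["event"], where),
                )
                for p in a["pairs"]
            )
            attempts.append(VerbalAttempt(pairs=pairs))
    extras = {k: v for k, v in d.items() if k not in known}
    return TrialRecord(
        subject_id=d["subject_id"],
        stage=stage,
        session_time=session_time,
        attempts=tuple(attempts),
        extras=extras,
    )


def write_log(trial: TrialRecord, path: str | Path) -> None:
    """Write a trial to canonical JSON (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(to_json_dict(trial), sort_keys=True, separators=(",", ":")) + "\n"
    )


def read_log(path: str | Path) -> TrialRecord:
    """Read and structurally validate one trial-log JSON file.

    Unknown top-level fields are preserved in ``TrialRecord.extras``.
    Schema violations raise :class:`LogParseError` naming the offending
    field; stream-invariant violations raise :class:`LogIntegrityError`.
    """
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LogParseError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(d, dict):
        raise LogParseError(f"{path}: trial log must be a JSON object")
    return from_json_dict(d)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read the subject metadata CSV (empty cells = missing)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "diagnosis", "age"}
    missing = required - set(df.columns)
    if missing:
        raise LogParseError(f"subject metadata missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in ("sdmt", "edss", "neurex", "fss7", "neurex1"):
            v = getattr(row, col, None)
            kwargs[col] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        out.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                diagnosis=row.diagnosis,
                age=float(row.age),
                **kwargs,
            )
        )
    return out
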