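"""Synthetic cohort generator for the memory-test pipeline.

Each simulated participant carries a latent profile with the ingredients the
biomarker layer is designed to recover:

* ``motor_floor`` — the subject's minimal sensory-motor inter-tap interval.
  Observed intervals are ``motor_floor + cognitive demand + Exp(jitter)``
  (a shifted exponential), so the per-trial minimum interval converges to
  the floor as taps accumulate — exactly the premise behind iSMPT.
* ``cog_latency_scale`` — seconds of extra latency per unit cognitive
  demand; demand grows with pattern level and doubles in the dynamic stage.
* ``memory_capacity`` — location of a logistic pass/fail curve over pattern
  level, and (via a logistic link) the per-cue verbal accuracy.
* ``lapse_rate`` and ``self_correct_prob`` — random per-item errors and the
  probability that an erroneous square tap is noticed and deselected
  (feeding the self-correction mistake count).

Group presets encode an ordered impairment gradient, healthy donors <
relapsing-remitting MS < progressive MS, on both the timing and the
capacity parameters, and the simulated SDMT score is a noisy negative
linear function of the slowing latents — so the composite-model, QC and
reliability layers all see the structure they assume, at effect sizes a
memory clinic would consider plausible rather than generous.

Everything is deterministic given (config, seed): per-subject generators
are spawned from one root ``numpy`` SeedSequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import (
    SpatialAttempt,
    TapEvent,
    TrialRecord,
    VerbalAttempt,
    VerbalPair,
    write_log,
)

__all__ = [
    "LatentProfile",
    "GroupSpec",
    "SimConfig",
    "SDMTLink",
    "DEFAULT_GROUPS",
    "sample_cohort",
    "simulate_spatial_session",
    "simulate_verbal_session",
    "simulate_session",
    "simulate_sdmt",
    "generate_dataset",
    "random_pattern",
    "build_spatial_trial",
]


@dataclass(frozen=True)
class LatentProfile:
    """Latent trait vector of one simulated subject."""

    motor_floor: float          # seconds; > 0
    motor_jitter: float         # rate of the shifted-exponential noise (1/s)
    cog_latency_scale: float    # seconds per unit cognitive demand
    memory_capacity: float      # logistic location on the 4-8 level axis
    lapse_rate: float           # per-item probability of a random error
    self_correct_prob: float    # probability an error is deselected

    def __post_init__(self) -> None:
        if not self.motor_floor > 0:
            raise ValueError("motor_floor must be positive")
        for name in ("lapse_rate", "self_correct_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class GroupSpec:
    """Population of one diagnostic group: latent means, SDs, size, ages."""

    label: str
    n: int
    means: LatentProfile
    sds: dict = field(default_factory=dict)   # per-field between-subject SD
    age_range: tuple[float, float] = (20.0, 75.0)


@dataclass(frozen=True)
class SDMTLink:
    """SDMT = intercept − b_cog·cog_latency_scale − b_motor·motor_floor + noise."""

    intercept: float = 78.0
    b_cog: float = 22.0
    b_motor: float = 40.0
    noise_sd: float = 7.0
    bounds: tuple[float, float] = (0.0, 110.0)


# Ordered impairment gradient HD < RR-MS < P-MS on floor, cognitive latency
# and capacity; non-MS comparison groups sit between HD and RR-MS.
_BASE_SDS = {
    "motor_floor": 0.07,
    "motor_jitter": 0.4,
    "cog_latency_scale": 0.22,
    "memory_capacity": 0.9,
    "lapse_rate": 0.02,
    "self_correct_prob": 0.1,
}

DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec(
        "HD", 40,
        LatentProfile(0.30, 3.0, 0.55, 7.0, 0.03, 0.35),
        dict(_BASE_SDS), (20.0, 70.0),
    ),
    GroupSpec(
        "RR-MS", 80,
        LatentProfile(0.42, 2.6, 0.85, 6.0, 0.06, 0.35),
        dict(_BASE_SDS), (22.0, 72.0),
    ),
    GroupSpec(
        "SP-MS", 30,
        LatentProfile(0.58, 2.2, 1.25, 5.0, 0.10, 0.35),
        dict(_BASE_SDS), (30.0, 78.0),
    ),
    GroupSpec(
        "PP-MS", 30,
        LatentProfile(0.58, 2.2, 1.25, 5.0, 0.10, 0.35),
        dict(_BASE_SDS), (30.0, 78.0),
    ),
    GroupSpec(
        "NIND", 20,
        LatentProfile(0.38, 2.8, 0.70, 6.4, 0.05, 0.35),
        dict(_BASE_SDS), (22.0, 75.0),
    ),
    GroupSpec(
        "OIND", 20,
        LatentProfile(0.40, 2.7, 0.75, 6.2, 0.05, 0.35),
        dict(_BASE_SDS), (22.0, 75.0),
    ),
)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic study; (config, seed) fixes the output."""

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    seed: int = 0
    sessions_per_subject: int = 1
    drift_sd: float = 0.08     # session-to-session jitter on cog_latency_scale
    sdmt_link: SDMTLink = SDMTLink()
    start_time: datetime = datetime(2023, 1, 2, 9, 0)
    session_interval_days: float = 7.0


# ---------------------------------------------------------------------------
# Latent sampling
# ---------------------------------------------------------------------------

_PROFILE_FIELDS = (
    "motor_floor", "motor_jitter", "cog_latency_scale",
    "memory_capacity", "lapse_rate", "self_correct_prob",
)

# hard floors keeping sampled profiles physically meaningful
_FIELD_MIN = {
    "motor_floor": 0.12,
    "motor_jitter": 0.5,
    "cog_latency_scale": 0.05,
    "memory_capacity": 2.0,
    "lapse_rate": 0.0,
    "self_correct_prob": 0.0,
}


def _sample_profile(spec: GroupSpec, rng: np.random.Generator) -> LatentProfile:
    values = {}
    for name in _PROFILE_FIELDS:
        mu = getattr(spec.means, name)
        sd = spec.sds.get(name, 0.0)
        v = mu + sd * rng.standard_normal() if sd > 0 else mu
        v = max(v, _FIELD_MIN[name])
        if name in ("lapse_rate", "self_correct_prob"):
            v = min(v, 1.0)
        values[name] = float(v)
    return LatentProfile(**values)


def sample_cohort(config: SimConfig) -> tuple[pd.DataFrame, dict[str, LatentProfile]]:
    """Draw subjects and their latent profiles for every group.

    Returns a subject metadata table (subject_id, diagnosis, age, sdmt) and
    the latent-truth map — the latter is for recovery tests only and is
    never visible to the analysis pipeline.
    """
    root = np.random.SeedSequence(config.seed)
    subjects = []
    profiles: dict[str, LatentProfile] = {}
    group_seeds = root.spawn(len(config.groups))
    for spec, gseed in zip(config.groups, group_seeds):
        if spec.n == 0:
            continue
        rng = np.random.default_rng(gseed)
        for i in range(spec.n):
            sid = f"{spec.label}-{i:03d}"
            prof = _sample_profile(spec, rng)
            age = float(rng.uniform(*spec.age_range))
            sdmt = simulate_sdmt(prof, config.sdmt_link, rng)
            profiles[sid] = prof
            subjects.append(
                {"subject_id": sid, "diagnosis": spec.label, "age": age, "sdmt": sdmt}
            )
    return pd.DataFrame(subjects), profiles


def simulate_sdmt(
    profile: LatentProfile, link: SDMTLink, rng: np.random.Generator
) -> float:
    """Symbol Digit Modalities Test score linked to the slowing latents."""
    raw = (
        link.intercept
        - link.b_cog * profile.cog_latency_scale
        - link.b_motor * profile.motor_floor
        + link.noise_sd * rng.standard_normal()
    )
    return float(np.clip(raw, *link.bounds))


# ---------------------------------------------------------------------------
# Tap-stream machinery
# ---------------------------------------------------------------------------

#: Fraction of taps that are cognitively trivial (immediate confirmations,
#: reflexive responses). These carry no cognitive latency, so the minimum
#: inter-tap interval of a trial converges to the motor floor as taps
#: accumulate — the premise that gives iSMPT its interpretation.
EASY_TAP_PROB = 0.3


class _TapClock:
    """Accumulates shifted-exponential inter-tap intervals as integer ms."""

    def __init__(self, profile: LatentProfile, rng: np.random.Generator) -> None:
        self.profile = profile
        self.rng = rng
        self.t_ms = 0

    def tick(self, demand: float) -> int:
        if self.rng.random() < EASY_TAP_PROB:
            demand = 0.0
        dt = (
            self.profile.motor_floor
            + self.profile.cog_latency_scale * demand
            + self.rng.exponential(1.0 / self.profile.motor_jitter)
        )
        self.t_ms += max(1, int(round(dt * 1000)))
        return self.t_ms


def build_spatial_trial(
    stage: str,
    attempts: Sequence[tuple[int, bool, int]],
    subject_id: str = "fixture",
    self_corrections: int = 0,
    interval_ms: int = 800,
    session_time: datetime = datetime(2023, 1, 2, 9, 0),
) -> TrialRecord:
    """Deterministically construct a spatial trial from an attempt plan.

    ``attempts`` is a sequence of ``(level, passed, n_incorrect_taps)``
    tuples; taps are laid out on a fixed clock with ``interval_ms`` between
    events. The first ``self_corrections`` incorrect taps of each attempt
    are followed by a deselect of the same cell. Pattern cells are a
    contiguous row-major block (always corner-adjacent).
    """
    t = 0
    built: list[SpatialAttempt] = []
    for level, passed, n_wrong in attempts:
        pattern = frozenset(range(level))
        taps: list[TapEvent] = []
        n_correct = level if passed else max(0, level - n_wrong)
        for c in sorted(pattern)[:n_correct]:
            t += interval_ms
            taps.append(TapEvent(t, "select", c, True))
        wrong_cells = [c for c in range(15, -1, -1) if c not in pattern]
        for j in range(0 if passed else n_wrong):
            cell = wrong_cells[j % len(wrong_cells)]
            t += interval_ms
            taps.append(TapEvent(t, "select", cell, False))
            if j < self_corrections:
                t += interval_ms
                taps.append(TapEvent(t, "deselect", cell, True))
        built.append(SpatialAttempt(level=level, pattern=pattern, taps=tuple(taps), passed=passed))
    return TrialRecord(subject_id=subject_id, stage=stage,
                       session_time=session_time, attempts=tuple(built))


def random_pattern(level: int, rng: np.random.Generator) -> frozenset[int]:
    """Checkerboard pattern of ``level`` cells on the 4x4 grid, grown by
    corner-adjacent accretion: each new cell is within Chebyshev distance 1
    of the current pattern."""
    cells = {int(rng.integers(16))}
    while len(cells) < level:
        frontier = set()
        for c in cells:
            r, k = divmod(c, 4)
            for dr in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    r2, k2 = r + dr, k + dk
                    if 0 <= r2 < 4 and 0 <= k2 < 4:
                        frontier.add(r2 * 4 + k2)
        frontier -= cells
        cells.add(int(rng.choice(sorted(frontier))))
    return frozenset(cells)


def _pass_probability(profile: LatentProfile, level: int) -> float:
    # logistic in (capacity − level); slope 1.3 gives a sharp but not
    # step-like difficulty gradient over the 4-8 range
    return 1.0 / (1.0 + math.exp(-1.3 * (profile.memory_capacity - level)))


def _spatial_attempt(
    profile: LatentProfile,
    level: int,
    clock: _TapClock,
    rng: np.random.Generator,
    demand: float,
) -> SpatialAttempt:
    pattern = random_pattern(level, rng)
    p_pass = _pass_probability(profile, level) * (1 - profile.lapse_rate) ** level
    passed = bool(rng.random() < p_pass)
    taps: list[TapEvent] = []
    cells = sorted(pattern)
    non_pattern = [c for c in range(16) if c not in pattern]
    if passed:
        order = rng.permutation(len(cells))
        for idx in order:
            taps.append(TapEvent(clock.tick(demand), "select", cells[int(idx)], True))
    else:
        # number of erroneous taps grows with how far the level exceeds capacity
        excess = max(0.0, level - profile.memory_capacity)
        n_mistakes = 1 + int(rng.poisson(0.8 * excess + 0.3))
        n_correct = max(0, level - n_mistakes)
        plan = [True] * n_correct + [False] * n_mistakes
        rng.shuffle(plan)
        correct_iter = iter(rng.permutation(cells))
        for is_correct in plan:
            if is_correct:
                taps.append(TapEvent(clock.tick(demand), "select", int(next(correct_iter)), True))
            else:
                wrong = int(rng.choice(non_pattern)) if non_pattern else int(rng.integers(16))
                taps.append(TapEvent(clock.tick(demand), "select", wrong, False))
                if rng.random() < profile.self_correct_prob:
                    taps.append(TapEvent(clock.tick(0.3 * demand), "deselect", wrong, True))
    return SpatialAttempt(level=level, pattern=pattern, taps=tuple(taps), passed=passed)


def simulate_spatial_session(
    profile: LatentProfile,
    stage: str,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    session_time: datetime = datetime(2023, 1, 2, 9, 0),
) -> TrialRecord:
    """One spatial trial: levels 4-8, failed levels repeated, 5 attempts max.

    The dynamic stage doubles the per-tap cognitive demand (serial-order
    encoding) — its correctness bookkeeping is already folded into the
    pass/fail draw and the per-tap correct flags.
    """
    if stage not in ("spatial_static", "spatial_dynamic"):
        raise ValueError(f"stage must be spatial_static or spatial_dynamic, got {stage!r}")
    rng = np.random.default_rng(seed)
    clock = _TapClock(profile, rng)
    demand_scale = 2.0 if stage == "spatial_dynamic" else 1.0
    attempts: list[SpatialAttempt] = []
    level = 4
    while len(attempts) < TrialRecord.MAX_SPATIAL_ATTEMPTS and level <= 8:
        demand = demand_scale * (0.4 + 0.08 * level)
        attempt = _spatial_attempt(profile, level, clock, rng, demand)
        attempts.append(attempt)
        if attempt.passed:
            level += 1
    return TrialRecord(
        subject_id=subject_id,
        stage=stage,
        session_time=session_time,
        attempts=tuple(attempts),
    )


def _verbal_accuracy(profile: LatentProfile, delayed: bool) -> float:
    # per-cue accuracy via logistic link on capacity; consolidation loss
    # attenuates delayed recall toward the 1/4 guessing floor
    base = 1.0 / (1.0 + math.exp(-(profile.memory_capacity - 4.0)))
    p = 0.25 + 0.75 * base
    if delayed:
        p = 0.25 + 0.85 * (p - 0.25)
    return p * (1 - profile.lapse_rate)


def simulate_verbal_session(
    profile: LatentProfile,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    session_time: datetime = datetime(2023, 1, 2, 9, 0),
    max_attempts: int = 5,
) -> tuple[TrialRecord, TrialRecord]:
    """Immediate and delayed verbal recall trials for one session.

    Ten cue words per attempt; any error triggers a repeat attempt (capped
    at ``max_attempts``). Cues and options are opaque ids.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for stage, delayed in (("verbal_immediate", False), ("verbal_delayed", True)):
        p_correct = _verbal_accuracy(profile, delayed)
        clock = _TapClock(profile, rng)
        attempts: list[VerbalAttempt] = []
        while len(attempts) < max_attempts:
            pairs = []
            for j in range(VerbalAttempt.N_PAIRS):
                options = tuple(f"w{j}_{k}" for k in range(4))
                correct = bool(rng.random() < p_correct)
                chosen = options[0] if correct else options[int(rng.integers(1, 4))]
                ev = TapEvent(clock.tick(1.0), "select", options.index(chosen), correct)
                pairs.append(VerbalPair(cue=f"cue{j}", options=options, chosen=chosen, event=ev))
            attempt = VerbalAttempt(pairs=tuple(pairs))
            attempts.append(attempt)
            if attempt.passed:
                break
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                stage=stage,
                session_time=session_time if not delayed else session_time + timedelta(minutes=20),
                attempts=tuple(attempts),
            )
        )
    return trials[0], trials[1]


def simulate_session(
    profile: LatentProfile,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sim",
    session_time: datetime = datetime(2023, 1, 2, 9, 0),
) -> dict[str, TrialRecord]:
    """All four stage trials of one session, keyed by stage name."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_verbal, s_static, s_dynamic = ss.spawn(3)
    imm, dly = simulate_verbal_session(profile, s_verbal, subject_id, session_time)
    static = simulate_spatial_session(profile, "spatial_static", s_static, subject_id, session_time)
    dynamic = simulate_spatial_session(profile, "spatial_dynamic", s_dynamic, subject_id, session_time)
    return {
        "verbal_immediate": imm,
        "verbal_delayed": dly,
        "spatial_static": static,
        "spatial_dynamic": dynamic,
    }


def generate_dataset(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[dict[str, TrialRecord]], dict[str, LatentProfile]]:
    """Simulate a full study: subjects, per-session stage trials, latent truth.

    Session-to-session variation perturbs ``cog_latency_scale`` with
    independent Gaussian jitter (``drift_sd``). When ``out_dir`` is given,
    trial logs are written as one canonical JSON file per trial alongside a
    ``subjects.csv`` and a clearly marked ``latent_truth.csv``.
    """
    subjects, profiles = sample_cohort(config)
    root = np.random.SeedSequence((config.seed, 1))
    seeds = iter(root.spawn(len(subjects) * config.sessions_per_subject))
    sessions: list[dict[str, TrialRecord]] = []
    for row in subjects.itertuples(index=False):
        prof = profiles[row.subject_id]
        for k in range(config.sessions_per_subject):
            ss = next(seeds)
            if config.drift_sd > 0 and config.sessions_per_subject > 1:
                jitter_rng = np.random.default_rng(ss.spawn(1)[0])
                drifted = max(
                    _FIELD_MIN["cog_latency_scale"],
                    prof.cog_latency_scale + config.drift_sd * jitter_rng.standard_normal(),
                )
                use_prof = replace(prof, cog_latency_scale=drifted)
            else:
                use_prof = prof
            when = config.start_time + timedelta(days=config.session_interval_days * k)
            sessions.append(simulate_session(use_prof, ss, row.subject_id, when))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        subjects.to_csv(out / "subjects.csv", index=False)
        truth = pd.DataFrame(
            [{"subject_id": sid, **prof.__dict__} for sid, prof in profiles.items()]
        )
        # latent truth is simulator bookkeeping for recovery tests only
        truth.to_csv(out / "latent_truth.csv", index=False)
        for i, session in enumerate(sessions):
            for stage, trial in session.items():
                write_log(trial, out / f"{trial.subject_id}_s{i:04d}_{stage}.json")
    return subjects, sessions, profiles
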