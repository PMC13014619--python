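"""The fourteen digital biomarkers derived from tap-event trial logs.

Three families of metrics are computed per trial:

* **Timing** — the individualized sensory-motor processing threshold
  (iSMPT), defined as the minimum inter-tap interval of the trial,
  ``iSMPT_i = min(dt_i1, ..., dt_in)``; and the adjusted recall latency
  (RLa) = mean inter-tap interval − iSMPT, which removes the
  subject-specific motor floor and isolates cognitive slowing.
* **Accuracy** — verbal/spatial recall impairment (VRI/SRI): accuracy
  inverted (higher = more impaired) and log10-transformed, with a +1 shift
  inside the log so perfect performance maps to exactly 0. The spatial raw
  score uses partial credit: a failed level earns its square count minus the
  mean number of incorrect taps across its attempts (double-weighted in the
  dynamic stage), floored at 0.
* **Self-corrections** — spatial recall mistakes (SRM): the log10(+1) count
  of select-then-deselect events per stage.

With four stages (verbal immediate/delayed, spatial static/dynamic) this
yields 4 iSMPT + 4 latency + 4 impairment + 2 mistake biomarkers = 14.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dc_fields
from datetime import datetime
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .events import (
    SPATIAL_STAGES,
    SpatialAttempt,
    TrialRecord,
    all_intervals,
)

__all__ = [
    "BIOMARKER_NAMES",
    "SPATIAL_BIOMARKERS",
    "VERBAL_BIOMARKERS",
    "BiomarkerVector",
    "ismpt",
    "adjusted_latency",
    "verbal_recall_impairment",
    "static_partial_credit",
    "dynamic_partial_credit",
    "spatial_recall_impairment",
    "spatial_recall_mistakes",
    "biomarker_vector",
    "biomarker_table",
    "quadrant_stratify",
]

BIOMARKER_NAMES = (
    "iSMPT_V_imm",
    "iSMPT_V_del",
    "iSMPT_S_static",
    "iSMPT_S_dynamic",
    "ImmVRLa",
    "DelVRLa",
    "StaticSRLa",
    "DynamicSRLa",
    "ImmVRI",
    "DelVRI",
    "StaticSRI",
    "DynamicSRI",
    "StaticSRM",
    "DynamicSRM",
)

#: The eight spatial biomarkers (candidate predictors of SDMT).
SPATIAL_BIOMARKERS = (
    "iSMPT_S_static",
    "iSMPT_S_dynamic",
    "StaticSRLa",
    "DynamicSRLa",
    "StaticSRI",
    "DynamicSRI",
    "StaticSRM",
    "DynamicSRM",
)

VERBAL_BIOMARKERS = ("iSMPT_V_imm", "iSMPT_V_del", "ImmVRLa", "DelVRLa", "ImmVRI", "DelVRI")

STATIC_LEVELS = (4, 5, 6, 7, 8)
STATIC_MAX = sum(STATIC_LEVELS)          # 30
DYNAMIC_MAX = sum(2 * n for n in STATIC_LEVELS)  # 60

_STAGE_FIELDS = {
    "verbal_immediate": ("iSMPT_V_imm", "ImmVRLa", "ImmVRI", None),
    "verbal_delayed": ("iSMPT_V_del", "DelVRLa", "DelVRI", None),
    "spatial_static": ("iSMPT_S_static", "StaticSRLa", "StaticSRI", "StaticSRM"),
    "spatial_dynamic": ("iSMPT_S_dynamic", "DynamicSRLa", "DynamicSRI", "DynamicSRM"),
}


def ismpt(trial: TrialRecord) -> float:
    """Individualized sensory-motor processing threshold of one trial.

    The minimum over all inter-tap intervals of all attempts, interpreted as
    the subject's fastest (cognitively least demanding) response. Returns
    NaN when no attempt has two or more taps.
    """
    intervals = all_intervals(trial)
    if not intervals:
        return math.nan
    return min(intervals)


def adjusted_latency(trial: TrialRecord) -> float:
    """Adjusted recall latency: mean inter-tap interval minus trial iSMPT.

    Equals the mean of per-interval excesses over the motor floor, hence is
    non-negative by construction. A constant added to every interval shifts
    the minimum by the same amount and leaves this quantity unchanged — the
    decomposition that separates motor slowing from cognitive slowing.
    """
    intervals = all_intervals(trial)
    if not intervals:
        return math.nan
    return float(np.mean(intervals)) - min(intervals)


def verbal_recall_impairment(trial: TrialRecord) -> float:
    """VRI of a verbal trial from its first attempt.

    ``pct = 100 * correct / attempted``; VRI = log10(100 − pct + 1), so a
    perfect 10/10 maps to 0. Only the first attempt counts: repeats exist
    only after errors and would dilute the accuracy estimate.
    """
    if not trial.attempts:
        return math.nan
    first = trial.attempts[0]
    attempted = len(first.pairs)
    if attempted == 0:
        return math.nan
    pct = 100.0 * sum(p.event.correct for p in first.pairs) / attempted
    return math.log10(100.0 - pct + 1.0)


def _incorrect_selects(attempt: SpatialAttempt) -> int:
    return sum(1 for t in attempt.taps if t.action == "select" and not t.correct)


def _partial_credit(trial: TrialRecord, weight: int, max_score: int) -> float:
    """Shared partial-credit machinery for the two spatial stages.

    Passed levels earn ``weight * level`` points. The highest level that was
    failed and never passed earns ``weight * level − weight * mean(incorrect
    taps per attempt at that level)``, floored at 0.
    """
    if not trial.attempts:
        return math.nan
    passed_levels: set[int] = set()
    failed: dict[int, list[int]] = {}
    for a in trial.attempts:
        if a.passed:
            passed_levels.add(a.level)
        else:
            failed.setdefault(a.level, []).append(_incorrect_selects(a))
    score = float(sum(weight * lvl for lvl in passed_levels))
    open_failures = [lvl for lvl in failed if lvl not in passed_levels]
    if open_failures:
        lvl = max(open_failures)
        mean_mistakes = float(np.mean(failed[lvl]))
        score += max(0.0, weight * lvl - weight * mean_mistakes)
    return min(score, float(max_score))


def static_partial_credit(trial: TrialRecord) -> float:
    """Raw static spatial score with partial credit, 0-30.

    Example: pass levels 4 and 5, then fail level 6 twice with 3 and 1
    incorrect taps → 4 + 5 + (6 − 2) = 13. A flawless run scores 30
    (4+5+6+7+8).
    """
    if trial.stage != "spatial_static":
        raise ValueError(f"expected a spatial_static trial, got stage {trial.stage!r}")
    return _partial_credit(trial, weight=1, max_score=STATIC_MAX)


def dynamic_partial_credit(trial: TrialRecord) -> float:
    """Raw dynamic spatial score with double-weighted partial credit, 0-60.

    Each level's tile count carries double weight (level 6 is worth 12
    points; an average of 2 mistakes leaves 12 − 2×2 = 8). Correctness in
    this stage requires both the right cell and the right serial position.
    """
    if trial.stage != "spatial_dynamic":
        raise ValueError(f"expected a spatial_dynamic trial, got stage {trial.stage!r}")
    return _partial_credit(trial, weight=2, max_score=DYNAMIC_MAX)


def spatial_recall_impairment(raw: float, max_score: float) -> float:
    """SRI = log10(max − raw + 1): 0 when flawless, monotone in impairment."""
    if math.isnan(raw):
        return math.nan
    if not 0 <= raw <= max_score:
        raise ValueError(f"raw score {raw} outside [0, {max_score}]")
    return math.log10(max_score - raw + 1.0)


def spatial_recall_mistakes(trial: TrialRecord) -> float:
    """SRM = log10(count + 1) of self-corrected errors over the stage.

    A self-corrected error is an incorrect square that was selected and
    later deselected within the same attempt.
    """
    if trial.stage not in SPATIAL_STAGES:
        raise ValueError(f"expected a spatial trial, got stage {trial.stage!r}")
    count = 0
    for attempt in trial.attempts:
        wrong_open: set[int] = set()
        for tap in attempt.taps:
            if tap.action == "select":
                if not tap.correct:
                    wrong_open.add(tap.target)
            elif tap.target in wrong_open:
                count += 1
                wrong_open.discard(tap.target)
    return math.log10(count + 1.0)


@dataclass
class BiomarkerVector:
    """The 14 digital biomarkers of one subject-session (NaN = missing)."""

    subject_id: str
    session_time: datetime
    iSMPT_V_imm: float = math.nan
    iSMPT_V_del: float = math.nan
    iSMPT_S_static: float = math.nan
    iSMPT_S_dynamic: float = math.nan
    ImmVRLa: float = math.nan
    DelVRLa: float = math.nan
    StaticSRLa: float = math.nan
    DynamicSRLa: float = math.nan
    ImmVRI: float = math.nan
    DelVRI: float = math.nan
    StaticSRI: float = math.nan
    DynamicSRI: float = math.nan
    StaticSRM: float = math.nan
    DynamicSRM: float = math.nan
    stage_valid: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stage_valid is None:
            self.stage_valid = {}
        names = tuple(
            f.name for f in dc_fields(self) if f.name not in ("subject_id", "session_time", "stage_valid")
        )
        assert names == BIOMARKER_NAMES  # 14 biomarker fields, fixed order

    def as_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "session_time": self.session_time}
        d.update({name: getattr(self, name) for name in BIOMARKER_NAMES})
        for stage in _STAGE_FIELDS:
            d[f"valid_{stage}"] = self.stage_valid.get(stage, False)
        return d


def biomarker_vector(trials: Mapping[str, TrialRecord]) -> BiomarkerVector:
    """Derive the biomarker vector of one session from its stage trials.

    ``trials`` maps stage name to the (already integrity-screened)
    TrialRecord. Invalid or absent stages yield NaN fields — exclusion is at
    trial level, never imputed.
    """
    present = [t for t in trials.values() if t is not None]
    if not present:
        raise ValueError("no trials supplied")
    subject_id = present[0].subject_id
    session_time = min(t.session_time for t in present)
    vec = BiomarkerVector(subject_id=subject_id, session_time=session_time)
    for stage, trial in trials.items():
        if trial is None:
            continue
        if stage not in _STAGE_FIELDS:
            raise ValueError(f"unknown stage {stage!r}")
        vec.stage_valid[stage] = bool(trial.valid)
        if not trial.valid:
            continue
        f_ismpt, f_rla, f_imp, f_srm = _STAGE_FIELDS[stage]
        setattr(vec, f_ismpt, ismpt(trial))
        setattr(vec, f_rla, adjusted_latency(trial))
        if stage == "spatial_static":
            raw = static_partial_credit(trial)
            setattr(vec, f_imp, spatial_recall_impairment(raw, STATIC_MAX))
        elif stage == "spatial_dynamic":
            raw = dynamic_partial_credit(trial)
            setattr(vec, f_imp, spatial_recall_impairment(raw, DYNAMIC_MAX))
        else:
            setattr(vec, f_imp, verbal_recall_impairment(trial))
        if f_srm is not None:
            setattr(vec, f_srm, spatial_recall_mistakes(trial))
    return vec


def biomarker_table(sessions: Iterable[Mapping[str, TrialRecord]]) -> pd.DataFrame:
    """Biomarker vectors for many sessions as one row-per-session DataFrame."""
    rows = [biomarker_vector(s).as_dict() for s in sessions]
    return pd.DataFrame(rows)


def quadrant_stratify(
    table: pd.DataFrame,
    ismpt_col: str = "iSMPT_S_static",
    latency_col: str = "StaticSRLa",
) -> pd.Series:
    """Stratify subjects into quadrants of the (iSMPT-S, adjusted latency) plane.

    Median split on each axis within the supplied table; values at or below
    the median count as "low". Q1 = high iSMPT & high latency (combined
    physical + cognitive impairment), Q2 = low iSMPT & high latency (cognitive
    only), Q3 = low & low (neither), Q4 = high iSMPT & low latency (physical
    only).
    """
    sub = table[[ismpt_col, latency_col]].dropna()
    if len(sub) < 4:
        raise ValueError(f"need >=4 subjects with both fields, got {len(sub)}")
    labels = pd.Series(index=sub.index, dtype=object)
    med_i = sub[ismpt_col].median()
    med_l = sub[latency_col].median()
    for col, med in ((ismpt_col, med_i), (latency_col, med_l)):
        if (sub[col] == sub[col].iloc[0]).all():
            warnings.warn(f"degenerate split: all {col!r} values identical; all assigned 'low'")
    hi_i = sub[ismpt_col] > med_i
    hi_l = sub[latency_col] > med_l
    labels[hi_i & hi_l] = "Q1"
    labels[~hi_i & hi_l] = "Q2"
    labels[~hi_i & ~hi_l] = "Q3"
    labels[hi_i & ~hi_l] = "Q4"
    return labels.reindex(table.index)
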