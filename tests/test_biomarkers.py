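"""Biomarker derivation: iSMPT decomposition, partial credit, transforms."""

import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from tapcog.biomarkers import (
    BIOMARKER_NAMES,
    DYNAMIC_MAX,
    STATIC_MAX,
    adjusted_latency,
    biomarker_vector,
    dynamic_partial_credit,
    ismpt,
    quadrant_stratify,
    spatial_recall_impairment,
    spatial_recall_mistakes,
    static_partial_credit,
    verbal_recall_impairment,
)
from tapcog.events import SpatialAttempt, TapEvent, TrialRecord, all_intervals, validate_trial
from tapcog.simulate import LatentProfile, build_spatial_trial, simulate_session

from conftest import make_verbal_trial


def trial_with_intervals(intervals_s, stage="spatial_static"):
    """Single-attempt spatial trial with the given inter-tap intervals."""
    t, taps = 0, []
    level_cells = list(range(4))
    taps.append(TapEvent(0, "select", level_cells[0], True))
    for i, dt in enumerate(intervals_s):
        t += int(round(dt * 1000))
        taps.append(TapEvent(t, "select", level_cells[(i + 1) % 4], True))
    attempt = SpatialAttempt(level=4, pattern=frozenset(level_cells), taps=tuple(taps), passed=True)
    return TrialRecord("x", stage, datetime(2023, 1, 2), (attempt,))


class TestISMPT:
    def test_minimum_of_intervals(self):
        assert ismpt(trial_with_intervals([0.9, 0.45, 1.2])) == pytest.approx(0.45)

    def test_single_interval(self):
        assert ismpt(trial_with_intervals([0.7])) == pytest.approx(0.7)

    def test_no_intervals_is_missing(self):
        trial = trial_with_intervals([])
        assert math.isnan(ismpt(trial))

    def test_never_exceeds_any_interval(self, healthy_profile):
        session = simulate_session(healthy_profile, seed=3)
        for trial in session.values():
            v = ismpt(trial)
            assert all(v <= dt + 1e-12 for dt in all_intervals(trial))

    def test_converges_to_motor_floor(self):
        """Median iSMPT over shifted-exponential sessions approaches the floor."""
        prof = LatentProfile(0.35, 2.0, 0.9, 3.0, 0.4, 0.3)
        vals = []
        for s in range(300):
            session = simulate_session(prof, seed=s)
            vals.append(ismpt(session["verbal_immediate"]))
        err = abs(np.median(vals) - 0.35)
        assert err < 0.15 * 0.35


class TestAdjustedLatency:
    def test_mean_minus_minimum(self):
        trial = trial_with_intervals([0.9, 0.45, 1.2])
        assert adjusted_latency(trial) == pytest.approx(np.mean([0.9, 0.45, 1.2]) - 0.45)

    def test_equals_mean_of_per_interval_excesses(self):
        intervals = [0.5, 0.8, 1.1, 0.62, 0.9]
        trial = trial_with_intervals(intervals)
        m = min(intervals)
        oracle = np.mean([dt - m for dt in intervals])
        assert adjusted_latency(trial) == pytest.approx(oracle)

    def test_zero_when_all_intervals_equal(self):
        assert adjusted_latency(trial_with_intervals([0.6, 0.6, 0.6])) == pytest.approx(0.0)

    def test_invariant_under_pure_motor_slowing(self):
        """Adding a constant to every interval moves iSMPT, not the latency —
        the decomposition separating motor from cognitive slowing."""
        base = [0.5, 0.8, 1.1, 0.62]
        slowed = [dt + 0.25 for dt in base]
        t1, t2 = trial_with_intervals(base), trial_with_intervals(slowed)
        assert ismpt(t2) == pytest.approx(ismpt(t1) + 0.25)
        assert adjusted_latency(t2) == pytest.approx(adjusted_latency(t1))

    def test_nonnegative_on_simulated_sessions(self, impaired_profile):
        for s in range(20):
            for trial in simulate_session(impaired_profile, seed=s).values():
                v = adjusted_latency(trial)
                assert math.isnan(v) or v >= 0


class TestVerbalRecallImpairment:
    @pytest.mark.parametrize(
        "n_correct, expected",
        [(10, 0.0), (9, math.log10(11)), (0, math.log10(101))],
    )
    def test_transform(self, n_correct, expected):
        assert verbal_recall_impairment(make_verbal_trial(n_correct)) == pytest.approx(expected)

    def test_uses_first_attempt_only(self):
        perfect = make_verbal_trial(10)
        flawed = make_verbal_trial(7)
        trial = TrialRecord(
            "x", "verbal_immediate", flawed.session_time,
            attempts=(flawed.attempts[0], perfect.attempts[0]),
        )
        assert verbal_recall_impairment(trial) == pytest.approx(math.log10(31))


class TestPartialCredit:
    def test_static_worked_example(self):
        """Pass 4, pass 5, fail level 6 with 3 then 1 mistakes -> 4+5+(6-2) = 13."""
        trial = build_spatial_trial(
            "spatial_static",
            [(4, True, 0), (5, True, 0), (6, False, 3), (6, False, 1)],
        )
        assert static_partial_credit(trial) == 13

    def test_static_flawless_is_30(self):
        trial = build_spatial_trial("spatial_static", [(lvl, True, 0) for lvl in range(4, 9)])
        assert static_partial_credit(trial) == STATIC_MAX == 30

    def test_static_floor_at_zero(self):
        """Pass 4; level-5 attempts with 5 and 5 mistakes -> 4 + max(0, 5-5) = 4."""
        trial = build_spatial_trial(
            "spatial_static", [(4, True, 0), (5, False, 5), (5, False, 5)]
        )
        assert static_partial_credit(trial) == 4

    def test_dynamic_worked_example(self):
        """Failed level 6 (worth 12 when double-weighted), avg 2 mistakes -> 8."""
        trial = build_spatial_trial("spatial_dynamic", [(6, False, 2)])
        # direct application to the failed level only
        assert dynamic_partial_credit(trial) == 12 - 2 * 2 == 8

    def test_dynamic_flawless_is_60(self):
        trial = build_spatial_trial("spatial_dynamic", [(lvl, True, 0) for lvl in range(4, 9)])
        assert dynamic_partial_credit(trial) == DYNAMIC_MAX == 60

    def test_dynamic_pass4_fail5(self):
        trial = build_spatial_trial("spatial_dynamic", [(4, True, 0), (5, False, 1)])
        assert dynamic_partial_credit(trial) == 8 + (10 - 2)

    @pytest.mark.parametrize("stage, scorer, weight", [
        ("spatial_static", static_partial_credit, 1),
        ("spatial_dynamic", dynamic_partial_credit, 2),
    ])
    def test_brute_force_rule_oracle(self, stage, scorer, weight):
        """Score equals the rule evaluated independently over the attempt list."""
        plans = [
            [(4, True, 0), (5, False, 2), (5, False, 4), (5, False, 0)],
            [(4, False, 1), (4, True, 0), (5, True, 0), (6, False, 6)],
            [(4, True, 0), (5, True, 0), (6, True, 0), (7, False, 3), (7, False, 2)],
        ]
        for plan in plans:
            trial = build_spatial_trial(stage, plan)
            passed = {lvl for lvl, ok, _ in plan if ok}
            failed = {}
            for lvl, ok, wrong in plan:
                if not ok:
                    failed.setdefault(lvl, []).append(wrong)
            expect = sum(weight * lvl for lvl in passed)
            open_fail = [lvl for lvl in failed if lvl not in passed]
            if open_fail:
                lvl = max(open_fail)
                expect += max(0.0, weight * lvl - weight * np.mean(failed[lvl]))
            assert scorer(trial) == pytest.approx(expect)

    def test_monotone_in_mistakes(self):
        """More mistakes in an attempt never increases the score."""
        prev = math.inf
        for wrong in range(7):
            trial = build_spatial_trial(
                "spatial_static", [(4, True, 0), (5, True, 0), (6, False, wrong)]
            )
            score = static_partial_credit(trial)
            assert score <= prev
            prev = score


class TestSpatialImpairmentAndMistakes:
    @pytest.mark.parametrize("raw, mx, expected", [
        (30, 30, 0.0),
        (13, 30, math.log10(18)),
        (0, 30, math.log10(31)),
        (60, 60, 0.0),
    ])
    def test_sri_transform(self, raw, mx, expected):
        assert spatial_recall_impairment(raw, mx) == pytest.approx(expected)

    def test_sri_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            spatial_recall_impairment(31, 30)

    def test_srm_zero_without_deselections(self):
        trial = build_spatial_trial("spatial_static", [(4, False, 2)])
        assert spatial_recall_mistakes(trial) == 0.0

    def test_srm_counts_self_corrections(self):
        trial = build_spatial_trial(
            "spatial_static",
            [(4, False, 3), (4, False, 3), (4, False, 3)],
            self_corrections=3,
        )
        assert spatial_recall_mistakes(trial) == pytest.approx(math.log10(10))

    def test_srm_generator_bookkeeping(self, impaired_profile):
        """SRM equals log10(k+1) of deselect events injected by the simulator."""
        for s in range(10):
            trial = simulate_session(impaired_profile, seed=s)["spatial_static"]
            k = sum(1 for tap in trial.iter_taps() if tap.action == "deselect")
            assert spatial_recall_mistakes(trial) == pytest.approx(math.log10(k + 1))


class TestBiomarkerVector:
    def test_full_session_populates_all_fourteen(self, healthy_profile):
        session = {k: validate_trial(t) for k, t in simulate_session(healthy_profile, 1).items()}
        vec = biomarker_vector(session)
        values = [getattr(vec, n) for n in BIOMARKER_NAMES]
        assert len(values) == 14
        assert not any(math.isnan(v) for v in values)

    def test_verbal_only_session(self, healthy_profile):
        session = {k: validate_trial(t) for k, t in simulate_session(healthy_profile, 1).items()
                   if k.startswith("verbal")}
        vec = biomarker_vector(session)
        missing = [n for n in BIOMARKER_NAMES if math.isnan(getattr(vec, n))]
        assert len(missing) == 8
        assert all(("S" in n and "V" not in n) or "Static" in n or "Dynamic" in n for n in missing)

    def test_matches_stagewise_recomputation(self, impaired_profile):
        session = {k: validate_trial(t) for k, t in simulate_session(impaired_profile, 9).items()}
        vec = biomarker_vector(session)
        assert vec.iSMPT_S_static == pytest.approx(ismpt(session["spatial_static"]))
        assert vec.DynamicSRLa == pytest.approx(adjusted_latency(session["spatial_dynamic"]))
        assert vec.ImmVRI == pytest.approx(verbal_recall_impairment(session["verbal_immediate"]))


class TestQuadrants:
    def test_symmetric_grid(self):
        df = pd.DataFrame({
            "iSMPT_S_static": [1.0, 1.0, -1.0, -1.0, 0.0],
            "StaticSRLa": [1.0, -1.0, 1.0, -1.0, 0.0],
        })
        labels = quadrant_stratify(df)
        assert list(labels[:4]) == ["Q1", "Q4", "Q2", "Q3"]

    def test_exact_median_goes_low(self):
        # the fifth subject sits exactly at both medians -> low/low = Q3
        df = pd.DataFrame({
            "iSMPT_S_static": [1.0, 1.0, -1.0, -1.0, 0.0],
            "StaticSRLa": [1.0, -1.0, 1.0, -1.0, 0.0],
        })
        assert quadrant_stratify(df).iloc[4] == "Q3"

    def test_latent_class_recovery(self):
        """Subjects simulated with a high motor floor but low cognitive latency
        land in Q4 (physical-only impairment)."""
        rows = []
        specs = {
            "Q1": LatentProfile(0.7, 2.5, 1.4, 6.0, 0.05, 0.3),
            "Q2": LatentProfile(0.25, 2.5, 1.4, 6.0, 0.05, 0.3),
            "Q3": LatentProfile(0.25, 2.5, 0.3, 6.0, 0.05, 0.3),
            "Q4": LatentProfile(0.7, 2.5, 0.3, 6.0, 0.05, 0.3),
        }
        for label, prof in specs.items():
            for s in range(12):
                trial = simulate_session(prof, seed=hash((label, s)) % 2**31)["spatial_static"]
                rows.append({
                    "truth": label,
                    "iSMPT_S_static": ismpt(trial),
                    "StaticSRLa": adjusted_latency(trial),
                })
        df = pd.DataFrame(rows)
        labels = quadrant_stratify(df)
        acc = (labels == df["truth"]).mean()
        assert acc > 0.7

    def test_too_few_subjects(self):
        df = pd.DataFrame({"iSMPT_S_static": [1.0], "StaticSRLa": [2.0]})
        with pytest.raises(ValueError):
            quadrant_stratify(df)
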