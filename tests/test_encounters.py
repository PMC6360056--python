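"""Timeframe construction, surrogate issuance and encounter assignment."""

from __future__ import annotations

import datetime as dt
import random

import pytest

from txstar.encounters import (
    AmbiguousTransplantError,
    SurrogateRegistry,
    TemporalIntegrityError,
    Timeframe,
    TransplantRecord,
    assign_encounter,
    assign_encounter_with_rule,
    build_timeframes,
    surrogate_for,
)

D0 = dt.date(2010, 1, 1)


def day(n: int) -> dt.date:
    return D0 + dt.timedelta(days=n)


def brute_force_assign(patient, fact_day, frames, registry):
    """Extensional oracle: test every window's membership predicate directly,
    resolve multi-membership by latest start, otherwise count preceding
    window starts for the gap index."""
    containing = []
    for tf in frames:
        inside = tf.window_start <= fact_day
        if tf.window_end is not None:
            inside = inside and fact_day <= tf.window_end
        elif tf.truncated_at is not None:
            inside = inside and fact_day < tf.truncated_at
        if inside:
            containing.append(tf)
    if containing:
        return max(containing, key=lambda t: t.window_start).encounter_id
    gap = sum(1 for tf in frames if tf.window_start <= fact_day)
    return registry.surrogate_for(patient, gap)


class TestBuildTimeframes:
    def test_failed_transplant_window_is_two_weeks_each_side(self):
        frames = build_timeframes(1, [TransplantRecord(10, day(100), day(200))])
        tf = frames[0]
        assert tf.window_start == day(86)
        assert tf.window_end == day(214)

    def test_unfailed_final_transplant_is_open_ended(self):
        frames = build_timeframes(1, [TransplantRecord(10, day(100), None)])
        tf = frames[0]
        assert tf.window_end is None and tf.truncated_at is None
        assert tf.contains(day(5000))

    def test_truncation_at_next_window_start(self):
        frames = build_timeframes(
            1, [TransplantRecord(10, day(100), None), TransplantRecord(11, day(400), None)]
        )
        # brute-force membership over all days 0..500 against the stated rule
        for n in range(0, 501):
            d = day(n)
            in_first = 86 <= n < 386
            in_second = 386 <= n
            assert frames[0].contains(d) == in_first
            assert frames[1].contains(d) == in_second

    def test_duplicate_transplant_dates_rejected(self):
        with pytest.raises(AmbiguousTransplantError):
            build_timeframes(1, [TransplantRecord(1, day(5), None),
                                 TransplantRecord(2, day(5), None)])

    def test_failure_before_transplant_rejected(self):
        with pytest.raises(TemporalIntegrityError):
            build_timeframes(1, [TransplantRecord(1, day(100), day(90))])


class TestAssignment:
    @pytest.fixture()
    def failed_frames(self):
        return build_timeframes(1, [TransplantRecord(10, day(100), day(200))])

    def test_boundaries_inclusive(self, failed_frames):
        reg = SurrogateRegistry({1: 1})
        assert assign_encounter(1, day(86), failed_frames, reg) == 10
        assert assign_encounter(1, day(214), failed_frames, reg) == 10

    def test_just_outside_window_gets_surrogate(self, failed_frames):
        reg = SurrogateRegistry({1: 1})
        enc, rule = assign_encounter_with_rule(1, day(85), failed_frames, reg)
        assert enc < 0 and rule == "SURROGATE"

    def test_overlap_tiebreak_prefers_later_transplant(self):
        # failed graft's tail (to day 394) overlaps next lead (from day 386)
        frames = build_timeframes(
            1, [TransplantRecord(20, day(100), day(380)), TransplantRecord(21, day(400), None)]
        )
        assert frames[0].contains(day(390)) and frames[1].contains(day(390))
        enc, rule = assign_encounter_with_rule(1, day(390), frames, SurrogateRegistry({1: 2}))
        assert enc == 21 and rule == "OVERLAP_TIEBREAK"

    def test_patient_without_transplants_gets_surrogate(self):
        reg = SurrogateRegistry({7: 0})
        assert assign_encounter(7, day(50), [], reg) < 0

    def test_oracle_equivalence_randomized(self):
        """Implementation matches the brute-force extensional oracle for
        every day in range over randomized transplant histories."""
        rng = random.Random(99)
        windows_per_patient = {}
        histories = {}
        for pid in range(1, 201):
            n_tx = rng.randint(0, 5)
            days = sorted(rng.sample(range(30, 900), n_tx))
            recs = []
            for i, dnum in enumerate(days):
                tid = pid * 100 + i
                failure = day(dnum + rng.randint(0, 300)) if rng.random() < 0.5 else None
                recs.append(TransplantRecord(tid, day(dnum), failure))
            histories[pid] = build_timeframes(pid, recs)
            windows_per_patient[pid] = len(recs)
        reg_impl = SurrogateRegistry(windows_per_patient)
        reg_oracle = SurrogateRegistry(windows_per_patient)
        for pid, frames in histories.items():
            for n in range(0, 1000, 7):
                got = assign_encounter(pid, day(n), frames, reg_impl)
                want = brute_force_assign(pid, day(n), frames, reg_oracle)
                assert got == want, (pid, n)

    def test_assignment_independent_of_fact_order(self):
        frames = build_timeframes(
            1, [TransplantRecord(1, day(100), day(150)), TransplantRecord(2, day(400), None)]
        )
        days = [day(n) for n in range(0, 600, 11)]
        reg_a = SurrogateRegistry({1: 2})
        forward = {d: assign_encounter(1, d, frames, reg_a) for d in days}
        reg_b = SurrogateRegistry({1: 2})
        backward = {d: assign_encounter(1, d, frames, reg_b) for d in reversed(days)}
        assert forward == backward


class TestSurrogates:
    def test_idempotent_and_counter_contract(self):
        reg = SurrogateRegistry({1: 2})
        assert surrogate_for(reg, 1, 0) == -1
        assert surrogate_for(reg, 1, 0) == -1
        assert surrogate_for(reg, 1, 1) == -2

    def test_globally_unique_across_patients(self):
        reg = SurrogateRegistry({1: 2, 2: 1, 5: 3})
        issued = {
            surrogate_for(reg, pid, gap)
            for pid, n in ((1, 3), (2, 2), (5, 4))
            for gap in range(n)
        }
        assert len(issued) == 9
        assert all(sid < 0 for sid in issued)
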