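import datetime as dt
import statistics

import numpy as np
import pytest

from bestdiary.detection import (
    characterize_reported,
    count_worsened_domains,
    detect_events,
    detect_unreported,
    estimate_baseline,
    stable_day_mask,
)
from bestdiary.synthetic import SyntheticConfig, generate_cohort

START = dt.date(2014, 1, 6)
ONE_DAY = dt.timedelta(days=1)


# --- independent brute-force oracle -----------------------------------------
# A plain nested-loop restatement of the detection contract, sharing no code
# with the implementation: baseline = median of the 7 days before the run
# start (first study week near the start, sliding back up to 21 days when
# sparse, >= 4 observed days), qualifying run = >= 2 consecutive observed
# days at baseline + 3 or more, end = first later day at or below baseline,
# events closer than 7 days merged.


def oracle_baseline(totals, start_day, ref, excluded):
    def window_values(w_start, w_end):
        out = []
        day = w_start
        while day < w_end:
            if day in totals and day not in excluded:
                out.append(totals[day])
            day += ONE_DAY
        return out

    if (ref - start_day).days < 7:
        values = window_values(start_day, start_day + 7 * ONE_DAY)
        if len(values) >= 4:
            return statistics.median(values)
        return None
    for back in range(22):
        end = ref - back * ONE_DAY
        w_start = end - 7 * ONE_DAY
        if w_start < start_day:
            return None
        values = window_values(w_start, end)
        if len(values) >= 4:
            return statistics.median(values)
    return None


def oracle_unreported(totals, start_day, censored=frozenset()):
    observed = [d for d in sorted(totals) if d not in censored]
    excluded = set(censored)
    events = []
    consumed_until = None
    for day in observed:
        if consumed_until is not None and day <= consumed_until:
            continue
        base = oracle_baseline(totals, start_day, day, excluded)
        if base is None or totals[day] < base + 3:
            continue
        run = [day]
        nxt = day + ONE_DAY
        while nxt in totals and nxt not in censored and totals[nxt] >= base + 3:
            run.append(nxt)
            nxt += ONE_DAY
        if len(run) < 2:
            continue
        end = None
        for later in observed:
            if later <= run[-1]:
                continue
            if totals[later] <= base:
                end = later
                break
        truncated = end is None
        if end is None:
            end = observed[-1]
        events.append(
            {"onset": run[0], "end": end, "baseline": base, "truncated": truncated}
        )
        day_i = run[0]
        while day_i <= end:
            excluded.add(day_i)
            day_i += ONE_DAY
        consumed_until = end
    merged = []
    for ev in events:
        if merged and (ev["onset"] - merged[-1]["end"]).days < 7:
            merged[-1]["end"] = max(merged[-1]["end"], ev["end"])
            merged[-1]["truncated"] = ev["truncated"]
        else:
            merged.append(dict(ev))
    for ev in merged:
        peak = max(
            totals[d]
            for d in totals
            if ev["onset"] <= d <= ev["end"]
        )
        ev["peak_change"] = peak - ev["baseline"]
    return merged


def random_totals_diary(rng, make_diary, n_days):
    """A jagged random series: random walk plus occasional planted bumps."""
    base = rng.integers(2, 12)
    totals = [int(base)] * n_days
    level = float(base)
    for i in range(n_days):
        level = float(np.clip(level + rng.normal(0, rng.uniform(0.3, 2.0)), 0, 26))
        totals[i] = int(round(level))
    for _ in range(rng.integers(0, 3)):
        onset = int(rng.integers(8, max(9, n_days - 6)))
        length = int(rng.integers(2, 9))
        bump = int(rng.integers(3, 9))
        for k in range(length):
            if onset + k < n_days:
                totals[onset + k] = int(min(totals[onset + k] + bump, 26))
    missing = {
        int(i) for i in rng.choice(n_days, size=rng.integers(0, n_days // 8 + 1), replace=False)
    }
    missing -= {0, n_days - 1}
    return make_diary(totals, missing_days=missing), totals, missing


class TestBaselineEstimate:
    def test_constant_prior_week(self, make_diary):
        diary = make_diary([7] * 14)
        est = estimate_baseline(diary, START + 10 * ONE_DAY)
        assert est.value == 7 and est.usable and est.n_observed == 7

    def test_median_ignores_one_spike(self, make_diary):
        diary = make_diary([5, 6, 7, 7, 8, 9, 20, 7, 7, 7])
        est = estimate_baseline(diary, START + 7 * ONE_DAY)
        assert est.value == 7

    def test_median_of_observed_days_under_min_four_rule(self, make_diary):
        diary = make_diary([6, 0, 7, 0, 8, 0, 9, 5, 5], missing_days={1, 3, 5})
        est = estimate_baseline(diary, START + 7 * ONE_DAY)
        assert est.usable and est.n_observed == 4
        assert est.value == 7.5

    def test_walkback_when_recent_week_sparse(self, make_diary):
        totals = [6] * 10 + [9] * 10
        diary = make_diary(totals, missing_days={10, 11, 12, 13, 14, 15})
        est = estimate_baseline(diary, START + 17 * ONE_DAY)
        assert est.usable
        assert est.value == 6

    def test_reference_before_diary_start_rejected(self, make_diary):
        diary = make_diary([7] * 14)
        with pytest.raises(ValueError):
            estimate_baseline(diary, START - ONE_DAY)


class TestDetectUnreported:
    def test_two_day_rise_is_one_event(self, make_diary):
        totals = [7] * 10 + [10, 11, 7] + [7] * 7
        diary = make_diary(totals)
        events = detect_unreported(diary, [])
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_day == START + 10 * ONE_DAY
        assert ev.peak_change == 4
        assert ev.qualifying_run_days == 2
        assert ev.end_day == START + 12 * ONE_DAY

    def test_single_day_spike_is_not_an_event(self, make_diary):
        totals = [7] * 10 + [15] + [7] * 9
        assert detect_unreported(make_diary(totals), []) == []

    def test_sustained_subthreshold_rise_is_not_an_event(self, make_diary):
        totals = [7] * 10 + [9] * 10 + [7] * 5
        assert detect_unreported(make_diary(totals), []) == []

    def test_missing_day_breaks_a_run(self, make_diary):
        totals = [7] * 10 + [11, 11, 11] + [7] * 7
        diary = make_diary(totals, missing_days={11})
        assert detect_unreported(diary, []) == []

    def test_short_diary_rejected(self, make_diary):
        with pytest.raises(ValueError, match="14"):
            detect_unreported(make_diary([7] * 10), [])

    def test_raising_threshold_never_finds_more_events(self, make_diary):
        rng = np.random.default_rng(4)
        for _ in range(20):
            diary, _, _ = random_totals_diary(rng, make_diary, 60)
            counts = [
                len(detect_unreported(diary, [], threshold=t)) for t in (3, 4, 5, 6)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_oracle_on_random_corpus(self, make_diary):
        rng = np.random.default_rng(1234)
        checked_events = 0
        for case in range(1000):
            n_days = int(rng.integers(14, 61))
            diary, _, _ = random_totals_diary(rng, make_diary, n_days)
            got = detect_unreported(diary, [])
            want = oracle_unreported(diary.totals(), diary.start)
            assert [(e.onset_day, e.end_day, e.truncated) for e in got] == [
                (w["onset"], w["end"], w["truncated"]) for w in want
            ], f"case {case} mismatch"
            for e, w in zip(got, want):
                assert e.peak_change == pytest.approx(w["peak_change"])
            checked_events += len(got)
        assert checked_events > 100  # the corpus genuinely exercises the rule


class TestCharacterizeReported:
    def build(self, make_diary):
        # baseline 7, linear rise over 5 days to 16 at treatment, linear
        # fall reaching 7 on day 15 after treatment
        totals = [7] * 10
        rise = [9, 11, 12, 14, 16]
        fall = [16 - round(9 * k / 15) for k in range(1, 15)]
        totals += rise + fall + [7] + [7] * 10
        return make_diary(totals, treatment_days={14})

    def test_constructed_event_measured_by_definition(self, make_diary):
        diary = self.build(make_diary)
        ev = characterize_reported(diary, START + 14 * ONE_DAY)
        assert ev.baseline.value == 7
        assert ev.onset_time_days == 4
        assert ev.peak_score == 16
        assert ev.peak_change == 9
        assert ev.duration_days == 15
        assert not ev.truncated
        assert ev.pre_period_mean == pytest.approx(statistics.fmean([9, 11, 12, 14]))

    def test_flat_series_before_treatment_is_atypical(self, make_diary):
        totals = [7] * 30
        diary = make_diary(totals, treatment_days={15})
        ev = characterize_reported(diary, START + 15 * ONE_DAY)
        assert ev.onset_time_days == 0
        assert ev.atypical

    def test_never_returning_series_truncated_at_cap(self, make_diary):
        totals = [7] * 10 + [16] * 60
        diary = make_diary(totals, treatment_days={12})
        ev = characterize_reported(diary, START + 12 * ONE_DAY)
        assert ev.truncated
        assert ev.duration_days == 42

    def test_missing_treatment_flag_rejected(self, make_diary):
        diary = make_diary([7] * 30)
        with pytest.raises(ValueError, match="antibiotic"):
            characterize_reported(diary, START + 15 * ONE_DAY)


class TestWorsenedDomains:
    def test_two_rising_items_do_not_meet_consensus_definition(self, make_diary):
        # only cough and sputum volume rise: a reported event below the
        # three-symptom consensus threshold
        from bestdiary.instrument import DiaryEntry, PatientDiary

        entries = []
        for i in range(30):
            cough, vol = (1, 1)
            if 12 <= i <= 18:
                cough, vol = (4, 4)
            flag = i == 14
            entries.append(
                DiaryEntry(
                    "P001",
                    START + i * ONE_DAY,
                    breathlessness=1,
                    fatigue=1,
                    sputum_volume=vol,
                    sputum_colour=1,
                    cough=cough,
                    cold_flu=0,
                    reported_flag=flag,
                    antibiotic_start=flag,
                )
            )
        diary = PatientDiary("P001", entries)
        ev = characterize_reported(diary, START + 14 * ONE_DAY)
        assert ev.n_worsened_domains == 2
        assert ev.met_embarc is False

    def test_all_items_rising_meets_definition(self, make_diary):
        diary = make_diary(
            [6] * 12 + [20] * 6 + [6] * 12, treatment_days={13}
        )
        ev = characterize_reported(diary, START + 13 * ONE_DAY)
        assert ev.met_embarc is True
        assert ev.n_worsened_domains >= 3

    def test_no_rise_counts_zero_domains(self, make_diary):
        diary = make_diary([7] * 30, treatment_days={15})
        ev = characterize_reported(diary, START + 15 * ONE_DAY)
        assert ev.n_worsened_domains == 0
        assert ev.met_embarc is False


class TestStableDayMask:
    def test_no_events_all_days_stable(self, make_diary):
        diary = make_diary([7] * 20)
        mask = stable_day_mask(diary, [])
        assert mask.all() and len(mask) == 20

    def test_event_window_with_pre_buffer_masked(self, make_diary):
        totals = [7] * 25 + [11, 11] + [7] * 25
        diary = make_diary(totals)
        events = detect_unreported(diary, [])
        assert len(events) == 1
        mask = stable_day_mask(diary, events)
        unstable = {d for d, ok in mask.items() if not ok}
        lo = events[0].onset_day - 7 * ONE_DAY
        hi = events[0].end_day
        assert unstable == {
            lo + k * ONE_DAY for k in range((hi - lo).days + 1)
        }

    def test_events_covering_whole_diary_leave_no_stable_days(self, make_diary):
        totals = [7] * 10 + [12] * 30
        diary = make_diary(totals)
        events = detect_unreported(diary, [])
        mask = stable_day_mask(diary, events, pre_buffer=40)
        assert not mask.any()


class TestNoisyCohortRecovery:
    def test_planted_unreported_events_with_change_ge_4_mostly_detected(self):
        cfg = SyntheticConfig(n_patients=200, followup_days=180, seed=17)
        diaries, truth = generate_cohort(cfg)
        found, total = 0, 0
        for pid, diary in diaries.items():
            detected = [e for e in detect_events(diary) if e.kind == "unreported"]
            for t in truth[pid].events:
                if t.kind != "unreported" or t.peak_change < 4:
                    continue
                total += 1
                span_end = t.onset_day + dt.timedelta(days=t.duration_days)
                if any(
                    e.onset_day <= span_end and e.end_day >= t.onset_day
                    for e in detected
                ):
                    found += 1
        assert total > 50
        assert found / total >= 0.9

    def test_unreported_events_never_overlap_reported_censor_windows(self):
        cfg = SyntheticConfig(n_patients=60, followup_days=180, seed=23)
        diaries, _ = generate_cohort(cfg)
        for diary in diaries.values():
            events = detect_events(diary)
            reported = [e for e in events if e.kind == "reported"]
            for ue in (e for e in events if e.kind == "unreported"):
                for re_ in reported:
                    lo = re_.onset_day - 7 * ONE_DAY
                    assert ue.end_day < lo or ue.onset_day > re_.end_day
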