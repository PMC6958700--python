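"""Baseline estimation and exacerbation detection/characterisation.

Two event kinds are handled:

* **Reported (treated)** exacerbations are anchored on the antibiotic-start
  day recorded in the diary; the algorithm walks back to find symptom onset,
  the pre-treatment symptom level, the peak, and the day symptoms return to
  the pre-event baseline.
* **Unreported** exacerbations are found by the consensus screening rule: a
  rise of at least 3 points over the rolling baseline sustained for at least
  48 h (two consecutive diary days), outside treated-event windows and with
  no antibiotic treatment.

The baseline is the median diary total over the week preceding an event (or
the first study week), re-estimated per event.
"""

from __future__ import annotations

import csv
import datetime as dt
import statistics
from dataclasses import dataclass, field

from .instrument import ITEM_NAMES, PatientDiary

__all__ = [
    "BaselineEstimate",
    "ExacerbationEvent",
    "estimate_baseline",
    "characterize_reported",
    "detect_unreported",
    "detect_events",
    "count_worsened_domains",
    "stable_day_mask",
    "events_to_rows",
    "write_events_csv",
    "EVENT_COLUMNS",
]

ONE_DAY = dt.timedelta(days=1)


@dataclass(frozen=True)
class BaselineEstimate:
    """Median-of-prior-week symptom baseline.

    ``window_start``/``window_end`` delimit the half-open calendar window
    actually used (it can slide back up to ``max_walkback`` days when the
    preceding week is too sparse, and falls back to the first study week for
    events near the diary start).
    """

    reference_day: dt.date
    window_start: dt.date
    window_end: dt.date
    n_observed: int
    value: float
    usable: bool

    @property
    def window_days(self) -> list[dt.date]:
        days = []
        day = self.window_start
        while day < self.window_end:
            days.append(day)
            day += ONE_DAY
        return days


@dataclass
class ExacerbationEvent:
    kind: str  # "reported" | "unreported"
    patient_id: str
    onset_day: dt.date
    end_day: dt.date
    baseline: BaselineEstimate
    peak_score: float
    peak_change: float
    duration_days: int
    treatment_start: dt.date | None = None
    pre_period_mean: float | None = None
    onset_time_days: int | None = None
    n_worsened_domains: int | None = None
    met_embarc: bool | None = None
    truncated: bool = False
    atypical: bool = False
    qualifying_run_days: int = 0

    def span(self) -> tuple[dt.date, dt.date]:
        return self.onset_day, self.end_day


def estimate_baseline(
    diary: PatientDiary,
    reference_day: dt.date,
    exclusion: set[dt.date] | None = None,
    *,
    window: int = 7,
    min_obs: int = 4,
    max_walkback: int = 21,
) -> BaselineEstimate:
    """Median diary total over the week preceding ``reference_day``.

    Excluded days (e.g. days inside other events) do not contribute. If the
    window holds fewer than ``min_obs`` usable days it slides back one day
    at a time, up to ``max_walkback`` days; when the reference day falls
    within the first study week the first seven diary days are used instead.
    An estimate that never reaches ``min_obs`` days is flagged unusable.
    """
    if reference_day < diary.start:
        raise ValueError(
            f"reference day {reference_day} precedes diary start {diary.start}"
        )
    exclusion = exclusion or set()
    totals = diary.totals()

    def collect(start: dt.date, end: dt.date) -> list[float]:
        return [
            float(totals[d])
            for d in (start + dt.timedelta(days=i) for i in range((end - start).days))
            if d in totals and d not in exclusion
        ]

    if (reference_day - diary.start).days < window:
        start = diary.start
        end = start + dt.timedelta(days=window)
        values = collect(start, end)
        usable = len(values) >= min_obs
        value = statistics.median(values) if values else float("nan")
        return BaselineEstimate(reference_day, start, end, len(values), value, usable)

    best: BaselineEstimate | None = None
    for back in range(max_walkback + 1):
        end = reference_day - dt.timedelta(days=back)
        start = end - dt.timedelta(days=window)
        if start < diary.start:
            break
        values = collect(start, end)
        if len(values) >= min_obs:
            return BaselineEstimate(
                reference_day, start, end, len(values), statistics.median(values), True
            )
        if best is None or len(values) > best.n_observed:
            value = statistics.median(values) if values else float("nan")
            best = BaselineEstimate(
                reference_day, start, end, len(values), value, False
            )
    assert best is not None
    return best


def characterize_reported(
    diary: PatientDiary,
    treatment_start_day: dt.date,
    exclusion: set[dt.date] | None = None,
    *,
    lookback_days: int = 14,
    max_duration_days: int = 42,
    baseline_min_obs: int = 4,
) -> ExacerbationEvent:
    """Characterise a treated exacerbation anchored on its treatment day.

    Onset is the earliest day within the lookback window starting a run of
    totals strictly above baseline that persists to treatment start; the
    event ends on the first post-treatment day at or below baseline (capped
    at ``max_duration_days``, flagged truncated). Duration is measured from
    treatment start, matching how recovery time is reported clinically.
    """
    totals = diary.totals()
    entry = diary.entry_on(treatment_start_day)
    if entry is None or not entry.antibiotic_start:
        raise ValueError(
            f"{diary.patient_id}: no antibiotic start recorded on "
            f"{treatment_start_day}"
        )
    exclusion = exclusion or set()

    earliest = max(diary.start, treatment_start_day - dt.timedelta(days=lookback_days))
    lookback = [
        d
        for d in (
            earliest + dt.timedelta(days=i)
            for i in range((treatment_start_day - earliest).days + 1)
        )
        if d in totals
    ]
    if not lookback:
        raise ValueError(
            f"{diary.patient_id}: no observed entries in the "
            f"{lookback_days}-day window before {treatment_start_day}"
        )

    onset = treatment_start_day
    baseline = estimate_baseline(
        diary, treatment_start_day, exclusion, min_obs=baseline_min_obs
    )
    for candidate in lookback:
        if candidate >= treatment_start_day:
            break
        cand_baseline = estimate_baseline(
            diary, candidate, exclusion, min_obs=baseline_min_obs
        )
        observed = [
            totals[d]
            for d in (
                candidate + dt.timedelta(days=i)
                for i in range((treatment_start_day - candidate).days + 1)
            )
            if d in totals
        ]
        if observed and all(v > cand_baseline.value for v in observed):
            onset = candidate
            baseline = cand_baseline
            break

    pre_days = [
        totals[d]
        for d in (
            onset + dt.timedelta(days=i)
            for i in range((treatment_start_day - onset).days)
        )
        if d in totals
    ]
    pre_period_mean = sum(pre_days) / len(pre_days) if pre_days else None

    cap = treatment_start_day + dt.timedelta(days=max_duration_days)
    end = None
    day = treatment_start_day + ONE_DAY
    while day <= min(cap, diary.end):
        if day in totals and totals[day] <= baseline.value:
            end = day
            break
        day += ONE_DAY
    truncated = end is None
    if end is None:
        end = min(cap, diary.end)

    event_days = [
        totals[d]
        for d in (onset + dt.timedelta(days=i) for i in range((end - onset).days + 1))
        if d in totals
    ]
    peak = max(event_days)
    peak_change = peak - baseline.value
    onset_time = (treatment_start_day - onset).days
    atypical = onset_time == 0 or peak_change <= 0

    event = ExacerbationEvent(
        kind="reported",
        patient_id=diary.patient_id,
        onset_day=onset,
        end_day=end,
        baseline=baseline,
        peak_score=float(peak),
        peak_change=float(peak_change),
        duration_days=(end - treatment_start_day).days,
        treatment_start=treatment_start_day,
        pre_period_mean=pre_period_mean,
        onset_time_days=onset_time,
        truncated=truncated,
        atypical=atypical,
    )
    n_dom, met = count_worsened_domains(diary, event)
    event.n_worsened_domains = n_dom
    event.met_embarc = met
    return event


def detect_unreported(
    diary: PatientDiary,
    reported_events: list[ExacerbationEvent],
    *,
    threshold: float = 3.0,
    min_days: int = 2,
    refractory_days: int = 7,
    censor_pre_days: int = 7,
    baseline_min_obs: int = 4,
) -> list[ExacerbationEvent]:
    """Detect unreported exacerbations by the sustained-rise rule.

    A candidate is a maximal run of at least ``min_days`` consecutive
    observed calendar days whose totals are all at least ``threshold`` points
    above the baseline re-estimated at the run's first day. The event ends on
    the first later day at or below that baseline. Candidates closer than
    ``refractory_days`` merge into one event. Days within
    ``censor_pre_days`` before a reported event's onset through its end are
    censored (antibiotic-treated periods are reported by definition).
    """
    if diary.span_days < 14:
        raise ValueError(
            f"{diary.patient_id}: diary spans {diary.span_days} days; "
            "need >= 14 to establish a baseline plus a qualifying run"
        )
    totals = diary.totals()
    censored: set[dt.date] = set()
    for ev in reported_events:
        day = ev.onset_day - dt.timedelta(days=censor_pre_days)
        while day <= ev.end_day:
            censored.add(day)
            day += ONE_DAY

    observed = [d for d in sorted(totals) if d not in censored]
    exclusion: set[dt.date] = set(censored)
    raw: list[ExacerbationEvent] = []
    i = 0
    while i < len(observed):
        day = observed[i]
        baseline = estimate_baseline(diary, day, exclusion, min_obs=baseline_min_obs)
        if not baseline.usable or totals[day] < baseline.value + threshold:
            i += 1
            continue
        run = [day]
        j = i + 1
        while (
            j < len(observed)
            and observed[j] == run[-1] + ONE_DAY
            and totals[observed[j]] >= baseline.value + threshold
        ):
            run.append(observed[j])
            j += 1
        if len(run) < min_days:
            i += 1
            continue
        end = None
        k = j
        while k < len(observed):
            if totals[observed[k]] <= baseline.value:
                end = observed[k]
                break
            k += 1
        truncated = end is None
        if end is None:
            end = observed[-1]
        raw.append(
            ExacerbationEvent(
                kind="unreported",
                patient_id=diary.patient_id,
                onset_day=run[0],
                end_day=end,
                baseline=baseline,
                peak_score=0.0,
                peak_change=0.0,
                duration_days=(end - run[0]).days,
                truncated=truncated,
                qualifying_run_days=len(run),
            )
        )
        day = run[0]
        while day <= end:
            exclusion.add(day)
            day += ONE_DAY
        while i < len(observed) and observed[i] <= end:
            i += 1

    merged: list[ExacerbationEvent] = []
    for ev in raw:
        if (
            merged
            and (ev.onset_day - merged[-1].end_day).days < refractory_days
        ):
            prev = merged[-1]
            prev.end_day = max(prev.end_day, ev.end_day)
            prev.duration_days = (prev.end_day - prev.onset_day).days
            prev.truncated = ev.truncated
            prev.qualifying_run_days += ev.qualifying_run_days
        else:
            merged.append(ev)

    for ev in merged:
        event_days = [
            totals[d]
            for d in (
                ev.onset_day + dt.timedelta(days=i)
                for i in range((ev.end_day - ev.onset_day).days + 1)
            )
            if d in totals
        ]
        ev.peak_score = float(max(event_days))
        ev.peak_change = float(ev.peak_score - ev.baseline.value)
        n_dom, met = count_worsened_domains(diary, ev)
        ev.n_worsened_domains = n_dom
        ev.met_embarc = met
    return merged


def count_worsened_domains(
    diary: PatientDiary, event: ExacerbationEvent
) -> tuple[int | None, bool | None]:
    """Count symptom domains worsened during an event.

    A domain counts as worsened when its item score exceeds its own
    baseline-window median on at least two consecutive observed days within
    the event. ``met_embarc`` requires at least three worsened domains (the
    consensus exacerbation definition). Returns (None, None) when the
    baseline is unusable.
    """
    if not event.baseline.usable:
        return None, None
    entries_by_day = {e.day: e for e in diary.entries}
    window_entries = [
        entries_by_day[d] for d in event.baseline.window_days if d in entries_by_day
    ]
    if not window_entries:
        return None, None
    count = 0
    for name in ITEM_NAMES:
        med = statistics.median(getattr(e, name) for e in window_entries)
        streak = 0
        worsened = False
        day = event.onset_day
        prev_observed: dt.date | None = None
        while day <= event.end_day:
            entry = entries_by_day.get(day)
            if entry is not None and getattr(entry, name) > med:
                if prev_observed == day - ONE_DAY and streak > 0:
                    streak += 1
                else:
                    streak = 1
                if streak >= 2:
                    worsened = True
                    break
                prev_observed = day
            else:
                streak = 0
                prev_observed = day if entry is not None else None
            day += ONE_DAY
        if worsened:
            count += 1
    return count, count >= 3


def stable_day_mask(
    diary: PatientDiary,
    events: list[ExacerbationEvent],
    *,
    pre_buffer: int = 7,
    post_buffer: int = 0,
):
    """Boolean stability mask over observed days (pandas Series).

    A day is stable unless it lies within ``[onset - pre_buffer,
    end + post_buffer]`` of any event.
    """
    import pandas as pd

    days = [e.day for e in diary.entries]
    mask = pd.Series(True, index=pd.Index(days, name="date"))
    for ev in events:
        lo = ev.onset_day - dt.timedelta(days=pre_buffer)
        hi = ev.end_day + dt.timedelta(days=post_buffer)
        for day in days:
            if lo <= day <= hi:
                mask[day] = False
    return mask


def detect_events(
    diary: PatientDiary,
    *,
    threshold: float = 3.0,
    min_days: int = 2,
    refractory_days: int = 7,
    censor_pre_days: int = 7,
    lookback_days: int = 14,
    max_duration_days: int = 42,
) -> list[ExacerbationEvent]:
    """Characterise all reported events, then detect unreported ones."""
    reported: list[ExacerbationEvent] = []
    exclusion: set[dt.date] = set()
    for treat_day in diary.treatment_days():
        ev = characterize_reported(
            diary,
            treat_day,
            exclusion,
            lookback_days=lookback_days,
            max_duration_days=max_duration_days,
        )
        reported.append(ev)
        day = ev.onset_day
        while day <= ev.end_day:
            exclusion.add(day)
            day += ONE_DAY
    unreported = detect_unreported(
        diary,
        reported,
        threshold=threshold,
        min_days=min_days,
        refractory_days=refractory_days,
        censor_pre_days=censor_pre_days,
    )
    return sorted(reported + unreported, key=lambda ev: ev.onset_day)


EVENT_COLUMNS = [
    "patient_id",
    "kind",
    "onset_date",
    "treatment_start_date",
    "end_date",
    "baseline",
    "peak_score",
    "peak_change",
    "pre_period_mean",
    "onset_time_days",
    "duration_days",
    "n_worsened_domains",
    "met_embarc",
    "truncated",
]


def events_to_rows(events: list[ExacerbationEvent]) -> list[dict]:
    rows = []
    for ev in events:
        rows.append(
            {
                "patient_id": ev.patient_id,
                "kind": ev.kind,
                "onset_date": ev.onset_day.isoformat(),
                "treatment_start_date": (
                    ev.treatment_start.isoformat() if ev.treatment_start else ""
                ),
                "end_date": ev.end_day.isoformat(),
                "baseline": ev.baseline.value,
                "peak_score": ev.peak_score,
                "peak_change": ev.peak_change,
                "pre_period_mean": (
                    "" if ev.pre_period_mean is None else round(ev.pre_period_mean, 3)
                ),
                "onset_time_days": (
                    "" if ev.onset_time_days is None else ev.onset_time_days
                ),
                "duration_days": ev.duration_days,
                "n_worsened_domains": (
                    "" if ev.n_worsened_domains is None else ev.n_worsened_domains
                ),
                "met_embarc": "" if ev.met_embarc is None else int(ev.met_embarc),
                "truncated": int(ev.truncated),
            }
        )
    return rows


def write_events_csv(events: list[ExacerbationEvent], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=EVENT_COLUMNS)
        writer.writeheader()
        writer.writerows(events_to_rows(events))
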