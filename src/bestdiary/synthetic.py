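"""Synthetic bronchiectasis cohorts with planted exacerbations.

Generates daily BEST diaries, correlated anchor questionnaires and
ground-truth event labels so that every downstream stage (detection,
characterisation, psychometrics) can be exercised and checked against known
truth. Defaults are calibrated to the published cohort kinetics: baseline
7.1 (SD 2.2), reported exacerbations peaking +9.1 (SD 2.5) with a ~4.8-day
prodrome and 15.3-day recovery, unreported exacerbations of +4.7 (SD 1.5,
range 3-8) lasting 10 days (SD 3.8), and anchor correlations CAT/SGRQ 0.61,
LCQ -0.52, 6MWT -0.46.

Day-to-day noise is Gaussian on the latent total with per-patient SD
``cv * baseline / 100``. The per-patient coefficient of variation is derived
from a common daily jitter scale (``daily_sd``) as ``100 * daily_sd /
baseline``, capped at the top of ``daily_cv_range``: the wide published CV
range is
a denominator effect (low-baseline patients), not evidence of multi-point
daily swings, which would trip the 48-h detection rule far more often than
the published event counts allow.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .instrument import (
    ITEMS,
    ITEM_NAMES,
    MAX_TOTAL,
    DiaryEntry,
    PatientDiary,
)

__all__ = [
    "AnchorSpec",
    "EventTemplate",
    "SyntheticConfig",
    "TruthEvent",
    "PatientTruth",
    "GroundTruth",
    "generate_patient",
    "generate_cohort",
    "decompose_total_to_items",
    "reported_offsets",
    "unreported_offsets",
    "config_with_planted_anchor_slope",
    "write_truth_csv",
    "anchors_to_frame",
]

DEFAULT_START_DATE = dt.date(2014, 1, 6)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class AnchorSpec:
    """Marginal distribution and baseline correlation of one anchor."""

    mean: float
    sd: float
    corr: float  # Pearson correlation with the latent baseline BEST score
    lo: float
    hi: float


def _default_anchors() -> dict[str, AnchorSpec]:
    return {
        "cat": AnchorSpec(19.1, 6.1, 0.61, 0.0, 40.0),
        "sgrq_total": AnchorSpec(41.5, 17.0, 0.61, 0.0, 100.0),
        # Symptom domain marginals are not published; plausible values are
        # assumed, with the published correlation 0.52.
        "sgrq_symptom": AnchorSpec(55.0, 18.0, 0.52, 0.0, 100.0),
        # LCQ marginals are not published; 14 (SD 3) assumed within the
        # instrument's 3-21 range.
        "lcq": AnchorSpec(14.0, 3.0, -0.52, 3.0, 21.0),
        "six_mwt_m": AnchorSpec(439.0, 104.0, -0.46, 0.0, math.inf),
    }


@dataclass(frozen=True)
class EventTemplate:
    """A sampled symptom excursion: additive offsets to the latent baseline.

    ``offsets[k]`` is the offset on day ``onset + k``; offsets are positive
    through the event and return to 0 on the day after recovery completes.
    """

    kind: str  # "reported" | "unreported"
    prodrome_days: int
    peak_change: float
    recovery_days: int
    report_lag_days: int | None = None  # reported only

    def __post_init__(self) -> None:
        if self.kind not in ("reported", "unreported"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.prodrome_days + self.recovery_days < 2:
            raise ValueError("event template must span at least 2 days")
        if self.peak_change <= 0:
            raise ValueError("peak_change must be positive")

    def offsets(self) -> np.ndarray:
        if self.kind == "reported":
            assert self.report_lag_days is not None
            return reported_offsets(
                self.report_lag_days, self.peak_change, self.recovery_days
            )
        return unreported_offsets(
            self.peak_change, self.prodrome_days + self.recovery_days
        )


def reported_offsets(lag: int, peak: float, duration: int) -> np.ndarray:
    """Offset profile of a reported (treated) exacerbation.

    Index 0 is symptom onset; index ``lag`` is the treatment-start day
    (the peak); recovery completes ``duration`` days after treatment, where
    the offset first returns to 0. The rise is convex (slow start,
    accelerating), the decay drops sharply off the peak then declines
    through a shallow tail that stays just above baseline until recovery —
    the shape that makes "return to baseline" occur at the nominal duration
    even under daily noise.
    """
    if lag < 0 or duration < 2:
        raise ValueError("need lag >= 0 and duration >= 2")
    offsets = np.zeros(lag + duration + 1)
    for k in range(lag + 1):
        rise = peak * ((k + 1) / (lag + 1)) ** 1.5
        offsets[k] = max(rise, 0.8)
    tail = 2.0
    drop = 0.65 * peak
    for u in range(1, duration):
        frac = (1.0 - (u - 1) / (duration - 1)) ** 1.2
        offsets[lag + u] = tail + max(drop - tail, 0.0) * frac
    offsets[lag + duration] = 0.0
    return offsets


def unreported_offsets(change: float, duration: int) -> np.ndarray:
    """Offset profile of an unreported exacerbation.

    Starts at +3 (the detection threshold), rises to ``change`` at roughly a
    third of the duration, decays steeply off the peak, then lingers ~2
    points above baseline before returning to 0 on day ``duration``.
    """
    if duration < 4:
        raise ValueError("unreported events need duration >= 4 days")
    change = max(change, 3.0)
    k_peak = max(1, round(duration / 3))
    offsets = np.zeros(duration + 1)
    for k in range(k_peak + 1):
        offsets[k] = 3.0 + (change - 3.0) * (k / k_peak) ** 2
    tail = 2.2
    for k in range(k_peak + 1, duration):
        frac = (1.0 - (k - k_peak) / (duration - k_peak)) ** 2
        offsets[k] = tail + max(change - tail, 0.0) * frac
    offsets[duration] = 0.0
    return offsets


@dataclass
class SyntheticConfig:
    """All generator parameters; defaults calibrated to published cohort kinetics."""

    n_patients: int = 21
    followup_days: int = 180
    start_date: dt.date = DEFAULT_START_DATE

    # Between-patient baseline distribution (stable BEST level).
    baseline_mean: float = 7.1
    baseline_sd_between: float = 2.2
    baseline_range: tuple[float, float] = (1.0, 16.0)

    # Day-to-day noise: common jitter scale; per-patient CV capped at the
    # top of the published range.
    daily_sd: float = 1.15
    daily_cv_range: tuple[float, float] = (16.1, 97.8)

    # Event frequencies (per patient-year).
    reported_rate_per_year: float = 1.5
    unreported_rate_per_year: float = 1.2

    # Reported (treated) event kinetics.
    report_lag_mean: float = 4.8
    report_lag_sd: float = 3.5
    report_lag_range: tuple[int, int] = (1, 10)
    reported_change_mean: float = 9.1
    reported_change_sd: float = 2.5
    reported_change_range: tuple[float, float] = (5.0, 14.0)
    reported_duration_mean: float = 15.3
    reported_duration_sd: float = 5.7
    reported_duration_range: tuple[int, int] = (5, 28)

    # Unreported event kinetics.
    unreported_change_mean: float = 4.7
    unreported_change_sd: float = 1.5
    unreported_change_range: tuple[float, float] = (3.0, 8.0)
    unreported_duration_mean: float = 10.0
    unreported_duration_sd: float = 3.8
    unreported_duration_range: tuple[int, int] = (4, 20)

    # Minimum clear days between planted event spans.
    event_gap_days: int = 14

    anchors: dict[str, AnchorSpec] = field(default_factory=_default_anchors)

    missing_day_prob: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        if self.followup_days < 14:
            errors.append("followup_days must be >= 14")
        for name in (
            "baseline_sd_between",
            "daily_sd",
            "reported_change_sd",
            "reported_duration_sd",
            "unreported_change_sd",
            "unreported_duration_sd",
            "report_lag_sd",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.reported_rate_per_year < 0 or self.unreported_rate_per_year < 0:
            errors.append("event rates must be >= 0")
        if not 0 <= self.missing_day_prob < 1:
            errors.append("missing_day_prob must be in [0, 1)")
        lo, hi = self.daily_cv_range
        if not 0 < lo <= hi:
            errors.append("daily_cv_range must be 0 < low <= high")
        for name, spec in self.anchors.items():
            if spec.sd < 0:
                errors.append(f"anchor {name}: sd must be >= 0")
            if not -1 < spec.corr < 1:
                errors.append(f"anchor {name}: correlation must be in (-1, 1)")
        if not errors:
            # One-factor structure is PSD whenever |corr| < 1, but guard the
            # assembled matrix anyway so custom structures fail early.
            corr = self.correlation_matrix()
            eigvals = np.linalg.eigvalsh(corr)
            if eigvals.min() < -1e-9:
                errors.append(
                    "implied anchor correlation matrix is not positive "
                    f"semi-definite (min eigenvalue {eigvals.min():.3g})"
                )
        if errors:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(errors))

    def correlation_matrix(self) -> np.ndarray:
        """Implied correlation matrix of (baseline, anchors...).

        Anchors load on the baseline factor only, so the anchor-anchor
        correlation is the product of their baseline correlations.
        """
        rs = np.array([spec.corr for spec in self.anchors.values()])
        k = len(rs) + 1
        corr = np.empty((k, k))
        corr[0, 0] = 1.0
        corr[0, 1:] = corr[1:, 0] = rs
        corr[1:, 1:] = np.outer(rs, rs)
        np.fill_diagonal(corr, 1.0)
        return corr

    def patient_noise_sd(self, baseline: float) -> tuple[float, float]:
        """(cv_percent, daily sd) for a patient with the given baseline.

        The CV is the common jitter scale over the patient's own baseline,
        capped at the top of ``daily_cv_range`` so near-floor baselines do
        not get absurd noise. The bottom of the range is the published
        observed minimum across a small cohort, not a per-patient floor:
        forcing it would inflate day-to-day noise for every high-baseline
        patient and trip the 48-h rule far more often than published event
        counts allow.
        """
        cv = float(min(100.0 * self.daily_sd / baseline, self.daily_cv_range[1]))
        return cv, cv * baseline / 100.0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["start_date"] = self.start_date.isoformat()
        out["anchors"] = {
            name: dataclasses.asdict(spec) for name, spec in self.anchors.items()
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, default=str)


def config_with_planted_anchor_slope(
    config: SyntheticConfig, anchor: str, slope: float
) -> SyntheticConfig:
    """Return a config whose BEST-on-anchor regression slope equals ``slope``.

    The population slope of baseline BEST on an anchor is
    ``corr * sd_best / sd_anchor``; the anchor SD is adjusted to plant the
    requested slope while keeping the correlation fixed.
    """
    spec = config.anchors[anchor]
    if spec.corr == 0 or slope == 0:
        raise ValueError("cannot plant a slope with zero correlation")
    new_sd = abs(spec.corr) * config.baseline_sd_between / abs(slope)
    anchors = dict(config.anchors)
    corr = abs(spec.corr) if slope > 0 else -abs(spec.corr)
    anchors[anchor] = dataclasses.replace(spec, sd=new_sd, corr=corr)
    return dataclasses.replace(config, anchors=anchors)


@dataclass(frozen=True)
class TruthEvent:
    """A planted event, in truth coordinates."""

    kind: str
    onset_day: dt.date
    treatment_start: dt.date | None
    peak_day: dt.date
    peak_change: float
    duration_days: int  # reported: days from treatment to recovery; unreported: onset to recovery


@dataclass
class PatientTruth:
    patient_id: str
    baseline: float
    cv_percent: float
    daily_sd: float
    events: list[TruthEvent]
    anchors: dict[str, float]


GroundTruth = dict[str, PatientTruth]


def decompose_total_to_items(
    latent_total: float,
    previous_items: tuple[int, ...] | None,
    *,
    event_active: bool = False,
) -> tuple[int, ...]:
    """Decompose a latent daily total into six valid item scores.

    The returned scores sum exactly to ``round(clamp(latent_total, 0, 26))``.
    Movement from ``previous_items`` is limited to two steps per item per day
    on each item's ordinal ladder (temporal smoothness), relaxed only when no
    smooth allocation can reach the target. The cold/flu item leaves 0 only
    while an event is active (systemic symptoms accompany exacerbations) and
    decays once it ends.
    """
    target = _round_half_up(min(max(latent_total, 0.0), float(MAX_TOTAL)))
    ladders = [sorted(item.allowed_levels) for item in ITEMS]
    cold_idx = ITEM_NAMES.index("cold_flu")

    if previous_items is None:
        prev_pos = [0] * len(ITEMS)
        max_step = max(len(ladder) for ladder in ladders)  # unconstrained
    else:
        prev_pos = [
            ladders[i].index(previous_items[i]) for i in range(len(ITEMS))
        ]
        max_step = 2

    def bounds(relax: bool) -> list[tuple[int, int]]:
        out = []
        for i, ladder in enumerate(ladders):
            top = len(ladder) - 1
            lo = 0 if relax else max(0, prev_pos[i] - max_step)
            hi = top if relax else min(top, prev_pos[i] + max_step)
            if i == cold_idx and not event_active and not relax:
                # decay toward 0, never rise, outside events
                hi = min(hi, max(0, prev_pos[i] - 1))
                lo = min(lo, hi)
            out.append((lo, hi))
        return out

    # Increment order spreads load across domains plausibly for a symptom
    # diary: cough and sputum move first, systemic symptoms last.
    order = [
        ITEM_NAMES.index(n)
        for n in (
            "cough",
            "sputum_volume",
            "fatigue",
            "breathlessness",
            "sputum_colour",
            "cold_flu",
        )
    ]

    for relax in (False, True):
        lohi = bounds(relax)
        pos = [min(max(prev_pos[i], lohi[i][0]), lohi[i][1]) for i in range(6)]
        current = sum(ladders[i][pos[i]] for i in range(6))
        delta = target - current
        for _ in range(64):
            if delta == 0:
                break
            moved = False
            for i in order:
                if delta == 0:
                    break
                lo, hi = lohi[i]
                if delta > 0 and pos[i] < hi:
                    gain = ladders[i][pos[i] + 1] - ladders[i][pos[i]]
                    if gain <= delta:
                        pos[i] += 1
                        delta -= gain
                        moved = True
                elif delta < 0 and pos[i] > lo:
                    loss = ladders[i][pos[i]] - ladders[i][pos[i] - 1]
                    if loss <= -delta:
                        pos[i] -= 1
                        delta += loss
                        moved = True
            if not moved:
                # Only the cold/flu 2->5 jump can strand the greedy walk;
                # take it and let the loop walk other items back down.
                i = cold_idx
                lo, hi = lohi[i]
                if delta > 0 and pos[i] < hi:
                    delta -= ladders[i][pos[i] + 1] - ladders[i][pos[i]]
                    pos[i] += 1
                elif delta < 0 and pos[i] > lo:
                    delta += ladders[i][pos[i]] - ladders[i][pos[i] - 1]
                    pos[i] -= 1
                else:
                    break
        if delta == 0:
            return tuple(ladders[i][pos[i]] for i in range(6))
    raise AssertionError(
        f"could not allocate total {target} (previous {previous_items})"
    )  # pragma: no cover - caps sum to 26, always reachable


def _sample_events(config: SyntheticConfig, rng: np.random.Generator):
    """Sample non-overlapping event placements for one patient.

    Returns a list of dicts with keys kind, onset (day index), span
    (array of offsets), lag, change, duration.
    """
    years = config.followup_days / 365.0
    last_error: RuntimeError | None = None
    # A crowded draw (many events for the follow-up length) may not admit a
    # non-overlapping layout; resample the whole layout a bounded number of
    # times before giving up.
    for _ in range(50):
        n_rep = rng.poisson(config.reported_rate_per_year * years)
        n_unrep = rng.poisson(config.unreported_rate_per_year * years)
        try:
            return _place_events(config, rng, n_rep, n_unrep)
        except RuntimeError as exc:
            last_error = exc
    raise RuntimeError(
        "could not place planted events without overlap after repeated "
        "resampling; increase followup_days or lower the event rates"
    ) from last_error


def _place_events(
    config: SyntheticConfig, rng: np.random.Generator, n_rep: int, n_unrep: int
):
    placed: list[dict] = []
    occupied: list[tuple[int, int]] = []

    def try_place(kind: str) -> None:
        for _ in range(200):
            if kind == "reported":
                lag = int(
                    np.clip(
                        _round_half_up(
                            rng.normal(config.report_lag_mean, config.report_lag_sd)
                        ),
                        *config.report_lag_range,
                    )
                )
                change = float(
                    np.clip(
                        rng.normal(
                            config.reported_change_mean, config.reported_change_sd
                        ),
                        *config.reported_change_range,
                    )
                )
                duration = int(
                    np.clip(
                        _round_half_up(
                            rng.normal(
                                config.reported_duration_mean,
                                config.reported_duration_sd,
                            )
                        ),
                        *config.reported_duration_range,
                    )
                )
                offsets = reported_offsets(lag, change, duration)
            else:
                change = float(
                    np.clip(
                        rng.normal(
                            config.unreported_change_mean,
                            config.unreported_change_sd,
                        ),
                        *config.unreported_change_range,
                    )
                )
                duration = int(
                    np.clip(
                        _round_half_up(
                            rng.normal(
                                config.unreported_duration_mean,
                                config.unreported_duration_sd,
                            )
                        ),
                        *config.unreported_duration_range,
                    )
                )
                lag = None
                offsets = unreported_offsets(change, duration)
            span = len(offsets)
            lo, hi = 8, config.followup_days - span - 1
            if hi <= lo:
                continue
            onset = int(rng.integers(lo, hi + 1))
            window = (onset - config.event_gap_days, onset + span + config.event_gap_days)
            if any(not (window[1] <= s or window[0] >= e) for s, e in occupied):
                continue
            occupied.append((onset, onset + span))
            placed.append(
                dict(
                    kind=kind,
                    onset=onset,
                    offsets=offsets,
                    lag=lag,
                    change=change,
                    duration=duration,
                )
            )
            return
        raise RuntimeError(
            "could not place all planted events without overlap; "
            "increase followup_days or lower the event rates"
        )

    for _ in range(n_rep):
        try_place("reported")
    for _ in range(n_unrep):
        try_place("unreported")
    return sorted(placed, key=lambda ev: ev["onset"])


def generate_patient(
    config: SyntheticConfig, patient_index: int
) -> tuple[PatientDiary, PatientTruth]:
    """Generate one patient's diary and ground truth.

    The random stream is derived from ``(config.seed, patient_index)`` so
    cohorts are reproducible and patients order-independent.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, patient_index])
    pid = f"P{patient_index + 1:03d}"

    z0 = rng.standard_normal()
    lo_b, hi_b = config.baseline_range
    baseline = float(
        np.clip(config.baseline_mean + config.baseline_sd_between * z0, lo_b, hi_b)
    )
    cv, noise_sd = config.patient_noise_sd(baseline)

    anchors: dict[str, float] = {}
    for name, spec in config.anchors.items():
        e = rng.standard_normal()
        z = spec.corr * z0 + math.sqrt(1.0 - spec.corr**2) * e
        anchors[name] = float(np.clip(spec.mean + spec.sd * z, spec.lo, spec.hi))

    events = _sample_events(config, rng)

    n = config.followup_days
    offsets = np.zeros(n)
    for ev in events:
        seg = ev["offsets"]
        offsets[ev["onset"] : ev["onset"] + len(seg)] += seg
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    latent = baseline + offsets + noise

    keep = rng.random(n) >= config.missing_day_prob
    treatment_idx = {
        ev["onset"] + ev["lag"] for ev in events if ev["kind"] == "reported"
    }
    # Treatment start is study-recorded (the patient phoned the team), so
    # that day is never a missing diary day.
    for idx in treatment_idx:
        keep[idx] = True

    entries: list[DiaryEntry] = []
    prev_items: tuple[int, ...] | None = None
    for day_idx in range(n):
        items = decompose_total_to_items(
            latent[day_idx], prev_items, event_active=offsets[day_idx] > 0
        )
        prev_items = items
        if not keep[day_idx]:
            continue
        day = config.start_date + dt.timedelta(days=day_idx)
        is_treat = day_idx in treatment_idx
        entries.append(
            DiaryEntry(
                patient_id=pid,
                day=day,
                reported_flag=is_treat,
                antibiotic_start=is_treat,
                **dict(zip(ITEM_NAMES, items)),
            )
        )

    truth_events = []
    for ev in events:
        onset = config.start_date + dt.timedelta(days=int(ev["onset"]))
        if ev["kind"] == "reported":
            treat = onset + dt.timedelta(days=int(ev["lag"]))
            peak_day = treat
        else:
            treat = None
            k_peak = max(1, round(ev["duration"] / 3))
            peak_day = onset + dt.timedelta(days=k_peak)
        truth_events.append(
            TruthEvent(
                kind=ev["kind"],
                onset_day=onset,
                treatment_start=treat,
                peak_day=peak_day,
                peak_change=ev["change"],
                duration_days=int(ev["duration"]),
            )
        )

    diary = PatientDiary(pid, entries)
    truth = PatientTruth(
        patient_id=pid,
        baseline=baseline,
        cv_percent=cv,
        daily_sd=noise_sd,
        events=truth_events,
        anchors=anchors,
    )
    return diary, truth


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, PatientDiary], GroundTruth]:
    """Generate ``config.n_patients`` independent patients."""
    config.validate()
    diaries: dict[str, PatientDiary] = {}
    truth: GroundTruth = {}
    for i in range(config.n_patients):
        diary, patient_truth = generate_patient(config, i)
        diaries[diary.patient_id] = diary
        truth[diary.patient_id] = patient_truth
    return diaries, truth


def anchors_to_frame(truth: GroundTruth):
    """Baseline-visit anchor records as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for pid in sorted(truth):
        row = {"patient_id": pid, "visit": "baseline"}
        row.update(truth[pid].anchors)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame[
        ["patient_id", "visit", "sgrq_total", "sgrq_symptom", "cat", "lcq", "six_mwt_m"]
    ]


def write_truth_csv(truth: GroundTruth, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "patient_id",
                "kind",
                "onset_date",
                "treatment_start_date",
                "peak_change",
                "duration_days",
            ]
        )
        for pid in sorted(truth):
            for ev in truth[pid].events:
                writer.writerow(
                    [
                        pid,
                        ev.kind,
                        ev.onset_day.isoformat(),
                        ev.treatment_start.isoformat() if ev.treatment_start else "",
                        f"{ev.peak_change:.3f}",
                        ev.duration_days,
                    ]
                )
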