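"""Convergent validity, MCID estimation and cutoff performance.

Three MCID approaches are implemented, mirroring standard practice for new
patient-reported outcome instruments:

* distribution-based: half the between-participant SD of baseline scores;
* anchor-based: regress the diary score on an established instrument with a
  known MCID (SGRQ 4 points, CAT 2 points, LCQ 1.3 points) and convert
  through the regression slope, provided |r| > 0.3;
* event-onset: the mean rise from baseline over the pre-treatment
  (prodromal) period of reported exacerbations.

Also provided: OLS/Pearson convergent-validity fits, paired t-tests,
within-subject variability (SD and CV over stable days), and the
sensitivity/specificity sweep of change-score cutoffs for detecting treated
exacerbations against sampled stable windows.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detection import ExacerbationEvent, estimate_baseline
from .instrument import PatientDiary

__all__ = [
    "CorrelationResult",
    "MCIDEstimate",
    "CutoffRow",
    "VariabilityResult",
    "ValidityReport",
    "linear_fit",
    "anchor_mcid",
    "half_sd_mcid",
    "exacerbation_onset_mcid",
    "cutoff_performance",
    "sample_stable_window_changes",
    "within_subject_variability",
    "paired_t",
    "build_validity_report",
    "ANCHOR_MCID_POINTS",
]

P_FLOOR = 1e-15

#: Published MCIDs of the anchor instruments, in their own units.
ANCHOR_MCID_POINTS = {"sgrq_total": 4.0, "cat": 2.0, "lcq": 1.3}


@dataclass(frozen=True)
class CorrelationResult:
    anchor_name: str
    n: int
    slope: float
    intercept: float
    r: float
    p: float


@dataclass(frozen=True)
class MCIDEstimate:
    method: str  # half_sd | anchor | exacerbation_onset
    value: float
    anchor_name: str | None = None


@dataclass(frozen=True)
class CutoffRow:
    cutoff: float
    sensitivity: float  # percent of treated events with change >= cutoff
    specificity: float  # percent of stable windows with change < cutoff
    n_events: int
    n_stable: int


@dataclass(frozen=True)
class VariabilityResult:
    patient_id: str
    n_stable_days: int
    sd: float | None
    cv_percent: float | None
    reason: str | None = None


class DegenerateDataError(ValueError):
    """The data admit no defined estimate (zero variance, too few points)."""


def linear_fit(x, y, anchor_name: str = "") -> CorrelationResult:
    """OLS of ``y`` on ``x`` with Pearson r and its two-sided p-value.

    Missing values are dropped pairwise. The p-value is the usual
    t = r*sqrt((n-2)/(1-r^2)) against Student-t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise DegenerateDataError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            f"zero variance in {'x' if np.ptp(x) == 0 else 'y'}; "
            "correlation undefined"
        )
    fit = stats.linregress(x, y)
    p = max(float(fit.pvalue), P_FLOOR)
    return CorrelationResult(
        anchor_name=anchor_name,
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=p,
    )


def anchor_mcid(fit: CorrelationResult, anchor_mcid_points: float) -> MCIDEstimate:
    """Convert an anchor's MCID to the BEST scale through the regression.

    With BEST regressed on the anchor, a clinically meaningful change of
    ``anchor_mcid_points`` on the anchor corresponds to
    ``|slope| * anchor_mcid_points`` BEST points. The anchor is only
    eligible when |r| > 0.3.
    """
    if anchor_mcid_points <= 0:
        raise ValueError("anchor MCID must be positive")
    if abs(fit.r) <= 0.3:
        raise DegenerateDataError(
            f"anchor {fit.anchor_name or '?'} ineligible: |r| = {abs(fit.r):.2f} <= 0.3"
        )
    return MCIDEstimate(
        method="anchor",
        anchor_name=fit.anchor_name or None,
        value=abs(fit.slope) * anchor_mcid_points,
    )


def half_sd_mcid(scores) -> MCIDEstimate:
    """Distribution-based MCID: half the sample SD of participants' scores."""
    values = [float(v) for v in scores if not (isinstance(v, float) and math.isnan(v))]
    if len(values) < 2:
        raise DegenerateDataError("need >= 2 participants for the half-SD method")
    return MCIDEstimate(method="half_sd", value=statistics.stdev(values) / 2.0)


def exacerbation_onset_mcid(events: list[ExacerbationEvent]) -> MCIDEstimate:
    """Event-onset MCID: mean prodromal rise of reported exacerbations.

    For each treated event with a usable baseline and a non-empty
    pre-treatment period, the change is the pre-period mean minus the
    baseline median.
    """
    changes = [
        ev.pre_period_mean - ev.baseline.value
        for ev in events
        if ev.kind == "reported"
        and ev.pre_period_mean is not None
        and ev.baseline.usable
    ]
    if not changes:
        raise DegenerateDataError("no reported events with a usable pre-period")
    return MCIDEstimate(
        method="exacerbation_onset", value=sum(changes) / len(changes)
    )


def cutoff_performance(
    event_changes, stable_changes, cutoffs
) -> list[CutoffRow]:
    """Sensitivity/specificity of change-score cutoffs.

    ``event_changes`` are peak changes of treated exacerbations;
    ``stable_changes`` are change scores of sampled stable windows.
    Sensitivity(c) is the percentage of events at or above c; specificity(c)
    the percentage of stable windows below c.
    """
    event_changes = np.asarray(list(event_changes), dtype=float)
    stable_changes = np.asarray(list(stable_changes), dtype=float)
    if event_changes.size == 0:
        raise DegenerateDataError("no treated events to evaluate cutoffs on")
    if stable_changes.size == 0:
        raise DegenerateDataError("no stable windows to evaluate cutoffs on")
    rows = []
    for c in cutoffs:
        sens = 100.0 * float(np.mean(event_changes >= c))
        spec = 100.0 * float(np.mean(stable_changes < c))
        rows.append(
            CutoffRow(
                cutoff=float(c),
                sensitivity=sens,
                specificity=spec,
                n_events=int(event_changes.size),
                n_stable=int(stable_changes.size),
            )
        )
    return rows


def sample_stable_window_changes(
    diary: PatientDiary,
    stable_mask,
    *,
    window_days: int = 14,
    lead_days: int = 7,
    min_lead_obs: int = 4,
    min_tail_obs: int = 3,
) -> list[float]:
    """Change scores of non-overlapping stable windows.

    Stable days are tiled into consecutive ``window_days``-day calendar
    blocks; each block's change is the maximum total over its tail measured
    against the median of its leading week — the stable-period analogue of
    an exacerbation's peak change.
    """
    totals = diary.totals()
    stable_days = sorted(d for d, ok in stable_mask.items() if ok)
    changes: list[float] = []
    runs: list[list[dt.date]] = []
    for day in stable_days:
        if runs and (day - runs[-1][-1]).days == 1:
            runs[-1].append(day)
        else:
            runs.append([day])
    for run in runs:
        for i in range(0, len(run) - window_days + 1, window_days):
            block = run[i : i + window_days]
            lead_end = block[0] + dt.timedelta(days=lead_days)
            lead = [totals[d] for d in block if d < lead_end]
            tail = [totals[d] for d in block if d >= lead_end]
            if len(lead) < min_lead_obs or len(tail) < min_tail_obs:
                continue
            changes.append(float(max(tail) - statistics.median(lead)))
    return changes


def within_subject_variability(
    diary: PatientDiary, stable_mask, *, min_days: int = 8
) -> VariabilityResult:
    """Within-subject SD and CV (%) of totals over stable days."""
    totals = diary.totals()
    values = [float(totals[d]) for d, ok in stable_mask.items() if ok]
    if len(values) < min_days:
        return VariabilityResult(
            diary.patient_id,
            len(values),
            None,
            None,
            reason=f"only {len(values)} stable days (< {min_days})",
        )
    sd = statistics.stdev(values)
    mean = statistics.fmean(values)
    if mean == 0:
        return VariabilityResult(
            diary.patient_id, len(values), sd, None, reason="zero mean"
        )
    return VariabilityResult(diary.patient_id, len(values), sd, 100.0 * sd / mean)


def paired_t(before, after) -> tuple[float, float]:
    """Paired Student t-test; returns (t, two-sided p).

    Identical pairs give (0, 1). A zero-variance nonzero mean difference
    yields an infinite t with p reported at the 1e-15 floor.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise DegenerateDataError("need >= 2 pairs")
    diff = after - before
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff[0]), P_FLOOR
    res = stats.ttest_rel(after, before)
    return float(res.statistic), max(float(res.pvalue), P_FLOOR)


def _mean_sd(values):
    values = [v for v in values if v is not None and not math.isnan(v)]
    if not values:
        return None, None, 0
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd, len(values)


@dataclass
class ValidityReport:
    """All validation statistics of one cohort, in one serialisable object."""

    correlations: list[CorrelationResult] = field(default_factory=list)
    not_computable: dict[str, str] = field(default_factory=dict)
    mcids: list[MCIDEstimate] = field(default_factory=list)
    cutoff_table: list[CutoffRow] = field(default_factory=list)
    variability: list[VariabilityResult] = field(default_factory=list)
    cv_range: tuple[float, float] | None = None
    event_summary: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "correlations": [dataclasses.asdict(c) for c in self.correlations],
            "not_computable": dict(self.not_computable),
            "mcids": [dataclasses.asdict(m) for m in self.mcids],
            "cutoff_table": [dataclasses.asdict(r) for r in self.cutoff_table],
            "variability": [dataclasses.asdict(v) for v in self.variability],
            "cv_range": list(self.cv_range) if self.cv_range else None,
            "event_summary": self.event_summary,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as handle:
                handle.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        lines = ["# BEST diary validity report", ""]
        lines.append("## Convergent validity (baseline score vs anchors)")
        lines.append("")
        lines.append("| anchor | n | slope | r | p |")
        lines.append("|---|---|---|---|---|")
        for c in self.correlations:
            p = f"<{P_FLOOR:g}" if c.p <= P_FLOOR else f"{c.p:.4g}"
            lines.append(
                f"| {c.anchor_name} | {c.n} | {c.slope:.3f} | {c.r:.2f} | {p} |"
            )
        for name, reason in self.not_computable.items():
            lines.append(f"| {name} | - | - | - | not computable: {reason} |")
        lines.append("")
        lines.append("## MCID estimates (BEST points)")
        lines.append("")
        for m in self.mcids:
            label = m.method + (f" ({m.anchor_name})" if m.anchor_name else "")
            lines.append(f"- {label}: {m.value:.2f}")
        lines.append("")
        lines.append("## Change-score cutoffs for treated exacerbations")
        lines.append("")
        lines.append("| cutoff | sensitivity % | specificity % | events | stable windows |")
        lines.append("|---|---|---|---|---|")
        for row in self.cutoff_table:
            lines.append(
                f"| {row.cutoff:g} | {row.sensitivity:.0f} | {row.specificity:.0f} "
                f"| {row.n_events} | {row.n_stable} |"
            )
        lines.append("")
        lines.append("## Reported vs unreported exacerbations")
        lines.append("")
        lines.append("| quantity | reported | unreported |")
        lines.append("|---|---|---|")
        rep = self.event_summary.get("reported", {})
        unrep = self.event_summary.get("unreported", {})

        def cell(summary, key):
            entry = summary.get(key)
            if not entry or entry.get("mean") is None:
                return "n/a"
            return f"{entry['mean']:.1f} (SD {entry['sd']:.1f}, n={entry['n']})"

        for key, label in [
            ("onset_time_days", "Onset time (days)"),
            ("peak_change", "Change from baseline"),
            ("peak_score", "Peak score"),
            ("duration_days", "Duration (days)"),
        ]:
            right = "Not applicable" if key == "onset_time_days" else cell(unrep, key)
            lines.append(f"| {label} | {cell(rep, key)} | {right} |")
        lines.append("")
        if self.cv_range:
            lines.append(
                "Within-subject CV over stable days ranged "
                f"{self.cv_range[0]:.1f}% to {self.cv_range[1]:.1f}%."
            )
            lines.append("")
        return "\n".join(lines)


def build_validity_report(
    diaries: dict[str, PatientDiary],
    anchors_frame,
    events: list[ExacerbationEvent],
    *,
    cutoffs=(4.0, 5.0, 6.0),
    stable_pre_buffer: int = 7,
) -> ValidityReport:
    """Assemble the full validity report for a cohort.

    ``anchors_frame`` holds baseline-visit anchor questionnaire scores; the
    per-patient baseline BEST score is the median of the first study week.
    """
    from .detection import stable_day_mask

    report = ValidityReport()

    baselines: dict[str, float] = {}
    for pid, diary in diaries.items():
        est = estimate_baseline(diary, diary.start + dt.timedelta(days=7))
        if est.usable:
            baselines[pid] = est.value

    base = anchors_frame[anchors_frame["visit"] == "baseline"].copy()
    base["best_baseline"] = base["patient_id"].map(baselines)
    base = base.dropna(subset=["best_baseline"])

    for anchor in ("cat", "sgrq_total", "sgrq_symptom", "lcq", "six_mwt_m"):
        try:
            fit = linear_fit(base[anchor], base["best_baseline"], anchor_name=anchor)
            report.correlations.append(fit)
        except DegenerateDataError as exc:
            report.not_computable[anchor] = str(exc)

    try:
        report.mcids.append(half_sd_mcid(list(baselines.values())))
    except DegenerateDataError as exc:
        report.not_computable["half_sd_mcid"] = str(exc)
    for fit in report.correlations:
        points = ANCHOR_MCID_POINTS.get(fit.anchor_name)
        if points is None:
            continue
        try:
            report.mcids.append(anchor_mcid(fit, points))
        except DegenerateDataError as exc:
            report.not_computable[f"anchor_mcid_{fit.anchor_name}"] = str(exc)
    try:
        report.mcids.append(exacerbation_onset_mcid(events))
    except DegenerateDataError as exc:
        report.not_computable["exacerbation_onset_mcid"] = str(exc)

    by_patient: dict[str, list[ExacerbationEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    stable_changes: list[float] = []
    for pid, diary in diaries.items():
        mask = stable_day_mask(
            diary, by_patient.get(pid, []), pre_buffer=stable_pre_buffer
        )
        report.variability.append(within_subject_variability(diary, mask))
        stable_changes.extend(sample_stable_window_changes(diary, mask))

    cvs = [v.cv_percent for v in report.variability if v.cv_percent is not None]
    if cvs:
        report.cv_range = (min(cvs), max(cvs))

    reported_changes = [
        ev.peak_change for ev in events if ev.kind == "reported" and ev.baseline.usable
    ]
    try:
        report.cutoff_table = cutoff_performance(
            reported_changes, stable_changes, cutoffs
        )
    except DegenerateDataError as exc:
        report.not_computable["cutoff_table"] = str(exc)

    for kind in ("reported", "unreported"):
        kind_events = [ev for ev in events if ev.kind == kind]
        summary: dict[str, dict] = {}
        for key, getter in [
            ("peak_change", lambda e: e.peak_change),
            ("peak_score", lambda e: e.peak_score),
            (
                "duration_days",
                lambda e: float(e.duration_days) if not e.truncated else None,
            ),
            (
                "onset_time_days",
                lambda e: (
                    float(e.onset_time_days)
                    if e.onset_time_days is not None
                    else None
                ),
            ),
        ]:
            mean, sd, n = _mean_sd([getter(e) for e in kind_events])
            summary[key] = {"mean": mean, "sd": sd, "n": n}
        summary["n_events"] = {"mean": len(kind_events), "sd": 0.0, "n": len(kind_events)}
        summary["n_met_embarc"] = {
            "mean": sum(1 for e in kind_events if e.met_embarc),
            "sd": 0.0,
            "n": len(kind_events),
        }
        report.event_summary[kind] = summary
    return report
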