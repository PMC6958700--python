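"""End-to-end orchestration: simulate -> detect -> validate -> report."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import detection, instrument, psychometrics, synthetic

logger = logging.getLogger("bestdiary")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    out_dir: Path
    diary_path: Path | None = None
    anchors_path: Path | None = None
    simulate: bool = False
    seed: int | None = None
    n_patients: int = 21
    followup_days: int = 180
    threshold: float = 3.0
    min_days: int = 2
    refractory_days: int = 7
    censor_pre_days: int = 7
    lookback_days: int = 14
    max_duration_days: int = 42
    cutoffs: tuple[float, ...] = (4.0, 5.0, 6.0)
    lenient_coldflu: bool = False
    synthetic_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        errors = []
        if self.threshold <= 0:
            errors.append("threshold must be > 0")
        if self.min_days < 1:
            errors.append("min_days must be >= 1")
        if not self.cutoffs:
            errors.append("cutoff list must be non-empty")
        elif list(self.cutoffs) != sorted(self.cutoffs):
            errors.append("cutoff list must be sorted ascending")
        if self.simulate and self.seed is None:
            errors.append("simulate requires a seed")
        if not self.simulate and self.diary_path is None:
            errors.append("either --diary or simulate is required")
        if errors:
            raise PipelineError("config", "; ".join(errors))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a summary dict of counts and artifact paths.

    Writes diary.csv/anchors.csv/truth_events.csv (when simulating),
    events.csv, report.json and report.md under ``config.out_dir``.
    Identical config and seed give identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        syn = synthetic.SyntheticConfig(
            n_patients=config.n_patients,
            followup_days=config.followup_days,
            seed=int(config.seed),
            **config.synthetic_overrides,
        )
        try:
            diaries, truth = synthetic.generate_cohort(syn)
        except (ValueError, RuntimeError) as exc:
            raise PipelineError("simulate", str(exc)) from exc
        anchors = synthetic.anchors_to_frame(truth)
        instrument.write_diary_csv(diaries, out / "diary.csv")
        instrument.write_anchors_csv(anchors, out / "anchors.csv")
        synthetic.write_truth_csv(truth, out / "truth_events.csv")
        syn.to_json(out / "synthetic_config.json")
        logger.info("simulate: %d patients, %d days", syn.n_patients, syn.followup_days)
    else:
        try:
            diaries = instrument.read_diary_csv(
                config.diary_path, lenient_coldflu=config.lenient_coldflu
            )
        except (OSError, ValueError) as exc:
            raise PipelineError("read", str(exc)) from exc
        if not diaries:
            raise PipelineError("read", f"{config.diary_path}: no diary records")
        anchors = None
        if config.anchors_path is not None:
            try:
                anchors = instrument.read_anchors_csv(config.anchors_path)
            except (OSError, ValueError) as exc:
                raise PipelineError("read", str(exc)) from exc
        logger.info("read: %d patients", len(diaries))

    events = []
    for pid in sorted(diaries):
        try:
            events.extend(
                detection.detect_events(
                    diaries[pid],
                    threshold=config.threshold,
                    min_days=config.min_days,
                    refractory_days=config.refractory_days,
                    censor_pre_days=config.censor_pre_days,
                    lookback_days=config.lookback_days,
                    max_duration_days=config.max_duration_days,
                )
            )
        except ValueError as exc:
            raise PipelineError("detect", f"{pid}: {exc}") from exc
    detection.write_events_csv(events, out / "events.csv")
    n_rep = sum(1 for e in events if e.kind == "reported")
    n_unrep = len(events) - n_rep
    logger.info("detect: %d reported, %d unreported events", n_rep, n_unrep)

    report = None
    if anchors is not None:
        report = psychometrics.build_validity_report(
            diaries, anchors, events, cutoffs=config.cutoffs
        )
        report.to_json(out / "report.json")
        (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
        logger.info("validate: report written")

    return {
        "n_patients": len(diaries),
        "n_reported": n_rep,
        "n_unreported": n_unrep,
        "out_dir": str(out),
        "report": report,
    }
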