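"""Full validation analysis of a cohort: correlations, MCID, cutoffs.

Runs the complete pipeline on a 21-patient synthetic cohort: convergent
validity against the anchor questionnaires, the three MCID estimates
(half-SD, anchor regression, exacerbation onset), the change-score cutoff
sweep, and within-subject variability.
"""

from bestdiary import SyntheticConfig, build_validity_report, detect_events, generate_cohort
from bestdiary.synthetic import anchors_to_frame

config = SyntheticConfig(n_patients=21, followup_days=180, seed=11)
diaries, truth = generate_cohort(config)
events = [ev for pid in sorted(diaries) for ev in detect_events(diaries[pid])]
report = build_validity_report(diaries, anchors_to_frame(truth), events)

print(report.to_markdown())
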