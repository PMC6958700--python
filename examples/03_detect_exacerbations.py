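"""Detect and characterise exacerbations in a daily symptom series.

Builds one synthetic patient (fixed seed), then runs the full detector:
reported (treated) events are anchored on the antibiotic-start day and
characterised (onset, prodrome, peak, recovery); unreported events are
found by the consensus screening rule -- a sustained rise of >= 3 points
over the rolling median-of-prior-week baseline for >= 48 h without
treatment.
"""

from bestdiary import SyntheticConfig, detect_events, generate_patient

config = SyntheticConfig(n_patients=1, followup_days=180, seed=11)
diary, truth = generate_patient(config, 17)

print(f"patient {diary.patient_id}: true baseline {truth.baseline:.1f}, "
      f"{len(truth.events)} planted events")
print()
for ev in detect_events(diary):
    line = (f"{ev.kind:<10} onset {ev.onset_day}  baseline {ev.baseline.value:.1f}  "
            f"peak {ev.peak_score:.0f} (+{ev.peak_change:.1f})  "
            f"duration {ev.duration_days} d")
    if ev.kind == "reported":
        line += (f"  prodrome {ev.onset_time_days} d"
                 f"  >=3 worsened domains: {'yes' if ev.met_embarc else 'no'}")
    print(line)
print()
print("peak is the highest daily total inside the event; duration is days to")
print("return to the pre-event baseline (from treatment start for reported,")
print("from onset for unreported events).")
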