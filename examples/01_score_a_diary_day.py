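"""Score single diary days and map sputum volumes to categories.

The BEST diary has six items; the daily total runs 0 (no symptoms) to 26
(worst possible day). Sputum volume is recorded in household equivalents
(teaspoon 5 ml, tablespoon 15 ml, egg-cup 45 ml, cup ~250 ml).
"""

from bestdiary import DiaryEntry, ml_to_volume_category, score_entry, validate_entry
import datetime as dt

day = dt.date(2014, 3, 1)

typical = DiaryEntry("P001", day, breathlessness=1, fatigue=2, sputum_volume=2,
                     sputum_colour=2, cough=1, cold_flu=1)
worst = DiaryEntry("P001", day, breathlessness=4, fatigue=4, sputum_volume=4,
                   sputum_colour=5, cough=4, cold_flu=5)

print("typical day total:", score_entry(typical))   # 9: mild-moderate burden
print("worst possible total:", score_entry(worst))  # 26: every item at maximum

for ml in (0, 3, 5, 100, 300):
    print(f"{ml:>4} ml/day of sputum -> category {ml_to_volume_category(ml)}")

# Validation collects every violation, not just the first.
try:
    validate_entry({"patient_id": "P001", "date": "2014-03-01",
                    "breathlessness": 9, "fatigue": 0, "sputum_volume": 0,
                    "sputum_colour": 0, "cough": 0, "cold_flu": 3})
except Exception as exc:
    print("rejected record:", exc)
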