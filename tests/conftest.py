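import datetime as dt

import pytest

from bestdiary.instrument import ITEM_NAMES, DiaryEntry, PatientDiary
from bestdiary.synthetic import decompose_total_to_items

START = dt.date(2014, 1, 6)


def diary_from_totals(
    totals,
    *,
    patient_id: str = "P001",
    start: dt.date = START,
    treatment_days: set[int] = frozenset(),
    missing_days: set[int] = frozenset(),
) -> PatientDiary:
    """Build a diary whose daily totals follow ``totals`` exactly.

    ``treatment_days``/``missing_days`` are day indices relative to start.
    """
    entries = []
    prev = None
    for i, total in enumerate(totals):
        items = decompose_total_to_items(float(total), prev, event_active=True)
        prev = items
        if i in missing_days:
            continue
        flag = i in treatment_days
        entries.append(
            DiaryEntry(
                patient_id=patient_id,
                day=start + dt.timedelta(days=i),
                reported_flag=flag,
                antibiotic_start=flag,
                **dict(zip(ITEM_NAMES, items)),
            )
        )
    return PatientDiary(patient_id, entries)


@pytest.fixture
def make_diary():
    return diary_from_totals


@pytest.fixture(scope="session")
def small_cohort():
    """A 21-patient default cohort shared across tests."""
    from bestdiary.synthetic import SyntheticConfig, generate_cohort

    config = SyntheticConfig(n_patients=21, followup_days=180, seed=11)
    diaries, truth = generate_cohort(config)
    return config, diaries, truth
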