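from datetime import datetime, timedelta

import numpy as np
import pytest

from hemobleed.corpus_model import (
    CourseNote,
    HemoglobinMeasurement,
    PatientVisit,
    TransfusionEvent,
)
from hemobleed.feature_extraction import default_catalog
from hemobleed.synthetic_notes import SyntheticCorpusConfig, generate_corpus

SURGERY = datetime(2020, 5, 10, 10, 0)


def make_note(text, visit_id="V1", offset_hours=24, note_type="progress", note_id=None):
    ts = SURGERY + timedelta(hours=offset_hours)
    return CourseNote(
        note_id=note_id or f"{visit_id}-{offset_hours}",
        visit_id=visit_id,
        note_type=note_type,
        timestamp=ts,
        text=text,
    )


def make_visit(
    visit_id="V1",
    texts=("术后第1日，患者一般情况可。",),
    hb=(),  # (hours_offset, value_g_per_L)
    transfusions=(),  # (hours_offset, quantity, unit)
    label=None,
    age=60,
):
    notes = [make_note(t, visit_id, 12 * (i + 1)) for i, t in enumerate(texts)]
    hb_series = [
        HemoglobinMeasurement(SURGERY + timedelta(hours=h), v, "g_per_L") for h, v in hb
    ]
    events = [
        TransfusionEvent(SURGERY + timedelta(hours=h), "rbc_concentrate", q, u)
        for h, q, u in transfusions
    ]
    return PatientVisit(
        visit_id=visit_id,
        age=age,
        sex="female",
        surgery_time=SURGERY,
        notes=notes,
        hb_series=hb_series,
        transfusions=events,
        label=label,
    )


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_corpus():
    """100 noise-free visits at 10% prevalence, shared across tests."""
    config = SyntheticCorpusConfig(n_visits=100, prevalence=0.10, seed=7, noise_rate=0.4)
    return generate_corpus(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
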