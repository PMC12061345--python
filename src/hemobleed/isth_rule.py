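"""Quantitative adjudication of major bleeding (ISTH definition).

Major bleeding = symptomatic bleeding in a critical area or organ, OR a fall
in hemoglobin of >= 2 g/dL, OR transfusion of >= 2 units of erythrocyte
concentrate.  Both numeric thresholds are inclusive.  Missing data makes the
corresponding criterion false rather than raising (screening posture).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Sequence

from .corpus_model import HemoglobinMeasurement, PatientVisit, TransfusionEvent

#: blood products that count toward the erythrocyte-transfusion criterion
_RBC_PRODUCTS = ("rbc_concentrate", "whole_blood")


@dataclass(frozen=True)
class IsthThresholds:
    hb_drop_threshold: float = 2.0  # g/dL
    rbc_units_threshold: float = 2.0  # units
    ml_per_unit: float = 200.0  # Chinese blood-banking convention

    def __post_init__(self) -> None:
        for name in ("hb_drop_threshold", "rbc_units_threshold", "ml_per_unit"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_THRESHOLDS = IsthThresholds()


@dataclass
class IsthEvidence:
    max_postop_hb_drop: float | None  # g/dL; None when not determinable
    total_rbc_units: float
    critical_site_or_fatal: bool
    sources: list[str] = field(default_factory=list)


@dataclass
class IsthDecision:
    label: str  # "major" | "not_major"
    triggered_criteria: tuple[str, ...]  # subset of {hb_drop, transfusion, critical_site}
    evidence: IsthEvidence


def to_g_per_dL(measurement: HemoglobinMeasurement) -> float:
    if measurement.unit == "g_per_L":
        return measurement.value / 10.0
    if measurement.unit == "g_per_dL":
        return measurement.value
    raise ValueError(f"unknown hemoglobin unit {measurement.unit!r}")


def max_postop_hb_drop(
    series: Sequence[HemoglobinMeasurement], surgery_time: datetime
) -> float | None:
    """Baseline minus postoperative nadir, in g/dL.

    Baseline is the last measurement at or before surgery; if none exists the
    first postoperative measurement serves as baseline.  Returns None when no
    postoperative measurement (or no baseline) is determinable.
    """
    if not series:
        return None
    ordered = sorted(series, key=lambda m: m.timestamp)
    pre = [m for m in ordered if m.timestamp <= surgery_time]
    post = [m for m in ordered if m.timestamp > surgery_time]
    if not post:
        return None
    baseline = to_g_per_dL(pre[-1]) if pre else to_g_per_dL(post[0])
    nadir = min(to_g_per_dL(m) for m in post)
    return baseline - nadir


def total_rbc_units(
    transfusions: Sequence[TransfusionEvent],
    thresholds: IsthThresholds = DEFAULT_THRESHOLDS,
    window: tuple[datetime | None, datetime | None] = (None, None),
) -> float:
    """Total erythrocyte units transfused inside the (start, end] window.

    mL quantities convert at ``thresholds.ml_per_unit``; a ``None`` window
    bound is unbounded on that side.
    """
    start, end = window
    total = 0.0
    for event in transfusions:
        if event.product not in _RBC_PRODUCTS:
            continue
        if start is not None and event.timestamp <= start:
            continue
        if end is not None and event.timestamp > end:
            continue
        if event.quantity < 0:
            raise ValueError(f"negative transfusion quantity {event.quantity}")
        if event.unit == "U":
            total += event.quantity
        else:
            total += event.quantity / thresholds.ml_per_unit
    return total


def adjudicate(
    visit: PatientVisit,
    thresholds: IsthThresholds = DEFAULT_THRESHOLDS,
    critical_site_detector: Callable[[str], bool] | None = None,
    include_intraop: bool = False,
) -> IsthDecision:
    """Apply the ISTH disjunction to one visit, with evidence provenance.

    ``critical_site_detector`` is a predicate over raw note text; when None,
    the default catalog's critical-site patterns are used.  Postoperative
    transfusions are those strictly after surgery_time unless
    ``include_intraop`` is set.
    """
    if critical_site_detector is None:
        from .feature_extraction import default_critical_site_detector

        critical_site_detector = default_critical_site_detector()

    sources: list[str] = []
    criteria: list[str] = []

    drop = max_postop_hb_drop(visit.hb_series, visit.surgery_time)
    if drop is not None and drop >= thresholds.hb_drop_threshold:
        criteria.append("hb_drop")
        sources.append(f"lab: max postoperative hb drop {drop:.2f} g/dL")

    window_start = None if include_intraop else visit.surgery_time
    units = total_rbc_units(visit.transfusions, thresholds, window=(window_start, None))
    if units >= thresholds.rbc_units_threshold:
        criteria.append("transfusion")
        sources.append(f"transfusion records: {units:.2f} erythrocyte units post-op")

    critical = False
    for note in visit.notes:
        if critical_site_detector(note.text):
            critical = True
            sources.append(f"note {note.note_id}: critical-site bleeding text")
    if critical:
        criteria.append("critical_site")

    evidence = IsthEvidence(
        max_postop_hb_drop=drop,
        total_rbc_units=units,
        critical_site_or_fatal=critical,
        sources=sources,
    )
    label = "major" if criteria else "not_major"
    return IsthDecision(label=label, triggered_criteria=tuple(criteria), evidence=evidence)


def structured_feature(visit: PatientVisit, thresholds: IsthThresholds = DEFAULT_THRESHOLDS) -> int:
    """The catalog's category-3 binary feature: 1 iff the visit adjudicates major."""
    return 1 if adjudicate(visit, thresholds).label == "major" else 0
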