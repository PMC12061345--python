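"""Labeled synthetic Chinese postoperative EMR corpora.

Generates visits whose demographics, note counts, prevalence, hemoglobin
trajectories and transfusion records mirror the statistical structure the
pipeline assumes, together with per-visit ground truth recording *why* each
positive visit qualifies.  The core correctness contract: on a noise-free
corpus, :func:`hemobleed.isth_rule.adjudicate` reproduces the ground-truth
labels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .corpus_model import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    CourseNote,
    HemoglobinMeasurement,
    PatientVisit,
    TransfusionEvent,
)

MECHANISMS = ("hb_drop", "transfusion_2u", "critical_site_text", "none")

_BASE_DATE = datetime(2020, 3, 1, 9, 0)

# demographic moments of the emulated population
_AGE_MEAN, _AGE_SD = 62.86, 9.16
_FEMALE_FRACTION = 0.485


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    n_visits: int
    prevalence: float = 0.0431
    mean_notes_per_visit: float = 21.0
    seed: int = 0
    noise_rate: float = 0.3
    hb_unit: str = "g_per_L"
    hb_noise_sd: float = 0.0  # g/L; keep 0 for exact label-mechanism consistency

    def __post_init__(self) -> None:
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.mean_notes_per_visit < 1:
            raise ValueError("mean_notes_per_visit must be >= 1")
        if self.hb_unit not in ("g_per_L", "g_per_dL"):
            raise ValueError(f"unknown hb_unit {self.hb_unit!r}")


@dataclass(frozen=True)
class GroundTruth:
    visit_id: str
    label: str
    mechanism: str

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if (self.mechanism == "none") != (self.label == NEGATIVE_LABEL):
            raise ValueError("mechanism is 'none' iff label is absent")


# ---------------------------------------------------------------------------
# note templates
#
# Each entry: template_id -> (note_type, text with {slot} placeholders,
# catalog patterns it is designed to trigger -- documentation only).
# ---------------------------------------------------------------------------

TEMPLATES: dict[str, tuple[str, str, str]] = {
    # --- scaffolding notes (any visit) -------------------------------------
    "admission": ("admission",
        "患者{age}岁，因腹部肿物入院。既往体健，无出血性疾病史。查体：生命体征平稳，腹软。",
        "none (negated bleeding history is a distractor)"),
    "admission_chest": ("admission",
        "患者{age}岁，因胸部占位入院，拟行手术治疗。查体未见明显异常。",
        "none"),
    "operative_clean": ("operative",
        "今日在全麻下行肿瘤切除术，手术顺利，术中出血约{vol}ml，未输血，麻醉满意。",
        "key pattern 4 (bleeding term), sub-threshold blood-loss distractor"),
    "operative_plain": ("operative",
        "全麻下行根治性切除术，过程顺利，安返病房。",
        "none"),
    "discharge_clean": ("discharge",
        "患者恢复良好，切口愈合佳，予今日出院，嘱定期复查。",
        "cat2 token 复查"),
    "discharge_followup": ("discharge",
        "今日办理出院，生命体征平稳，门诊随诊。",
        "cat2 token 生命体征"),
    "admission_gyn": ("admission",
        "患者{age}岁，因盆腔肿物入院，拟行手术治疗，术前检查无明显禁忌。",
        "none"),
    "operative_gyn": ("operative",
        "全麻下行妇科肿瘤根治术，术程顺利，术中出血约{vol}ml，安返病房。",
        "key pattern 4 (bleeding term), sub-threshold blood-loss distractor"),
    "discharge_advice": ("discharge",
        "患者一般情况良好，予出院，出院后注意休息，定期门诊复查。",
        "cat2 token 复查"),
    # --- routine progress (negative filler) --------------------------------
    "routine_progress": ("progress",
        "术后第{day}日，患者一般情况可，生命体征平稳，切口敷料干燥，无渗出。",
        "cat2 tokens 生命体征/敷料"),
    "routine_labs": ("progress",
        "复查血常规：血红蛋白{hb}g/l，白细胞计数正常，继续补液对症治疗。",
        "cat2 tokens 复查/补液"),
    "routine_diet": ("progress",
        "患者术后第{day}日，已排气，进流质饮食，腹部体征阴性。",
        "none"),
    "routine_mobilize": ("progress",
        "患者今日下床活动，诉轻度切口疼痛，余无特殊不适。",
        "none"),
    "routine_pain": ("progress",
        "患者诉切口轻度疼痛，予对症止痛处理，夜间睡眠可。",
        "none"),
    "routine_dressing": ("progress",
        "今日换药，切口对合良好，无红肿，敷料清洁。",
        "cat2 tokens 换药/敷料"),
    "routine_monitor": ("progress",
        "继续监测血压、心率，目前各项指标稳定。",
        "cat2 tokens 监测/血压"),
    "routine_drain_clear": ("progress",
        "引流管通畅，引流液清亮，量少，予以观察。",
        "cat2 token 引流 (non-bloody)"),
    "routine_drain_removed": ("progress",
        "术后恢复顺利，今日拔除引流管，伤口无异常。",
        "cat2 token 引流"),
    # --- distractors (negative visits, noise_rate) --------------------------
    "distractor_negation": ("progress",
        "患者无呕血黑便，查体无出血征象，引流液清亮。",
        "negated bleeding mention (key patterns 3/4 may fire; adjudication unaffected)"),
    "distractor_small_loss": ("progress",
        "术中出血约{vol}ml，量少，未予特殊处理。",
        "sub-threshold blood-loss quantity"),
    "distractor_anemia_history": ("admission",
        "患者既往轻度贫血病史，术前血红蛋白{hb}g/l，已纠正。",
        "preoperative anemia distractor"),
    "distractor_one_unit": ("transfusion",
        "术中输注悬浮少白红细胞{qty}{unit}，输血过程顺利，无不良反应。",
        "transfusion pattern with sub-threshold quantity"),
    "distractor_oozing_mention": ("progress",
        "术中创面少许渗出，已彻底电凝处理，目前无活动性渗出。",
        "near-miss hemostasis vocabulary"),
    # --- positive mechanism notes -------------------------------------------
    "hb_drop": ("progress",
        "术后第{day}日复查血常规：血红蛋白{post}g/l，较术前{pre}g/l明显下降，嘱密切观察。",
        "hemoglobin-fall narrative; structured rule via hb_series"),
    "hb_drop_repeat": ("progress",
        "患者血红蛋白进行性下降，今日复查为{post}g/l，继续监测。",
        "standalone lexicon: 血红蛋白进行性下降"),
    "transfusion_2u": ("transfusion",
        "患者术后血红蛋白偏低，给予输注悬浮少白红细胞{qty}{unit}，过程顺利。",
        "key pattern 16 (transfusion with quantity); structured rule via transfusions"),
    "transfusion_pre_unit": ("transfusion",
        "予{qty}单位红细胞悬液输注，患者耐受可，无输血反应。",
        "key pattern 16, quantity-before-product order"),
    "critical_site": ("progress",
        "患者术后腹腔引流出血性液体约{vol}ml，色暗红，考虑腹腔内出血可能，急诊行剖腹探查止血术。",
        "key patterns 5/8/13 (critical-site bleeding, laparotomy, hemostasis surgery)"),
    "critical_site_anastomosis": ("progress",
        "胃镜检查示吻合口活动性出血，予电凝止血治疗，出血停止。",
        "key pattern 13 (anastomosis bleeding), standalone 电凝止血"),
    "critical_site_pelvic": ("progress",
        "盆腔引流液暗红，量多，考虑盆腔出血，行急诊手术探查止血。",
        "key patterns 13/15 (pelvic drainage of bloody fluid)"),
    "postop_transfusion_note": ("progress",
        "输血后复查血红蛋白{hb}g/l，较前回升，继续观察。",
        "post-transfusion recovery narrative"),
}

_DISTRACTOR_IDS = (
    "distractor_negation", "distractor_small_loss", "distractor_anemia_history",
    "distractor_one_unit", "distractor_oozing_mention",
)
_ROUTINE_IDS = (
    "routine_progress", "routine_labs", "routine_diet", "routine_mobilize",
    "routine_pain", "routine_dressing", "routine_monitor", "routine_drain_clear",
    "routine_drain_removed",
)
_ADMISSION_IDS = ("admission", "admission_chest", "admission_gyn")
_OPERATIVE_IDS = ("operative_clean", "operative_plain", "operative_gyn")
_DISCHARGE_IDS = ("discharge_clean", "discharge_followup", "discharge_advice")
_CRITICAL_IDS = ("critical_site", "critical_site_anastomosis", "critical_site_pelvic")


def render_note(
    template_id: str,
    slots: dict[str, object],
    rng: np.random.Generator,
    visit_id: str = "V0",
    timestamp: datetime | None = None,
    note_id: str | None = None,
) -> CourseNote:
    """Instantiate a template; the rendered text contains each slot verbatim."""
    if template_id not in TEMPLATES:
        raise KeyError(f"unknown template_id {template_id!r}")
    note_type, template, _ = TEMPLATES[template_id]
    try:
        text = template.format(**slots)
    except (KeyError, IndexError) as exc:
        raise KeyError(f"template {template_id!r}: missing slot {exc.args[0]!r}") from exc
    if timestamp is None:
        timestamp = _BASE_DATE
    if note_id is None:
        note_id = f"{visit_id}-{template_id}-{int(rng.integers(1_000_000))}"
    return CourseNote(note_id=note_id, visit_id=visit_id, note_type=note_type,
                      timestamp=timestamp, text=text)


def generate_hb_series(
    baseline: float,
    postop_drop: float,
    n_points: int,
    rng: np.random.Generator,
    noise_sd: float = 2.0,
    surgery_time: datetime = _BASE_DATE,
    unit: str = "g_per_L",
) -> list[HemoglobinMeasurement]:
    """Hemoglobin trajectory in g/L around a surgery timestamp.

    At least one preoperative and one postoperative point; the noise-free
    postoperative nadir equals ``baseline - postop_drop``; independent
    N(0, noise_sd) measurement noise is added per point.
    """
    if postop_drop > baseline:
        raise ValueError(f"drop {postop_drop} exceeds baseline {baseline}")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    n_post = max(1, n_points - 1)
    values = [baseline]  # one pre-op draw at baseline
    times = [surgery_time - timedelta(days=1)]
    nadir_at = int(rng.integers(0, n_post))
    for j in range(n_post):
        if j < nadir_at:
            frac = (j + 1) / (nadir_at + 1)
        elif j == nadir_at:
            frac = 1.0
        else:  # partial recovery after the nadir
            frac = 1.0 - 0.3 * (j - nadir_at) / max(n_post - nadir_at, 1)
        values.append(baseline - postop_drop * frac)
        times.append(surgery_time + timedelta(days=j + 1))
    noise = rng.normal(0.0, noise_sd, size=len(values)) if noise_sd > 0 else np.zeros(len(values))
    series = []
    for t, v, e in zip(times, values, noise):
        g_per_l = float(np.clip(v + e, 35.0, 240.0))
        if unit == "g_per_L":
            series.append(HemoglobinMeasurement(timestamp=t, value=round(g_per_l, 1), unit=unit))
        else:
            series.append(HemoglobinMeasurement(timestamp=t, value=round(g_per_l / 10.0, 2), unit=unit))
    return series


def _sample_age(rng: np.random.Generator) -> int:
    while True:
        age = rng.normal(_AGE_MEAN, _AGE_SD)
        if age >= 18:
            return int(round(age))


def _build_visit(
    visit_id: str,
    mechanism: str,
    config: SyntheticCorpusConfig,
    rng: np.random.Generator,
) -> PatientVisit:
    age = _sample_age(rng)
    sex = "female" if rng.random() < _FEMALE_FRACTION else "male"
    surgery_time = _BASE_DATE + timedelta(
        days=int(rng.integers(0, 365)), hours=int(rng.integers(8, 16))
    )
    positive = mechanism != "none"

    baseline = float(rng.uniform(115.0, 150.0))  # g/L
    if mechanism == "hb_drop":
        drop = float(rng.uniform(26.0, 45.0))  # comfortably >= 20 g/L threshold
    else:
        drop = float(rng.uniform(0.0, 10.0))  # comfortably below threshold
    n_hb = int(rng.integers(3, 7))
    hb_series = generate_hb_series(
        baseline, drop, n_hb, rng, noise_sd=config.hb_noise_sd,
        surgery_time=surgery_time, unit=config.hb_unit,
    )

    transfusions: list[TransfusionEvent] = []
    notes: list[CourseNote] = []
    day = timedelta(days=1)

    def add(template_id: str, offset: timedelta, **slots: object) -> None:
        notes.append(render_note(template_id, slots, rng, visit_id=visit_id,
                                 timestamp=surgery_time + offset,
                                 note_id=f"{visit_id}-N{len(notes):03d}"))

    add(str(rng.choice(_ADMISSION_IDS)), -2 * day, age=age)
    add(str(rng.choice(_OPERATIVE_IDS)), timedelta(hours=2), vol=int(rng.integers(30, 90)))

    n_notes = max(4, int(rng.poisson(config.mean_notes_per_visit)))
    n_body = n_notes - 3  # minus admission/operative/discharge
    post_day = 1

    if mechanism == "hb_drop":
        post_hb = hb_series and min(
            m.value if config.hb_unit == "g_per_L" else m.value * 10
            for m in hb_series if m.timestamp > surgery_time
        )
        add("hb_drop", timedelta(days=2, hours=3), day=2,
            pre=round(baseline, 1), post=round(post_hb, 1))
        add("hb_drop_repeat", timedelta(days=3, hours=3), post=round(post_hb, 1))
        post_day, n_body = 4, n_body - 2
    elif mechanism == "transfusion_2u":
        qty = float(rng.choice([2.0, 2.0, 3.0, 4.0]))
        when = surgery_time + timedelta(days=2, hours=5)
        transfusions.append(TransfusionEvent(timestamp=when, product="rbc_concentrate",
                                             quantity=qty, unit="U"))
        tmpl = "transfusion_2u" if rng.random() < 0.6 else "transfusion_pre_unit"
        add(tmpl, timedelta(days=2, hours=5), qty=int(qty), unit="u")
        add("postop_transfusion_note", timedelta(days=3, hours=2),
            hb=round(baseline - drop + 8, 1))
        post_day, n_body = 4, n_body - 2
    elif mechanism == "critical_site_text":
        add(str(rng.choice(_CRITICAL_IDS)), timedelta(days=1, hours=6),
            vol=int(rng.integers(200, 600)))
        post_day, n_body = 2, n_body - 1

    if not positive and rng.random() < config.noise_rate:
        tmpl = str(rng.choice(_DISTRACTOR_IDS))
        slots: dict[str, object] = {}
        if tmpl == "distractor_small_loss":
            slots["vol"] = int(rng.integers(20, 100))
        elif tmpl == "distractor_anemia_history":
            slots["hb"] = round(float(rng.uniform(100, 115)), 1)
        elif tmpl == "distractor_one_unit":
            slots["qty"], slots["unit"] = 1, "u"
            # matching structured record, intraoperative and sub-threshold
            transfusions.append(TransfusionEvent(timestamp=surgery_time,
                                                 product="rbc_concentrate",
                                                 quantity=1.0, unit="U"))
        add(tmpl, timedelta(days=1, hours=4), **slots)
        post_day, n_body = 2, n_body - 1

    for _ in range(max(n_body, 0)):
        tmpl = str(rng.choice(_ROUTINE_IDS))
        slots = {}
        if tmpl == "routine_labs":
            slots["hb"] = round(baseline - drop + float(rng.uniform(0, 5)), 1)
        elif tmpl in ("routine_progress", "routine_diet"):
            slots["day"] = post_day
        add(tmpl, timedelta(days=post_day, hours=int(rng.integers(8, 12))), **slots)
        post_day += 1

    add(str(rng.choice(_DISCHARGE_IDS)), timedelta(days=post_day, hours=10))

    notes.sort(key=lambda n: n.timestamp)
    return PatientVisit(
        visit_id=visit_id, age=age, sex=sex, surgery_time=surgery_time,
        notes=notes, hb_series=hb_series, transfusions=transfusions,
        label=POSITIVE_LABEL if positive else NEGATIVE_LABEL,
    )


def generate_corpus(config: SyntheticCorpusConfig) -> tuple[list[PatientVisit], list[GroundTruth]]:
    """Generate a labeled corpus and its ground truth, deterministically.

    The positive count is ``round(prevalence * n_visits)`` (at least 1 when
    prevalence > 0), with positive positions and mechanisms drawn from the
    seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_visits
    n_pos = int(round(config.prevalence * n))
    if config.prevalence > 0 and n_pos == 0:
        warnings.warn("prevalence * n_visits < 0.5; rounding up to 1 positive visit")
        n_pos = 1
    positive_idx = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()

    visits, truths = [], []
    for i in range(n):
        visit_id = f"V{i:05d}"
        if i in positive_idx:
            mechanism = str(rng.choice(["hb_drop", "transfusion_2u", "critical_site_text"]))
        else:
            mechanism = "none"
        visits.append(_build_visit(visit_id, mechanism, config, rng))
        truths.append(GroundTruth(
            visit_id=visit_id,
            label=POSITIVE_LABEL if mechanism != "none" else NEGATIVE_LABEL,
            mechanism=mechanism,
        ))
    return visits, truths


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("visit_id,label,mechanism\n")
        for t in truths:
            fh.write(f"{t.visit_id},{t.label},{t.mechanism}\n")
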