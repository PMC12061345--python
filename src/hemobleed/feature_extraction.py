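"""Three-category feature engineering over Chinese EMR free text.

Produces the 270-dimensional binary feature vector per visit:

* category 1 — 261 manually curated bleeding regexes (the 19 published key
  regex patterns plus 242 reconstructed lexicon patterns);
* category 2 — 8 frequency-selected segmentation tokens;
* category 3 — 1 structured quantitative rule (ISTH adjudication).

The catalog is ordered and versioned: its order defines the 1-D axis the
convolutional model sees.  A default catalog ships as ``data/catalog_v1.tsv``
and is user-replaceable by any TSV with the same columns.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .corpus_model import PatientVisit
from . import isth_rule

CAT1 = "cat1_manual"
CAT2 = "cat2_frequency"
CAT3 = "cat3_structured"

N_FEATURES = 270
N_CAT1 = 261
N_CAT2 = 8

_WS_RE = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# text normalization and segmentation
# ---------------------------------------------------------------------------

def normalize_text(text: str) -> str:
    """NFKC-fold (full-width -> half-width), casefold Latin, collapse whitespace.

    Idempotent: ``normalize_text(normalize_text(x)) == normalize_text(x)``.
    """
    folded = unicodedata.normalize("NFKC", text).casefold()
    return _WS_RE.sub(" ", folded).strip()


#: clinical lexicon for the built-in maximum-matching segmenter
_SEGMENT_LEXICON = [
    "悬浮少白红细胞", "少白悬浮红细胞", "失血性休克", "血红蛋白", "红细胞悬液",
    "活动性出血", "剖腹探查", "生命体征", "引流液", "悬浮红细胞", "血常规",
    "消化道", "吻合口", "后穹窿", "凝血功能", "红细胞", "止血术", "血凝块",
    "术后", "术前", "术中", "出血", "失血", "渗血", "止血", "血肿", "血性",
    "液体", "引流", "输注", "输血", "输入", "给予", "患者", "腹腔", "胸腔",
    "盆腔", "阴道", "直肠", "胰腺", "血压", "心率", "复查", "监测", "补液",
    "换药", "敷料", "切口", "创面", "贫血", "血浆", "血小板", "全血", "暗红",
    "急诊", "肿胀", "平稳", "干燥", "清亮", "休克", "单位", "毫升", "大量",
    "明显", "下降", "升高", "呕血", "黑便", "便血", "血尿", "顺利", "可见",
]
_LEXICON_SET = frozenset(_SEGMENT_LEXICON)
_MAX_WORD = max(len(w) for w in _SEGMENT_LEXICON)
_LATIN_RUN = re.compile(r"[0-9a-z.]+")


def _fmm_segment(text: str) -> list[str]:
    """Forward-maximum-matching over the built-in lexicon; unknown CJK chars
    become single-character tokens, Latin/digit runs stay whole."""
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        m = _LATIN_RUN.match(text, i)
        if m:
            tokens.append(m.group())
            i = m.end()
            continue
        for width in range(min(_MAX_WORD, n - i), 1, -1):
            if text[i : i + width] in _LEXICON_SET:
                tokens.append(text[i : i + width])
                i += width
                break
        else:
            tokens.append(text[i])
            i += 1
    return tokens


def jieba_segmenter() -> Callable[[str], list[str]]:
    """Return a jieba-backed segmenter if jieba is importable (optional)."""
    import jieba  # noqa: deferred; not a hard dependency

    return lambda text: list(jieba.cut(text, HMM=True))


def segment_text(text: str, segmenter: Callable[[str], list[str]] | None = None) -> list[str]:
    """Tokenize normalized text; concatenating the tokens recovers the input."""
    if not text:
        return []
    tokens = (segmenter or _fmm_segment)(text)
    if "".join(tokens) != text:
        raise ValueError("segmenter violated the coverage contract")
    return tokens


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegexFeaturePattern:
    feature_id: int
    pattern: str
    description: str
    category: str
    source: str
    flags: tuple[str, ...] = ()  # e.g. ("published_key", "critical_site")

    def __post_init__(self) -> None:
        if self.category not in (CAT1, CAT2, CAT3):
            raise ValueError(f"unknown category {self.category!r}")
        if self.category != CAT3:
            re.compile(self.pattern)  # must compile


class FeatureCatalog:
    """Ordered, versioned set of 270 feature definitions (261/8/1)."""

    def __init__(self, patterns: Sequence[RegexFeaturePattern], version: str):
        patterns = list(patterns)
        if len(patterns) != N_FEATURES:
            raise ValueError(f"catalog must have exactly {N_FEATURES} patterns, got {len(patterns)}")
        counts = Counter(p.category for p in patterns)
        if (counts[CAT1], counts[CAT2], counts[CAT3]) != (N_CAT1, N_CAT2, 1):
            raise ValueError(
                f"category counts must be {N_CAT1}/{N_CAT2}/1, got "
                f"{counts[CAT1]}/{counts[CAT2]}/{counts[CAT3]}"
            )
        if [p.feature_id for p in patterns] != list(range(N_FEATURES)):
            raise ValueError("feature_ids must be contiguous 0..269 in catalog order")
        if sum("published_key" in p.flags for p in patterns) != 20:
            raise ValueError("catalog must flag exactly 20 published key patterns")
        self.patterns = patterns
        self.version = version
        self._compiled = [
            re.compile(p.pattern) if p.category != CAT3 else None for p in patterns
        ]

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def cat3_index(self) -> int:
        return next(p.feature_id for p in self.patterns if p.category == CAT3)

    def critical_site_patterns(self) -> list[re.Pattern]:
        return [
            c
            for p, c in zip(self.patterns, self._compiled)
            if c is not None and "critical_site" in p.flags
        ]

    def cat1_compiled(self) -> list[re.Pattern]:
        return [c for p, c in zip(self.patterns, self._compiled) if p.category == CAT1]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# hemobleed feature catalog version={self.version}\n")
            fh.write("feature_id\tcategory\tpattern\tgloss\tsource\tflags\n")
            for p in self.patterns:
                fh.write(
                    f"{p.feature_id}\t{p.category}\t{p.pattern}\t{p.description}\t"
                    f"{p.source}\t{','.join(p.flags)}\n"
                )

    @classmethod
    def load_tsv(cls, path: str | Path) -> "FeatureCatalog":
        version = "unversioned"
        patterns: list[RegexFeaturePattern] = []
        with open(path, encoding="utf-8") as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    m = re.search(r"version=(\S+)", line)
                    if m:
                        version = m.group(1)
                    continue
                if not header_seen:
                    header_seen = True  # column header row
                    continue
                fid, category, pattern, gloss, source, flags = line.split("\t")
                patterns.append(
                    RegexFeaturePattern(
                        feature_id=int(fid),
                        pattern=pattern,
                        description=gloss,
                        category=category,
                        source=source,
                        flags=tuple(f for f in flags.split(",") if f),
                    )
                )
        return cls(patterns, version=version)


# --- default catalog construction ------------------------------------------
#
# The 19 published key regex patterns (English glosses preserved verbatim as
# descriptions) reconstructed in Chinese clinical vocabulary, after text
# normalization (lowercase Latin).  The 20th published key feature is the
# structured rule itself (category 3).

_SITES = r"(?:胸|腹|盆)腔|直肠.{0,2}陷凹|后穹窿|吻合口|胰腺|消化道|胃"
_RBC_PRODUCTS = (
    r"悬浮少白(?:红细胞输血量|红细胞|红)|全血|少白悬浮红细胞|红细胞悬液|红细胞|红悬"
)
_UNITS = r"u|ml|cc|毫升|单位"

_PUBLISHED_KEY_PATTERNS: list[tuple[str, str, tuple[str, ...]]] = [
    # (pattern, gloss, extra flags)
    (r"术后", "postoperative", ()),
    (_SITES + r"|阴道", "anatomic cavity / critical site mention", ()),
    (r"(?:出|失)血(?:止|破入)?|血肿|皮下(?:瘀|淤)斑|(?:瘀|淤)血",
     "bleed / hematoma / ecchymosis / congestion", ()),
    (r"出血", "bleeding", ()),
    (r"血性液体|红色?.{0,2}引流液", "bloody fluid / red drainage fluid", ()),
    (r"止血", "hemostasis", ()),
    (r"剖腹探查", "laparotomy", ()),
    (r"暗红", "dark red", ()),
    (r"急诊", "emergency", ()),
    (r"(?:行|予|给予).{0,15}止血", "procedure to stop bleeding (wide window)", ()),
    (r"肿胀", "swelling", ()),
    (r"(?:行|予|给予).{0,5}止血", "procedure to stop bleeding (narrow window)", ()),
    (r"(?:" + _SITES + r").{0,10}出血|阴道.{0,2}大量?.{0,2}(?:出|失)血",
     "critical-site bleeding", ("critical_site",)),
    (r"失血", "blood loss", ()),
    (r"盆腔.{0,5}引流.{0,5}(?:血性液|液.{0,2}暗红|暗红色?液)",
     "pelvic drainage of bloody / dark-red fluid", ()),
    (r"(?:输注?|输入|给予|予).{0,20}(?:" + _RBC_PRODUCTS + r").{0,20}(?:" + _UNITS + r"|输注)"
     r"|(?:输|入|予).{0,5}(?:" + _UNITS + r"|输注).{0,5}(?:" + _RBC_PRODUCTS + r")",
     "erythrocyte transfusion with quantity (either order)", ()),
    (r"(?:(?:出|失)血|引流|血性渗出液|血性积液).{0,15}(?:" + _UNITS + r")",
     "blood loss / drainage / bloody effusion with quantity", ()),
    (r"输.{0,20}(?:红细胞|全血|红悬)", "transfusion of red cells / whole blood", ()),
    (r"(?:存在|有).{0,5}出血", "documented presence of bleeding", ()),
]

_LEXICON_SITES = [
    "胸腔", "腹腔", "盆腔", "吻合口", "胃", "十二指肠", "消化道", "胰腺",
    "阴道", "直肠", "切口", "创面", "纵隔", "腹膜后", "腹壁", "肛门",
]
_LEXICON_EVENTS = [
    "出血", "渗血", "血肿", "积血", "大出血", "活动性出血", "再出血",
    "出血不止", "渗出", "血性液", "血凝块", "瘀斑",
]
_LEXICON_STANDALONE = [
    ("呕血", "hematemesis"), ("黑便", "melena"), ("便血", "hematochezia"),
    ("血便", "bloody stool"), ("咯血", "hemoptysis"), ("鼻衄", "epistaxis"),
    ("血尿", "hematuria"), ("血胸", "hemothorax"), ("腹腔积血", "hemoperitoneum"),
    ("失血性休克", "hemorrhagic shock"), ("出血点", "petechiae"),
    ("出血量", "bleeding volume"), ("血凝块", "blood clot"),
    ("凝血功能障碍", "coagulopathy"), ("血红蛋白下降", "hemoglobin fall"),
    ("血红蛋白降低", "hemoglobin decrease"),
    ("血红蛋白进行性下降", "progressive hemoglobin fall"),
    ("血色素下降", "hemoglobin (colloquial) fall"), ("休克", "shock"),
    ("面色苍白", "pallor"), ("心率增快", "tachycardia"), ("血压下降", "hypotension"),
    ("冷汗", "cold sweat"), ("头晕乏力", "dizziness and fatigue"),
    ("电凝止血", "electrocautery hemostasis"), ("压迫止血", "compression hemostasis"),
    ("缝扎止血", "suture-ligation hemostasis"), ("结扎止血", "ligation hemostasis"),
    ("填塞止血", "packing hemostasis"), ("止血药", "hemostatic drug"),
    ("止血治疗", "hemostatic therapy"), ("再次手术", "reoperation"),
    ("二次手术", "second operation"), ("急诊手术", "emergency surgery"),
    ("介入栓塞", "interventional embolization"), ("血管栓塞", "vascular embolization"),
    ("输血治疗", "transfusion therapy"), ("输血", "blood transfusion"),
    ("悬浮红细胞", "suspended red blood cells"), ("红细胞悬液", "red cell suspension"),
    ("血浆", "plasma"), ("冷沉淀", "cryoprecipitate"), ("血小板", "platelets"),
    ("贫血", "anemia"), ("重度贫血", "severe anemia"),
    ("引流量增多", "increased drainage volume"),
    ("引流液呈血性", "drainage fluid bloody"),
    ("引流液颜色加深", "drainage fluid darkening"),
    ("呕吐咖啡样物", "coffee-ground emesis"),
    ("大便隐血阳性", "positive fecal occult blood"),
]

#: frequency-selected segmentation tokens (category 2); chosen so that none
#: is covered by a category-1 pattern
_CAT2_TOKENS = [
    ("引流", "drainage"), ("复查", "recheck"), ("监测", "monitoring"),
    ("血压", "blood pressure"), ("补液", "fluid replacement"), ("换药", "dressing change"),
    ("敷料", "wound dressing"), ("生命体征", "vital signs"),
]


def build_default_catalog(version: str = "v1") -> FeatureCatalog:
    """Construct the default 270-entry catalog in its canonical order."""
    patterns: list[RegexFeaturePattern] = []
    fid = 0
    for i, (pat, gloss, extra) in enumerate(_PUBLISHED_KEY_PATTERNS):
        patterns.append(
            RegexFeaturePattern(fid, pat, gloss, CAT1, f"key pattern {i + 1}",
                                ("published_key",) + extra)
        )
        fid += 1
    for site in _LEXICON_SITES:
        for event in _LEXICON_EVENTS:
            patterns.append(
                RegexFeaturePattern(
                    fid, f"{site}.{{0,6}}{event}", f"site-event: {site} + {event}",
                    CAT1, "reconstructed lexicon (site x event)",
                )
            )
            fid += 1
    for term, gloss in _LEXICON_STANDALONE:
        patterns.append(
            RegexFeaturePattern(fid, term, gloss, CAT1, "reconstructed lexicon (standalone)")
        )
        fid += 1
    assert fid == N_CAT1, f"cat1 count mismatch: {fid}"
    for token, gloss in _CAT2_TOKENS:
        patterns.append(
            RegexFeaturePattern(fid, re.escape(token), f"frequency token: {gloss}",
                                CAT2, "frequency-selected token")
        )
        fid += 1
    patterns.append(
        RegexFeaturePattern(fid, "", "structured quantitative ISTH rule", CAT3,
                            "structured recognition", ("published_key",))
    )
    return FeatureCatalog(patterns, version=version)


def default_catalog() -> FeatureCatalog:
    """Load the shipped ``catalog_v1.tsv``."""
    path = resources.files("hemobleed").joinpath("data/catalog_v1.tsv")
    with resources.as_file(path) as p:
        return FeatureCatalog.load_tsv(p)


def default_critical_site_detector(catalog: FeatureCatalog | None = None) -> Callable[[str], bool]:
    """Predicate over raw note text using the catalog's critical-site patterns."""
    compiled = (catalog or default_catalog()).critical_site_patterns()

    def detector(text: str) -> bool:
        normalized = normalize_text(text)
        return any(c.search(normalized) for c in compiled)

    return detector


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    visit_id: str
    values: np.ndarray  # shape (270,), dtype int8, binary

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature values must be binary")


def match_features(text: str, catalog: FeatureCatalog) -> np.ndarray:
    """Binary presence indicators for cat1+cat2 patterns over normalized text.

    The cat3 position is left at 0 (it is not text-derivable); callers that
    need the full vector use :func:`extract_features`.
    """
    values = np.zeros(N_FEATURES, dtype=np.int8)
    if text:
        for pattern, compiled in zip(catalog.patterns, catalog._compiled):
            if compiled is not None and compiled.search(text):
                values[pattern.feature_id] = 1
    return values


def extract_features(visit: PatientVisit, catalog: FeatureCatalog) -> FeatureVector:
    """Full 270-vector: OR of per-note text matches, plus the structured rule."""
    values = np.zeros(N_FEATURES, dtype=np.int8)
    for note in visit.notes:
        values |= match_features(normalize_text(note.text), catalog)
    values[catalog.cat3_index] = isth_rule.structured_feature(visit)
    return FeatureVector(visit_id=visit.visit_id, values=values)


def extract_feature_matrix(
    visits: Sequence[PatientVisit], catalog: FeatureCatalog
) -> tuple[np.ndarray, list[str]]:
    """Stacked feature matrix (n, 270) plus visit ids, in corpus order."""
    vectors = [extract_features(v, catalog) for v in visits]
    if not vectors:
        return np.zeros((0, N_FEATURES), dtype=np.int8), []
    return np.stack([fv.values for fv in vectors]), [fv.visit_id for fv in vectors]


def write_feature_csv(
    X: np.ndarray,
    visit_ids: Sequence[str],
    path: str | Path,
    labels: Sequence[int] | None = None,
) -> None:
    """Flat feature-matrix CSV: visit_id, f000..f269[, label]."""
    import pandas as pd

    frame = pd.DataFrame(np.asarray(X, dtype=np.int8),
                         columns=[f"f{i:03d}" for i in range(N_FEATURES)])
    frame.insert(0, "visit_id", list(visit_ids))
    if labels is not None:
        frame["label"] = list(labels)
    frame.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    import pandas as pd

    frame = pd.read_csv(path)
    cols = [f"f{i:03d}" for i in range(N_FEATURES)]
    X = frame[cols].to_numpy(dtype=np.int8)
    labels = frame["label"].to_numpy() if "label" in frame.columns else None
    return X, frame["visit_id"].astype(str).tolist(), labels


# ---------------------------------------------------------------------------
# frequency-based token selection (category 2 derivation)
# ---------------------------------------------------------------------------

@dataclass
class FrequencySelectionResult:
    token: str
    corpus_frequency: int
    selected: bool
    threshold_used: int


_CJK = re.compile(r"[一-鿿]")


def build_frequency_features(
    corpus: Sequence[PatientVisit],
    threshold: int,
    exclusions: FeatureCatalog | Iterable[re.Pattern] | None = None,
    max_features: int = N_CAT2,
    segmenter: Callable[[str], list[str]] | None = None,
) -> list[FrequencySelectionResult]:
    """Select high-frequency tokens not already covered by cat1 patterns.

    Frequency is total term frequency across all note texts of the corpus.
    Tokens matching any exclusion pattern are never selected.  Results are
    sorted by frequency descending; at most ``max_features`` are selected.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if not corpus:
        raise ValueError("cannot select frequency features from an empty corpus")
    if isinstance(exclusions, FeatureCatalog):
        exclusion_patterns = exclusions.cat1_compiled()
    else:
        exclusion_patterns = list(exclusions) if exclusions is not None else []

    counts: Counter[str] = Counter()
    for visit in corpus:
        for note in visit.notes:
            for token in segment_text(normalize_text(note.text), segmenter):
                if _CJK.search(token):  # only content-bearing CJK tokens
                    counts[token] += 1

    results: list[FrequencySelectionResult] = []
    n_selected = 0
    for token, freq in counts.most_common():
        excluded = any(p.search(token) for p in exclusion_patterns)
        selected = freq >= threshold and not excluded and n_selected < max_features
        if selected:
            n_selected += 1
        results.append(FrequencySelectionResult(token, freq, selected, threshold))
    return results


# ---------------------------------------------------------------------------
# quantity extraction
# ---------------------------------------------------------------------------

_CN_NUM = {"一": 1, "二": 2, "三": 3, "四": 4, "五": 5, "六": 6, "七": 7,
           "八": 8, "九": 9, "十": 10, "两": 2}
_NUM = r"(?:\d+(?:\.\d+)?|[一二三四五六七八九十两])"
_GAP = r"[^。;；\n]"

_TRANSFUSION_PROD_QTY = re.compile(
    r"(?:输注|输入|给予|予|输)" + _GAP + r"{0,20}?(?:" + _RBC_PRODUCTS + r")"
    + _GAP + r"{0,10}?(?P<num>" + _NUM + r") ?(?P<unit>" + _UNITS + r")"
)
_TRANSFUSION_QTY_PROD = re.compile(
    r"(?:输注|输入|给予|予|输)" + _GAP + r"{0,5}?(?P<num>" + _NUM + r") ?(?P<unit>"
    + _UNITS + r")" + _GAP + r"{0,10}?(?:" + _RBC_PRODUCTS + r")"
)
_BLOOD_LOSS = re.compile(
    r"(?:出血|失血|血性渗出|渗血)" + _GAP + r"{0,15}?(?P<num>" + _NUM + r") ?(?P<unit>" + _UNITS + r")"
)
_DRAINAGE = re.compile(
    r"引流" + _GAP + r"{0,15}?(?P<num>" + _NUM + r") ?(?P<unit>ml|cc|毫升)"
)


def _parse_num(token: str) -> float:
    if token in _CN_NUM:
        return float(_CN_NUM[token])
    return float(token)


def _parse_unit(token: str) -> str:
    return "U" if token in ("u", "单位") else "mL"


def extract_quantities(text: str) -> list[tuple[str, float, str]]:
    """Extract (kind, quantity, unit) triples from normalized text.

    Kinds: ``transfusion_rbc``, ``blood_loss``, ``drainage``.  Handles both
    number-before-unit orders in transfusion statements and Chinese numerals
    up to ten.  A numeric span is attributed to at most one kind, with
    priority transfusion > blood_loss > drainage.
    """
    found: list[tuple[int, str, float, str]] = []  # (num position, kind, qty, unit)
    used_spans: set[tuple[int, int]] = set()
    searches = [
        ("transfusion_rbc", _TRANSFUSION_PROD_QTY),
        ("transfusion_rbc", _TRANSFUSION_QTY_PROD),
        ("blood_loss", _BLOOD_LOSS),
        ("drainage", _DRAINAGE),
    ]
    for kind, pattern in searches:
        for m in pattern.finditer(text):
            span = m.span("num")
            if any(span[0] < e and s < span[1] for s, e in used_spans):
                continue
            used_spans.add(span)
            found.append((span[0], kind, _parse_num(m.group("num")), _parse_unit(m.group("unit"))))
    found.sort(key=lambda item: item[0])
    return [(kind, qty, unit) for _, kind, qty, unit in found]
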