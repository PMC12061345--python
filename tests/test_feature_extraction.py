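import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemobleed.feature_extraction import (
    CAT1,
    CAT2,
    CAT3,
    N_FEATURES,
    FeatureCatalog,
    FeatureVector,
    build_default_catalog,
    build_frequency_features,
    default_catalog,
    extract_feature_matrix,
    extract_features,
    extract_quantities,
    match_features,
    normalize_text,
    read_feature_csv,
    segment_text,
    write_feature_csv,
)
from hemobleed.synthetic_notes import SyntheticCorpusConfig, generate_corpus

from conftest import make_visit

# fragments used to assemble random clinical-register strings
_FRAGMENTS = [
    "术后", "患者", "腹腔", "引流", "出血", "血性液体", "约300ml", "色暗红",
    "给予", "输注", "悬浮少白红细胞", "2u", "复查", "血红蛋白", "95g/l", "无",
    "生命体征平稳", "切口敷料干燥", "，", "。", "行剖腹探查止血术", "一般情况可",
]


def _random_text(rng, max_parts=8):
    n = int(rng.integers(0, max_parts))
    return "".join(rng.choice(_FRAGMENTS) for _ in range(n))


class TestNormalize:
    def test_width_folding(self):
        assert normalize_text("ＭＬ") == "ml"

    def test_mixed_fullwidth_digits(self):
        assert normalize_text("输血４００ｍｌ") == "输血400ml"

    def test_whitespace_collapse(self):
        assert normalize_text("术后  出血\n\t多") == "术后 出血 多"

    @given(st.text(max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_idempotence(self, text):
        once = normalize_text(text)
        assert normalize_text(once) == once


class TestSegment:
    def test_empty(self):
        assert segment_text("") == []

    def test_coverage_on_clinical_phrase(self):
        text = normalize_text("术后出血")
        tokens = segment_text(text)
        assert "".join(tokens) == text
        assert len(tokens) >= 2

    def test_punctuation_coverage(self):
        text = "，。；！"
        assert "".join(segment_text(text)) == text

    @given(st.integers(0, 10**9))
    @settings(max_examples=50, deadline=None)
    def test_coverage_property(self, seed):
        rng = np.random.default_rng(seed)
        text = normalize_text(_random_text(rng))
        assert "".join(segment_text(text)) == text

    def test_pluggable_segmenter(self):
        chars = lambda s: list(s)
        assert segment_text("术后出血", segmenter=chars) == ["术", "后", "出", "血"]

    def test_bad_segmenter_rejected(self):
        dropper = lambda s: [s[1:]]
        with pytest.raises(ValueError, match="coverage"):
            segment_text("术后", segmenter=dropper)


class TestCatalog:
    def test_shipped_catalog_contract(self, catalog):
        assert len(catalog) == N_FEATURES
        counts = {CAT1: 0, CAT2: 0, CAT3: 0}
        for p in catalog.patterns:
            counts[p.category] += 1
        assert (counts[CAT1], counts[CAT2], counts[CAT3]) == (261, 8, 1)

    def test_key_patterns_flagged(self, catalog):
        assert sum("published_key" in p.flags for p in catalog.patterns) == 20

    def test_feature_ids_contiguous(self, catalog):
        assert [p.feature_id for p in catalog.patterns] == list(range(N_FEATURES))

    def test_builder_matches_shipped_tsv(self, catalog):
        built = build_default_catalog()
        assert [p.pattern for p in built.patterns] == [p.pattern for p in catalog.patterns]
        assert [p.category for p in built.patterns] == [p.category for p in catalog.patterns]

    def test_tsv_round_trip(self, catalog, tmp_path):
        path = tmp_path / "cat.tsv"
        catalog.save_tsv(path)
        loaded = FeatureCatalog.load_tsv(path)
        assert loaded.version == catalog.version
        assert [p.pattern for p in loaded.patterns] == [p.pattern for p in catalog.patterns]

    def test_wrong_length_rejected(self, catalog):
        with pytest.raises(ValueError, match="270"):
            FeatureCatalog(catalog.patterns[:-1], version="bad")

    def test_cat2_tokens_not_covered_by_cat1(self, catalog):
        cat1 = catalog.cat1_compiled()
        for p in catalog.patterns:
            if p.category == CAT2:
                token = p.pattern.replace("\\", "")
                assert not any(c.search(token) for c in cat1), p.pattern


class TestMatchFeatures:
    def test_postoperative_feature(self, catalog):
        values = match_features(normalize_text("术后恢复良好"), catalog)
        assert values[0] == 1  # feature 0 is the postoperative key pattern

    def test_bloody_drainage_compound(self, catalog):
        values = match_features(normalize_text("腹腔引流出血性液体"), catalog)
        fired = {p.description for p in catalog.patterns if values[p.feature_id]}
        assert any("cavity" in d or "site" in d for d in fired)
        assert any("bleed" in d for d in fired)

    def test_empty_text_zero_vector(self, catalog):
        assert match_features("", catalog).sum() == 0

    def test_cat3_left_unset(self, catalog):
        values = match_features(normalize_text("术后出血"), catalog)
        assert values[catalog.cat3_index] == 0

    def test_binary_and_length(self, catalog):
        values = match_features(normalize_text("出血" * 50), catalog)
        assert values.shape == (N_FEATURES,)
        assert set(np.unique(values)) <= {0, 1}

    def test_simple_patterns_against_window_scan_oracle(self, catalog):
        # character-window scan oracle for literal patterns and the two-literal
        # windowed form "A.{0,w}B"; independent of the regex engine
        def literal_scan(text, lit):
            return any(text[i : i + len(lit)] == lit for i in range(len(text)))

        windowed = re.compile(r"^([^\\.{}()|?*+\[\]]+)\.\{0,(\d+)\}([^\\.{}()|?*+\[\]]+)$")
        oracles = []
        for p in catalog.patterns:
            if p.category == CAT3:
                continue
            if not re.search(r"[\\.{}()|?*+\[\]]", p.pattern):
                oracles.append((p.feature_id, "lit", (p.pattern,)))
            else:
                m = windowed.match(p.pattern)
                if m:
                    oracles.append((p.feature_id, "win", (m.group(1), int(m.group(2)), m.group(3))))
        assert len(oracles) > 200
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            text = normalize_text(_random_text(rng))
            values = match_features(text, catalog)
            for fid, kind, args in oracles:
                if kind == "lit":
                    expected = int(literal_scan(text, args[0]))
                else:
                    a, width, b = args
                    expected = 0
                    for i in range(len(text)):
                        if text[i : i + len(a)] != a:
                            continue
                        start = i + len(a)
                        for gap in range(width + 1):
                            j = start + gap
                            if text[j : j + len(b)] == b:
                                expected = 1
                                break
                        if expected:
                            break
                assert values[fid] == expected, (fid, text)


class TestExtractFeatures:
    def test_transfusion_positive_sets_cat3(self, catalog):
        visit = make_visit(transfusions=[(24, 2.0, "U")])
        assert extract_features(visit, catalog).values[catalog.cat3_index] == 1

    def test_bland_visit_mostly_zero(self, catalog):
        visit = make_visit(texts=("一般情况可。",))
        fv = extract_features(visit, catalog)
        assert fv.values[catalog.cat3_index] == 0

    def test_monotone_under_text_append(self, catalog):
        rng = np.random.default_rng(99)
        for _ in range(50):
            base = _random_text(rng) or "一般情况可"
            extra = _random_text(rng)
            v1 = match_features(normalize_text(base), catalog)
            v2 = match_features(normalize_text(base + extra), catalog)
            assert (v2 >= v1).all()

    def test_matrix_equals_per_note_or_oracle(self, catalog):
        visits, _ = generate_corpus(
            SyntheticCorpusConfig(n_visits=50, prevalence=0.1, seed=21, noise_rate=0.5)
        )
        X, ids = extract_feature_matrix(visits, catalog)
        for row, visit in zip(X, visits):
            expected = np.zeros(N_FEATURES, dtype=np.int8)
            for note in visit.notes:  # brute-force per-note loop
                expected |= match_features(normalize_text(note.text), catalog)
            expected[catalog.cat3_index] = row[catalog.cat3_index]
            assert (row == expected).all(), visit.visit_id

    def test_determinism(self, catalog):
        visit = make_visit(texts=("术后腹腔引流出血性液体。",))
        a = extract_features(visit, catalog).values
        b = extract_features(visit, catalog).values
        assert (a == b).all()

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError):
            FeatureVector("V1", np.zeros(100))
        with pytest.raises(ValueError):
            FeatureVector("V1", np.full(N_FEATURES, 2))

    def test_csv_round_trip(self, catalog, tmp_path):
        visits, truths = generate_corpus(
            SyntheticCorpusConfig(n_visits=20, prevalence=0.2, seed=4)
        )
        X, ids = extract_feature_matrix(visits, catalog)
        labels = [1 if t.mechanism != "none" else 0 for t in truths]
        path = tmp_path / "features.csv"
        write_feature_csv(X, ids, path, labels)
        X2, ids2, labels2 = read_feature_csv(path)
        assert (X2 == X).all()
        assert ids2 == ids
        assert labels2.tolist() == labels


class TestFrequencyFeatures:
    def _corpus_with(self, texts):
        return [make_visit(visit_id=f"V{i}", texts=(t,)) for i, t in enumerate(texts)]

    def test_brute_force_count(self):
        # 血肿 appears 7 times across 5 notes
        texts = ["血肿血肿血肿", "血肿", "无血肿", "血肿可见", "有血肿存在"]
        corpus = self._corpus_with(texts)
        results = build_frequency_features(corpus, threshold=3, max_features=5)
        by_token = {r.token: r for r in results}
        assert by_token["血肿"].corpus_frequency == 7
        assert by_token["血肿"].selected

    def test_threshold_filters_everything(self):
        corpus = self._corpus_with(["血肿", "血肿"])
        results = build_frequency_features(corpus, threshold=10)
        assert not any(r.selected for r in results)

    def test_cat1_exclusion(self, catalog):
        corpus = self._corpus_with(["出血出血出血出血"])
        results = build_frequency_features(corpus, threshold=1, exclusions=catalog)
        by_token = {r.token: r for r in results}
        assert not by_token["出血"].selected  # covered by a cat1 pattern

    def test_max_features_cap(self):
        texts = ["引流复查监测血压补液" * 3]
        corpus = self._corpus_with(texts)
        results = build_frequency_features(corpus, threshold=1, max_features=2)
        assert sum(r.selected for r in results) == 2

    def test_sorted_descending(self):
        corpus = self._corpus_with(["引流引流引流复查复查监测"])
        results = build_frequency_features(corpus, threshold=1)
        freqs = [r.corpus_frequency for r in results]
        assert freqs == sorted(freqs, reverse=True)

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            build_frequency_features([], threshold=1)


# hand-annotated oracle snippets: (normalized text, expected extractions)
QUANTITY_ORACLE = [
    ("输注悬浮少白红细胞4u", [("transfusion_rbc", 4.0, "U")]),
    ("输注悬浮少白红细胞2u，过程顺利", [("transfusion_rbc", 2.0, "U")]),
    ("给予输注悬浮少白红细胞3u", [("transfusion_rbc", 3.0, "U")]),
    ("给予2单位红细胞悬液", [("transfusion_rbc", 2.0, "U")]),
    ("予1单位红细胞悬液输注", [("transfusion_rbc", 1.0, "U")]),
    ("输入红细胞悬液400ml", [("transfusion_rbc", 400.0, "mL")]),
    ("输注全血600ml", [("transfusion_rbc", 600.0, "mL")]),
    ("给予红悬2u", [("transfusion_rbc", 2.0, "U")]),
    ("输红细胞2单位", [("transfusion_rbc", 2.0, "U")]),
    ("输注悬浮少白红细胞两单位", [("transfusion_rbc", 2.0, "U")]),
    ("给予输注红细胞悬液一单位", [("transfusion_rbc", 1.0, "U")]),
    ("术中输悬浮红细胞4单位", [("transfusion_rbc", 4.0, "U")]),
    ("输注少白悬浮红细胞2.5u", [("transfusion_rbc", 2.5, "U")]),
    ("予400ml全血输注", [("transfusion_rbc", 400.0, "mL")]),
    ("输2u红悬", [("transfusion_rbc", 2.0, "U")]),
    ("出血约300ml", [("blood_loss", 300.0, "mL")]),
    ("术中出血约100ml", [("blood_loss", 100.0, "mL")]),
    ("出血50ml", [("blood_loss", 50.0, "mL")]),
    ("失血约1000ml", [("blood_loss", 1000.0, "mL")]),
    ("术中失血200cc", [("blood_loss", 200.0, "mL")]),
    ("出血量约800毫升", [("blood_loss", 800.0, "mL")]),
    ("渗血约30ml", [("blood_loss", 30.0, "mL")]),
    ("出血约2000ml，失血性休克", [("blood_loss", 2000.0, "mL")]),
    ("引流出淡红色液体约50ml", [("drainage", 50.0, "mL")]),
    ("引流量约120ml", [("drainage", 120.0, "mL")]),
    ("腹腔引流管引流出150ml液体", [("drainage", 150.0, "mL")]),
    ("引流液300cc", [("drainage", 300.0, "mL")]),
    ("盆腔引流约80毫升", [("drainage", 80.0, "mL")]),
    # negatives: no quantity or no qualifying context
    ("患者一般情况可", []),
    ("无出血征象", []),
    ("出血已止", []),
    ("给予补液500ml", []),  # crystalloid, not an rbc product
    ("体温38.2度", []),
    ("引流管通畅", []),
    ("血红蛋白95g/l", []),
    ("白细胞10.5", []),
    ("输液治疗", []),
    ("止血治疗后好转", []),
    ("血压120/80mmhg", []),
    ("请血库备红细胞悬液", []),  # no transfusion verb with quantity
    # combinations
    ("术中出血约400ml，输注悬浮少白红细胞2u",
     [("blood_loss", 400.0, "mL"), ("transfusion_rbc", 2.0, "U")]),
    ("出血约600ml，予4单位红细胞悬液",
     [("blood_loss", 600.0, "mL"), ("transfusion_rbc", 4.0, "U")]),
    ("引流出血性液体约200ml", [("blood_loss", 200.0, "mL")]),  # 出血 takes priority
    ("术中出血約300ml", [("blood_loss", 300.0, "mL")]),  # stray char sits in the gap
    ("失血约450ml，输全血800ml",
     [("blood_loss", 450.0, "mL"), ("transfusion_rbc", 800.0, "mL")]),
    ("输注悬浮少白红细胞2u，术中出血约150ml",
     [("transfusion_rbc", 2.0, "U"), ("blood_loss", 150.0, "mL")]),
    ("引流约60ml，色清亮", [("drainage", 60.0, "mL")]),
    ("出血十ml", [("blood_loss", 10.0, "mL")]),
    ("输注红细胞三u", [("transfusion_rbc", 3.0, "U")]),
    ("出血5ml，量极少", [("blood_loss", 5.0, "mL")]),
    ("输悬浮少白红细胞1.5单位", [("transfusion_rbc", 1.5, "U")]),
]


class TestQuantityExtraction:
    def test_oracle_size(self):
        assert len(QUANTITY_ORACLE) >= 50

    @pytest.mark.parametrize("text,expected", QUANTITY_ORACLE, ids=range(len(QUANTITY_ORACLE)))
    def test_annotated_snippets(self, text, expected):
        assert extract_quantities(text) == expected

    def test_non_matching_returns_empty(self):
        assert extract_quantities("") == []
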