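"""Dual-detection merging and assessment JSON contracts."""

import json

import numpy as np
import pytest

from radqc import (
    ContextTrainingConfig,
    Detection,
    assess,
    assess_report,
    from_json,
    inject,
    merge,
    to_json,
    train,
    validate_assessment_dict,
)
from radqc.integrate import ReportAssessment, SchemaError, assessment_to_dict


def det(start, end, source="contextual", error_type="spelling_mistake",
        suggestion=None, confidence=0.5):
    return Detection(source=source, start=start, end=end, error_type=error_type,
                     suggestion=suggestion, confidence=confidence)


class TestMerge:
    def test_both_empty(self):
        assert merge([], []) == []

    def test_total_overlap_fuses_with_rule_precedence(self):
        contextual = [det(2, 4, suggestion="上叶")]
        rule = [det(2, 4, source="rule", error_type="gender_error",
                    suggestion="子宫", confidence=1.0)]
        (fused,) = merge(contextual, rule)
        assert fused.source == "both"
        assert fused.error_type == "gender_error"
        assert fused.suggestion == "子宫"
        assert fused.confidence == 1.0

    def test_disjoint_pass_through_sorted(self):
        merged = merge([det(5, 7)], [det(0, 2, source="rule", error_type="age_error")])
        assert [(d.start, d.end) for d in merged] == [(0, 2), (5, 7)]

    def test_fusion_idempotent(self):
        contextual = [det(0, 3), det(10, 12)]
        rule = [det(2, 5, source="rule", error_type="side_confusion")]
        once = merge(contextual, rule)
        assert merge(once, []) == once

    def test_matches_brute_force_overlap_clustering(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            spans_a = [det(int(s), int(s + w)) for s, w in
                       zip(rng.integers(0, 40, 5), rng.integers(1, 6, 5))]
            spans_b = [det(int(s), int(s + w), source="rule", error_type="age_error",
                           confidence=1.0)
                       for s, w in zip(rng.integers(0, 40, 5), rng.integers(1, 6, 5))]
            merged = merge(spans_a, spans_b)
            # oracle: union-find over pairwise interval overlaps
            items = sorted(spans_a + spans_b, key=lambda d: (d.start, d.end))
            parent = list(range(len(items)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    if max(items[i].start, items[j].start) < min(items[i].end,
                                                                 items[j].end):
                        parent[find(i)] = find(j)
            clusters = {}
            for i, item in enumerate(items):
                clusters.setdefault(find(i), []).append(item)
            oracle_spans = sorted(
                (min(d.start for d in c), max(d.end for d in c))
                for c in clusters.values()
            )
            assert [(d.start, d.end) for d in merged] == oracle_spans
            for a, b in zip(merged, merged[1:]):
                assert a.end <= b.start  # non-overlapping output


@pytest.fixture(scope="module")
def assessed(corpus, model, threshold, ruleset, lexicon):
    report = next(
        r for r in corpus
        if any("sex_specific" in m.attributes for m in lexicon.match_entities(r.text))
    )
    pair = inject(report, "gender_error", 11, lexicon)
    corrupted = assess(pair.corrupted_text, report.metadata, model, threshold,
                       ruleset, lexicon, report_id=report.id)
    clean = assess_report(report, model, threshold, ruleset, lexicon)
    return report, pair, clean, corrupted


class TestAssess:
    def test_clean_report_is_clean(self, assessed):
        _, _, clean, _ = assessed
        assert clean.status == "clean"
        assert clean.error_count == 0

    def test_injected_gender_error_flagged_with_type(self, assessed):
        _, pair, _, corrupted = assessed
        assert corrupted.status == "flagged"
        gold = pair.annotations[0]
        hits = [
            d for d in corrupted.detections
            if d.error_type == "gender_error"
            and max(d.start, gold.start) < min(d.end, gold.end)
        ]
        assert len(hits) == 1
        assert hits[0].source in {"rule", "both"}

    def test_text_never_mutated(self, assessed, model, threshold, ruleset, lexicon):
        report, pair, _, _ = assessed
        before = pair.corrupted_text
        assess(pair.corrupted_text, report.metadata, model, threshold, ruleset, lexicon)
        assert pair.corrupted_text == before

    def test_homophone_fragment_suggests_correct_term(self, lexicon, ruleset):
        corpus = ["左肺上叶可见结节影。", "右肺下叶可见阴影。"] * 30
        model = train(corpus, ContextTrainingConfig(rng_seed=3))
        from radqc import calibrate_threshold
        thr = calibrate_threshold(model, corpus)
        from radqc.synthesis import ReportMetadata
        meta = ReportMetadata(patient_sex="male", age_years=40, modality="CT",
                              submission_period="daytime",
                              radiologist_title="attending", month_index=0)
        assessment = assess("左肺商业可见结节影。", meta, model, thr, ruleset, lexicon)
        assert assessment.status == "flagged"
        assert any(d.suggestion == "上叶" for d in assessment.detections)


class TestJson:
    def test_clean_assessment_document(self):
        doc = assessment_to_dict(ReportAssessment("r1", ()))
        assert doc == {"report_id": "r1", "status": "clean", "error_count": 0,
                       "detections": []}
        validate_assessment_dict(doc)

    def test_round_trip_on_random_assessments(self):
        rng = np.random.default_rng(7)
        types = ["spelling_mistake", "gender_error", "age_error", "other"]
        for _ in range(200):
            detections = []
            cursor = 0
            for _ in range(rng.integers(0, 4)):
                start = cursor + int(rng.integers(0, 5))
                end = start + int(rng.integers(1, 4))
                cursor = end + 1
                detections.append(det(
                    start, end,
                    source=["contextual", "rule", "both"][rng.integers(3)],
                    error_type=types[rng.integers(len(types))],
                    suggestion=None if rng.random() < 0.5 else "上叶",
                    confidence=float(np.round(rng.random(), 6)),
                ))
            assessment = ReportAssessment(f"r{rng.integers(1e6)}", tuple(detections))
            doc = json.loads(to_json(assessment))
            validate_assessment_dict(doc)
            assert from_json(to_json(assessment)) == assessment

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda d: d.pop("status"),
            lambda d: d.update(status="ok"),
            lambda d: d.update(error_count=99),
            lambda d: d.update(extra=1),
            lambda d: d["detections"].append({}),
        ],
    )
    def test_schema_violations_rejected(self, mutate):
        doc = assessment_to_dict(ReportAssessment("r1", ()))
        mutate(doc)
        with pytest.raises(SchemaError):
            validate_assessment_dict(doc)
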