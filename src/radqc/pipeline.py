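"""End-to-end workflow functions: generate → corrupt → train → detect → evaluate.

These are the package's batch entry points (the scripts in ``examples/``
show them in narrative form). Each step is a plain function taking a seed
and explicit paths, writes its output atomically (temp-then-rename), never
mutates its inputs, and logs command, seed, counts and timing to stderr —
so a rerun with the same arguments is byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
import os
import time
from pathlib import Path
from typing import Mapping, Sequence

from . import context, evaluation, injection, integrate, rules as rules_mod, synthesis
from .lexicon import Lexicon, default_lexicon, load_lexicon

logger = logging.getLogger("radqc")
if not logger.handlers:  # stderr by default, quiet unless configured
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)


def _atomic_write(path, content: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as handle:
        handle.write(content)
    os.replace(tmp, path)


def _resources(lexicon_path=None, homophone_path=None, rules_path=None, templates_path=None):
    if lexicon_path is not None:
        lexicon = load_lexicon(lexicon_path, homophone_path)
    else:
        lexicon = default_lexicon()
    ruleset = rules_mod.load_rules(rules_path) if rules_path else rules_mod.default_rules()
    templates = (
        synthesis.load_templates(templates_path) if templates_path
        else synthesis.default_templates()
    )
    return lexicon, ruleset, templates


def run_generate(
    n: int,
    seed: int,
    out_path,
    mix: Mapping[str, Mapping[str, float]] | None = None,
    lexicon: Lexicon | None = None,
    templates: synthesis.TemplateSet | None = None,
) -> list[synthesis.Report]:
    started = time.perf_counter()
    reports = synthesis.generate_corpus(
        n, seed, mix=mix, templates=templates, lexicon=lexicon
    )
    lines = [
        json.dumps(synthesis.report_to_record(r), ensure_ascii=False, sort_keys=True)
        for r in reports
    ]
    _atomic_write(out_path, "".join(line + "\n" for line in lines))
    logger.info("generate seed=%d n=%d out=%s elapsed=%.2fs",
                seed, len(reports), out_path, time.perf_counter() - started)
    return reports


def run_corrupt(
    corpus_path,
    seed: int,
    out_path,
    per_report_error_prob: float = 0.5,
    type_mix: Mapping[str, float] | None = None,
    lexicon: Lexicon | None = None,
) -> list[injection.CorruptedReport]:
    started = time.perf_counter()
    reports = synthesis.read_corpus(corpus_path)
    pairs = injection.generate_paired_corpus(
        reports, per_report_error_prob, type_mix, rng_seed=seed, lexicon=lexicon
    )
    lines = [
        json.dumps(injection.pair_to_record(p), ensure_ascii=False, sort_keys=True)
        for p in pairs
    ]
    _atomic_write(out_path, "".join(line + "\n" for line in lines))
    corrupted = sum(p.is_corrupted for p in pairs)
    logger.info("corrupt seed=%d n=%d corrupted=%d out=%s elapsed=%.2fs",
                seed, len(pairs), corrupted, out_path, time.perf_counter() - started)
    return pairs


def run_train(
    corpus_path,
    seed: int,
    out_path,
    mask_rate: float = 0.15,
    epochs: int = 10,
    order: int = 2,
) -> context.ContextModel:
    started = time.perf_counter()
    reports = synthesis.read_corpus(corpus_path)
    config = context.ContextTrainingConfig(
        mask_rate=mask_rate, rng_seed=seed, epochs=epochs, order=order
    )
    model = context.train(reports, config)
    _atomic_write(out_path, model.to_json())
    logger.info("train seed=%d reports=%d vocab=%d out=%s elapsed=%.2fs",
                seed, len(reports), len(model.vocab), out_path,
                time.perf_counter() - started)
    return model


def run_detect(
    paired_path,
    model_path,
    out_path,
    threshold: float | None = None,
    rules_path=None,
    lexicon: Lexicon | None = None,
    target_false_flag_rate: float = 0.05,
) -> list[integrate.ReportAssessment]:
    """Assess the corrupted side of a paired corpus.

    With ``threshold=None`` the surprisal cutoff is calibrated on the clean
    halves of the input pairs at the target false-flag rate.
    """
    started = time.perf_counter()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    ruleset = rules_mod.load_rules(rules_path) if rules_path else rules_mod.default_rules()
    model = context.ContextModel.load(model_path)
    pairs = injection.read_paired_corpus(paired_path)
    if threshold is None:
        threshold = context.calibrate_threshold(
            model, [p.clean.text for p in pairs], target_false_flag_rate
        )
    assessments = []
    for pair in pairs:
        assessments.append(
            integrate.assess(
                pair.corrupted_text,
                pair.clean.metadata,
                model,
                threshold,
                ruleset,
                lexicon,
                report_id=pair.clean.id,
            )
        )
    lines = []
    for assessment in assessments:
        doc = integrate.assessment_to_dict(assessment)
        integrate.validate_assessment_dict(doc)
        lines.append(json.dumps(doc, ensure_ascii=False, sort_keys=True))
    _atomic_write(out_path, "".join(line + "\n" for line in lines))
    flagged = sum(a.status == "flagged" for a in assessments)
    logger.info(
        "detect n=%d flagged=%d threshold=%.3f out=%s elapsed=%.2fs (%.1f ms/report)",
        len(assessments), flagged, threshold, out_path,
        time.perf_counter() - started,
        1000 * (time.perf_counter() - started) / max(1, len(assessments)),
    )
    return assessments


def read_assessments(path) -> dict[str, integrate.ReportAssessment]:
    out = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                assessment = integrate.assessment_from_dict(json.loads(line))
                out[assessment.report_id] = assessment
    return out


def run_evaluate(
    pred_path,
    gold_path,
    out_json,
    out_csv=None,
    resamples: int = 1000,
    seed: int = 0,
    criterion: evaluation.MatchCriterion | None = None,
) -> dict:
    """Score predicted assessments against gold annotations.

    Writes a metrics JSON ``{metric: {point, ci_low, ci_high}}`` (percentile
    bootstrap over reports) and, optionally, a per-type detection-rate CSV
    (type matching enforced per type).
    """
    started = time.perf_counter()
    criterion = criterion or evaluation.MatchCriterion()
    assessments = read_assessments(pred_path)
    pairs = injection.read_paired_corpus(gold_path)
    predicted = {a.report_id: list(a.detections) for a in assessments.values()}
    gold = {p.clean.id: list(p.annotations) for p in pairs}
    per_report = evaluation.match_detections_per_report(predicted, gold, criterion)
    outcomes = list(per_report.values())

    def _sum(sample: Sequence[evaluation.ConfusionCounts]) -> evaluation.ConfusionCounts:
        total = evaluation.ConfusionCounts()
        for c in sample:
            total = evaluation.ConfusionCounts(
                total.tp + c.tp, total.fp + c.fp, total.fn + c.fn
            )
        return total

    metric_fns = {
        "precision": lambda s: evaluation.precision(_sum(s)),
        "recall": lambda s: evaluation.recall(_sum(s)),
        "f1": lambda s: evaluation.f1(_sum(s)),
        "accuracy": lambda s: evaluation.accuracy(
            evaluation.with_report_level_tn(_sum(s), len(s))
        ),
    }
    metrics = {}
    for name, fn in metric_fns.items():
        ci = evaluation.bootstrap_ci(fn, outcomes, resamples=resamples, rng_seed=seed)
        metrics[name] = {"point": ci.point, "ci_low": ci.ci_low, "ci_high": ci.ci_high}
    _atomic_write(out_json, json.dumps(metrics, sort_keys=True, indent=2) + "\n")

    if out_csv is not None:
        typed = evaluation.MatchCriterion(
            span_policy=criterion.span_policy, require_type_match=True
        )
        rows = []
        for error_type in injection.ERROR_TYPES:
            gold_t = {
                rid: [a for a in anns if a.error_type == error_type]
                for rid, anns in gold.items()
            }
            pred_t = {
                rid: [d for d in dets if d.error_type == error_type]
                for rid, dets in predicted.items()
            }
            counts = evaluation.match_detections(pred_t, gold_t, typed)
            total_gold = counts.tp + counts.fn
            rate = evaluation.percent(counts.tp / total_gold) if total_gold else ""
            rows.append((error_type, counts.tp, total_gold, rate))
        tmp = Path(out_csv).with_name(Path(out_csv).name + ".tmp")
        with open(tmp, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["error_type", "detected", "gold", "detection_rate_percent"])
            writer.writerows(rows)
        os.replace(tmp, out_csv)

    logger.info("evaluate n=%d seed=%d out=%s elapsed=%.2fs",
                len(outcomes), seed, out_json, time.perf_counter() - started)
    return metrics
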