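# radqc

Semantic-error detection and quality control for Chinese radiology reports.

Radiology reports written under time pressure accumulate *semantic* errors —
defects that change meaning without being diagnostic mistakes: homophone
typos (上叶 "upper lobe" mistyped as 商业 "business"), left/right side
confusion, wrong measurement units, sex-, age- or modality-inconsistent
terms. `radqc` implements a desk-scale dual-detection pipeline for this
problem, plus everything needed to study it without access to hospital data:

1. **Synthetic corpus generation** — template-based Chinese reports (DR / CT
   / MRI) whose text is consistent with patient metadata by construction,
   standing in for a proofread clinical corpus.
2. **Error injection** — seven error types injected by entity substitution,
   omission or insertion, with exact gold annotations whose inverse edits
   reconstruct the clean text.
3. **Contextual detection** — a masked-token character context model: each
   character is scored by the probability the model assigns to it when
   masked (a pseudo-likelihood); high-surprisal runs are flagged and
   corrections are ranked from homophone confusion sets.
4. **Rule checking** — a declarative entity-relationship database: mentions
   extracted by longest-match dictionary lookup are checked against metadata
   (sex, age band, modality), co-mentions (laterality contradictions) and
   context (unit/measurement-cue compatibility). Rules can also be mined
   from paired clean/corrupted corpora.
5. **Integration** — contextual and rule detections fuse into one
   non-overlapping assessment, serialized to a fixed JSON schema.
6. **Evaluation** — span matching against gold, precision / recall / F1 /
   accuracy with percentile-bootstrap CIs (report-level resampling), Cohen's
   κ, Gwet AC1, χ² proportion tests, stratified error rates, monthly-rate
   OLS regression and the Wilcoxon rank-sum test.

## The core statistics

For confusion counts (tp, fp, fn, tn over an annotated test set):

    precision = tp / (tp + fp)        recall = tp / (tp + fn)
    F1 = 2·tp / (2·tp + fp + fn)      accuracy = (tp + tn) / n

with 95% CIs from nonparametric bootstrapping (1,000 resamples of reports).
Agreement between two raters uses κ = (p_o − p_e)/(1 − p_e) with
p_e = Σ_k r_k·c_k (marginal products) and Gwet's AC1 with
p_e = (1/(K−1))·Σ_k π_k(1 − π_k), π_k the mean marginal proportion of
category k. The contextual detector's token score is the surprisal
−log p(c_i | context), with the flag threshold calibrated on held-out clean
reports to a target false-flag rate.

## Worked example

```python
from radqc import (ContextTrainingConfig, calibrate_threshold, default_lexicon,
                   generate_corpus, score_tokens, detect_anomalies,
                   suggest_correction, train)

lexicon = default_lexicon()
corpus = generate_corpus(2000, rng_seed=42)
model = train(corpus, ContextTrainingConfig(mask_rate=0.15, rng_seed=1))
threshold = calibrate_threshold(
    model, [r.text for r in generate_corpus(300, rng_seed=99)])

text = "胸部CT平扫示:左肺商业可见结节影。"
spans = detect_anomalies(score_tokens(model, text), threshold)
print(spans, [text[s:e] for s, e in spans])
span = (text.index("商业"), text.index("商业") + 2)
print(suggest_correction(model, text, span, lexicon.confusion_set("商业")))
```

prints

```
[(7, 12)] [':左肺商业']
[CorrectionCandidate(surface='上叶', context_score=-0.398...)]
```

i.e. the run of surprising characters around the typo is flagged, and the
confusion-set candidate 上叶 is ranked as the in-context correction. The
scripts in `examples/` walk through each capability (generation, injection,
contextual detection, rule checking, end-to-end evaluation, agreement
statistics) and print what the numbers mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end result from scratch: it generates a
2,000-report corpus, injects single errors at the default per-type mix,
trains the reference context model, calibrates the flag threshold on a
held-out clean split, runs dual detection on every report, and scores the
detections against the gold annotations, writing the report to `--out`. All
randomness derives from `--seed`.

## Layout

    src/radqc/        lexicon, synthesis, injection, context, rules,
                      integrate, evaluation, pipeline (+ bundled TSV/JSON
                      resources under data/)
    tests/            pytest suite, including acceptance-level checks
    examples/         narrative scripts, one per capability
    docs/methods.md   model, assumptions, parameters, design choices
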