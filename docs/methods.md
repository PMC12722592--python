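# Methods

This note documents the models and procedures `radqc` implements, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Problem setting

The package targets *semantic* errors in Chinese radiology reports: defects
that change or contradict meaning — homophone typos, left/right confusion,
wrong measurement units, sex-/age-/modality-inconsistent terms — as opposed
to diagnostic misreadings of images. Detection is *dual*: a statistical
contextual model catches locally implausible character sequences, and an
exact entity-relationship rule base catches knowledge-level inconsistencies.
The two outputs are merged into a single per-report assessment. The engine
never modifies report text; it emits annotations only.

## Entity lexicon and matching

Entities fall into 11 categories (orientation, anatomical location,
qualitative, size, measurement unit, positive sign, negative sign,
diagnosis, gender-related, device-related, age-related); an entry may carry
several categories at once (前列腺 is both an anatomical location and a
male-specific term). Attributes drive the rule engine: `sex_specific`
(male/female), `modality_set` (subset of {DR, CT, MRI}), `age_band`
(inclusive years), `laterality` (left/right/none).

Extraction is greedy left-to-right longest-match dictionary lookup over raw
characters — no word segmentation, offsets are 0-based half-open Unicode
code points. A learned extractor would not be exactly testable at this
scale; with an enumerable lexicon, longest-match makes extraction
deterministic and its behaviour provable in tests. Duplicate lexicon rows
merge by category-set union; equal-length ties cannot occur because surfaces
are unique keys.

## Synthetic report generation

Real corpora of finalized reports are hospital-private, so the generator
*is* the corpus: declarative templates per modality with typed slots, filled
only with lexicon entries whose attributes are compatible with the sampled
metadata. This yields a zero-error ground truth by construction (the role a
radiologist-panel proofread corpus plays in practice) and guarantees the
generator–rule-set cleanliness invariant: `check()` returns no violation on
any generated report, for any seed.

Default stratum proportions are the baseline-collection values of the
setting this package emulates: modality 26.6% DR / 55.7% CT / 17.7% MRI,
85.7% daytime, 69.3% attending; sex is balanced and age is uniform on
1–90 years (neither is reported for the reference collections). Daytime is
08:00–17:59 and nighttime is defined as its complement — the source
material's nighttime window (06:00–07:59) does not complement its own
daytime window and is treated as a typo. `month_index` is uniform over a
28-month study window (12 baseline + 16 post-deployment months) so
monthly-rate analyses need no date arithmetic. A report's findings and
impression are joined with a newline into one span-addressable text.

## Error injection

Seven types, one error per corrupted report by default (single-error pairs
make gold matching unambiguous; per-type evaluation counts errors
individually). Mechanics:

* **spelling_mistake** — replace an entity with a homophone-group co-member
  (上叶 → 商业). Replacement surfaces are deliberately absent from the
  lexicon, so spelling errors are invisible to the rule engine and exercise
  the contextual detector alone.
* **side_confusion** — swap one 左/右 orientation mention adjacent to an
  anatomical mention. Only sites where the same (side, anatomy) pair occurs
  at least twice are viable, so a single swap always leaves an intra-report
  contradiction; vertical orientations (上/下) are spared to keep the type
  pure. Without images, left/right truth is unknowable, so this is the only
  grounding under which side errors are decidable — and it makes rule-engine
  completeness on side injections exact rather than probabilistic.
* **incorrect_measurement_unit** — substitute a unit with one of a
  *different dimension class* (length cm/mm vs attenuation HU); a same-class
  swap would be a rescaling, not a semantic error.
* **gender_error / age_error** — substitute an existing sex-/age-bound
  mention with a metadata-incompatible entity, or, when none exists, insert
  one after a punctuation mark.
* **mismatched_imaging_modality** — substitute a device-related term with
  one whose modality set excludes the report's modality.
* **other** — residual class: omit or insert a single character outside
  entity spans (filler characters never occur in lexicon surfaces).

If a drawn type has no viable site, the type is redrawn from the
renormalized remaining mix (up to 7 draws), then the report is left clean —
corpus size is preserved at the cost of some distortion of the realized type
mix on templates lacking certain sites; the distributional-recovery test
therefore runs on a template where all seven types are viable. The default
type mix is the per-type reference-standard proportions
310/35/40/24/18/45/34 (out of 506). Gold annotations address the corrupted
text; applying their inverse edits right-to-left reconstructs the clean text
exactly.

## Contextual detector

The reference backbone is an order-2 bidirectional character context model
with additive smoothing (α = 0.01): left and right context each predict a
distribution over the vocabulary plus one out-of-vocabulary slot; the
combined prediction is their renormalized product. Training emulates the
masked-language-model objective: per pass, each character is masked
independently with probability `mask_rate` (default 0.15) and the model's
context counts are updated at masked positions only; 10 passes by default.
This trains in seconds, is exactly reproducible under a seed, and
serializes to a versioned JSON artifact — properties a 110M-parameter
transformer backbone does not have at desk scale. The backbone is pluggable
behind the `ContextModel` contract (a normalized distribution given
left/right context), so a neural model can be substituted without touching
the downstream stages.

Scoring masks each position and evaluates the probability of the observed
character (pseudo-likelihood); the anomaly score is the surprisal −log p.
Maximal runs of tokens with surprisal above a threshold merge into flagged
spans. The threshold is a calibration parameter, not a constant: it is set
to the (1 − target) quantile of per-report maximum surprisal on a held-out
clean split, targeting a 5% report-level false-flag rate by default.
Correction candidates from the homophone confusion set are ranked by the
mean log-probability of the affected window after substitution; ties break
lexicographically. Because a flagged run often spills into the neighbours of
a typo, the integrator searches the span for the longest confusion-indexed
substring before ranking corrections.

## Rule engine

Rules are declarative config (JSON), each mapping an invalid relation to an
error type: sex, age-band and modality consistency against metadata;
laterality contradiction (same anatomy mentioned with both sides);
unit–context compatibility (the nearest measurement cue within a 14-char
window — 大小约/直径约 expect cm/mm, CT值 expects HU — governs the unit).
Violations are reported once per satisfied predicate, ordered by span start
then rule id, with policy-driven suggestions (first metadata-compatible
alternative, majority side, first allowed unit).

Rules can also be mined from a paired corpus: attribute × metadata
combinations (sex_specific × patient sex, device modality-set × report
modality, age-band exclusion) that occur only in corrupted reports, with the
majority gold error type attached. Mining covers the categorical metadata
families; unit and side rules are context/co-mention predicates and remain
declared-only. Declared rules win on id collision.

## Integration

Detections sharing at least one position fuse into one span
(`source="both"`); the rule engine's type and suggestion take precedence
because rules are exact while the contextual model is statistical.
Contextual-only detections default to `spelling_mistake`, the family the
confusion-set mechanism realizes — this makes typing total, at the known
cost that "other"-type corruptions are flagged but typed as spelling.
Confidence is 1.0 for rule detections and 1 − exp(−mean surprisal) for
contextual ones (one minus the geometric-mean token likelihood over the
span, i.e. surprisal mapped back to probability scale). Assessments
serialize to a fixed all-keys-required JSON schema validated by a built-in
validator.

## Evaluation

Matching is one-to-one per report: candidate pairs under the criterion
(span overlap by default, optionally exact spans and/or type equality) are
completed to a maximum bipartite matching, so tp equals the exhaustive
matching size. Zero-width omission spans match their one-character
neighbourhood. Accuracy needs a true-negative convention; the report-level
convention tn = n_reports − tp − fp − fn is used, which is the convention
under which the reference worked example's printed accuracy is reproducible.
Note one documented discrepancy: from the reference counts (tp = 437,
fp = 58, fn = 69), F1 = 874/1001 = 87.3% after half-up rounding, while the
commonly quoted value is 87.4%; the tests assert the arithmetically correct
value.

Bootstrap CIs are percentile intervals over resampled *reports* (errors
within a report are dependent), 1,000 resamples by default. χ² is Pearson
without continuity correction (negligible at these sample sizes). Rates
render half-up — one decimal for metrics, two decimals for rates below 10%.
OLS uses classical standard errors and two-tailed t tests (statsmodels
backed, checked against a normal-equations oracle); binary predictors encode
the reference level as 0. The Wilcoxon rank-sum test uses midranks, exact
enumeration of rank assignments for pooled n ≤ 20 (valid under ties because
it conditions on observed midranks) and the tie-corrected normal
approximation otherwise.

## What a green test does and does not establish

The synthetic world is templated: its narrative diversity is far below real
clinical text, the contextual model can nearly memorize it, and the rule set
is mutually consistent with the generator by construction. Green closed-loop
tests therefore establish that the pipeline's mechanics are correct — exact
rule completeness on metadata-inconsistency injections, calibrated
false-flag control, faithful gold annotations — not that this detector would
reach comparable performance on hospital data. Field results that depend on
private data (inter-rater agreement levels, deployment effect sizes,
questionnaire scores) are deliberately replaced by property-based checks of
the statistics that would compute them.

## Known limitations

* Dictionary matching cannot find entities outside the lexicon; nested
  entities resolve to the longest match only.
* The laterality rule treats bilateral findings of the same organ as a
  contradiction; real reports mention 左/右 pairs legitimately, so this rule
  would need co-reference logic on real text.
* "other"-type corruptions are detected contextually but typed as spelling
  by the integrator's default-typing rule.
* The reference context model has a two-character horizon per direction;
  long-range inconsistencies are the rule engine's job.
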