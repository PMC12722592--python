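"""Generate a small synthetic radiology report corpus and inspect it.

The generator fills modality-specific templates with lexicon entries that are
compatible with the sampled metadata (sex, age, modality), so every report is
internally consistent — a zero-error ground truth for the rest of the
pipeline.
"""

from collections import Counter

from radqc import generate_corpus

reports = generate_corpus(500, rng_seed=42)

print("first report:")
print(" ", reports[0].metadata)
print(" ", reports[0].text.replace("\n", " / "))

mix = Counter(r.metadata.modality for r in reports)
print("\nmodality counts over 500 reports:", dict(mix))
print("(target mix is 26.6% DR / 55.7% CT / 17.7% MRI; counts are a seeded")
print(" multinomial draw around those proportions)")
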