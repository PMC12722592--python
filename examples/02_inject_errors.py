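"""Corrupt clean reports with the seven semantic error types.

Each corrupted report carries gold annotations: the span in the corrupted
text, the edit mechanism, and the correction. Applying the inverse edits
reconstructs the clean text exactly.
"""

from collections import Counter

from radqc import generate_corpus, generate_paired_corpus, reconstruct_clean

reports = generate_corpus(600, rng_seed=7)
pairs = generate_paired_corpus(reports, per_report_error_prob=1.0, rng_seed=8)

types = Counter(a.error_type for p in pairs for a in p.annotations)
print("injected error types over 600 reports:")
for error_type, count in types.most_common():
    print(f"  {error_type:32s} {count}")
print("(drawn from the per-type reference proportions, e.g. spelling ~61%)")

example = next(p for p in pairs if p.annotations[0].error_type == "spelling_mistake")
annotation = example.annotations[0]
print("\nexample spelling corruption:")
print("  clean    :", example.clean.text.replace("\n", " / "))
print("  corrupted:", example.corrupted_text.replace("\n", " / "))
print(f"  gold: {annotation.original!r} -> {annotation.corrupted!r} "
      f"at {annotation.start}:{annotation.end}, suggestion {annotation.suggestion!r}")

ok = all(reconstruct_clean(p.corrupted_text, p.annotations) == p.clean.text
         for p in pairs)
print("\ninverse edits reconstruct every clean text:", ok)
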