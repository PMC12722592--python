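"""Full pipeline: generate -> corrupt -> train -> detect -> evaluate.

Runs the five workflow steps through their file interfaces and prints the
detection metrics with bootstrap confidence intervals, plus the per-type
detection-rate table.
"""

import json
import tempfile
from pathlib import Path

from radqc import pipeline

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    pipeline.run_generate(1000, seed=42, out_path=root / "corpus.jsonl")
    pipeline.run_corrupt(root / "corpus.jsonl", seed=43,
                         out_path=root / "paired.jsonl", per_report_error_prob=0.5)
    pipeline.run_train(root / "corpus.jsonl", seed=44, out_path=root / "model.json")
    pipeline.run_detect(root / "paired.jsonl", root / "model.json",
                        out_path=root / "assessments.jsonl")
    metrics = pipeline.run_evaluate(
        root / "assessments.jsonl", root / "paired.jsonl",
        out_json=root / "metrics.json", out_csv=root / "by_type.csv",
        resamples=1000, seed=45,
    )
    print("\ndetection metrics (point [95% bootstrap CI], span-overlap matching):")
    for name, entry in metrics.items():
        print(f"  {name:9s} {100 * entry['point']:.1f}% "
              f"[{100 * entry['ci_low']:.1f}, {100 * entry['ci_high']:.1f}]")
    print("\nper-type detection rates (type-matched):")
    print((root / "by_type.csv").read_text(encoding="utf-8"))
    print("(high values are expected: the detector is evaluated on the same")
    print(" synthetic world it was built for — this validates the pipeline's")
    print(" mechanics, not clinical performance)")
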