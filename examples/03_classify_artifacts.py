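"""Classify miRNAs with the control-experiment evidence rules.

The control design contrasts intact and 96 h-degraded liver RNA (± DNase
digestion) with small-RNA-depleted RNA fragmented in vitro by RNase.  A
probe that lights up in degraded tissue AND in depleted, RNase-fragmented
RNA cannot be reporting a real miRNA — the depleted input contains
(almost) none — so it is labelled a likely cross-hybridization artifact.
A probe elevated only when DNase digestion is omitted is DNA background.
"""

from collections import Counter

import numpy as np

from mirdegrade import (
    SimConfig,
    build_evidence,
    classify,
    detection_filter,
    glog_normalize,
    simulate_study,
    version_bias_summary,
)

study = simulate_study(SimConfig(seed=1))
control = glog_normalize(detection_filter(study.control, 5))

evidence = build_evidence(control, study.control_meta)
labels = classify(evidence, fold_change=2.0, annotation=study.annotation)

counts = Counter(c.label for c in labels)
print("per-label counts:")
for label, n in counts.most_common():
    print(f"  {label:36s} {n}")

table = version_bias_summary(labels)
print("\nmiRBase annotation era by label (counts):")
print(table.to_string())
med = table.attrs["median_version_by_label"]
print(f"\nmedian first version: likely_artifact {med['likely_artifact']:.0f} "
      f"vs sensitive {med['sensitive']:.0f} — artifacts concentrate in the "
      "most recent annotation releases")

truth = study.truth_by_id()
hit = np.mean([
    c.label == "likely_artifact"
    for c in labels if truth[c.mirna_id].klass == "artifact"
])
print(f"artifact recovery against the simulation's ground truth: {hit:.1%}")
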