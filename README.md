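# mirdegrade

Degradation-bias analysis of miRNA microarray expression profiles.

## The problem

miRNA expression profiles measured on hybridization arrays are surprisingly
sensitive to RNA quality — not only because genuine miRNAs decay, but
because a degraded sample is full of labelled fragments of mRNAs and other
RNA species. With undirected 3′-labelling, any fragment that shares enough
sequence with a mature miRNA can occupy that miRNA's capture probe and
masquerade as miRNA signal. The result: profiles from low-integrity tissue
show *hundreds of apparent miRNA gains*, concentrated among miRNAs that were
added to miRBase in its most recent releases (largely NGS-predicted, never
validated by Northern blot). For biomarker work this is a serious bias.

`mirdegrade` packages the analysis needed to detect, quantify and label this
bias, for anyone doing miRNA array QC or re-evaluating miRNA annotations:

- **simulation** of the two experimental designs that isolate the effect: a
  tissue storage time course (liver/heart/brain × 4 °C/RT × 0–96 h, with
  tissue-specific RIN decay models — linear, plateau-then-linear, or
  hyperbolic) and a control experiment contrasting intact vs degraded RNA
  (± DNase) with small-RNA-depleted RNA fragmented in vitro by RNase.
  Every simulated miRNA carries a latent class (resilient / sensitive /
  artifact / DNA background) so recovery is measurable;
- **preprocessing**: robust multiplicative calibration + generalized-log
  (variance-stabilizing) transform, detection-based filtering, top-variance
  feature selection;
- **screens**: per-miRNA Pearson correlation with RIN and storage time
  (BH-adjusted, |r| > 0.5), Wilcoxon–Mann–Whitney differential expression
  between high- and low-integrity samples with a two-fold filter;
- **clustering**: Euclidean/complete-linkage hierarchical clustering with
  deterministic tie-breaking, fixed-k cuts, cluster-vs-miRBase-version
  summaries;
- **classification** of each miRNA from control-experiment evidence into
  `resilient`, `sensitive`, `likely_artifact`,
  `degradation_associated_unexplained`, `dna_background` or `unclassified`;
- **homology scanning**: contiguous ≥ 90%-of-length windows with at most one
  mismatch between mature miRNA sequences and a transcript FASTA — the
  mechanistic check for cross-hybridization.

## The core model

Degradation couples to signal through the degradation index
`D = (10 − RIN)/9 ∈ [0, 1]`; each simulated probe follows

```
log2 signal = baseline + effect · D + ε,   ε ~ N(0, σ²)
```

with `effect = 0` for resilient miRNAs, `effect < 0` for degradation-
sensitive miRNAs and `effect > 0` for cross-hybridization artifacts. The
classifier inverts this generative picture from the control design: a probe
whose signal rises in degraded tissue **and** persists in small-RNA-depleted,
RNase-fragmented RNA cannot be reporting a genuine miRNA; a probe elevated
only when DNase digestion is omitted is DNA background; a probe losing ≥
2-fold signal in degraded tissue is degradation-sensitive.

## Worked example

```python
from collections import Counter
from mirdegrade import (SimConfig, simulate_study, detection_filter,
                        glog_normalize, build_evidence, classify)

study = simulate_study(SimConfig(seed=1))          # 48 + 24 arrays, 900 miRNAs
control = glog_normalize(detection_filter(study.control, 5))
labels = classify(build_evidence(control, study.control_meta),
                  fold_change=2.0, annotation=study.annotation)
print(Counter(c.label for c in labels))
```

prints

```
Counter({'likely_artifact': 298, 'resilient': 289, 'sensitive': 194,
         'dna_background': 94})
```

— of 875 miRNAs surviving the detection filter, 298 are flagged as likely
cross-hybridization artifacts (the simulation planted 300; recovery is
99.3%), 194 as degradation-sensitive and 94 as DNA background. The version
bias is what makes the flag practically useful: the median miRBase
first-annotation release is 18 for `likely_artifact` versus 6 for
`sensitive` miRNAs. The `examples/` directory walks through each capability
(`python examples/01_simulate_and_screen.py`, …), and the `mirdegrade` CLI
(`simulate` / `analyze` / `report` / `homology`) runs the same pipeline on
files.

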