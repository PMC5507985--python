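"""High- vs low-integrity differential expression in liver samples.

Splits the liver time-course arrays at RIN 6 (low integrity = RIN <= 6) and
tests each miRNA with the Wilcoxon-Mann-Whitney test plus a two-fold
group-median filter.  In degrading tissue most significant changes are
*increases* — fragments of other RNAs hybridizing to miRNA probes — while a
smaller set of genuine miRNAs loses signal.
"""

from mirdegrade import (
    SimConfig,
    detection_filter,
    differential_expression,
    glog_normalize,
    simulate_study,
)

study = simulate_study(SimConfig(seed=1))
matrix = glog_normalize(detection_filter(study.timecourse, 5))
liver = [m.sample_id for m in study.timecourse_meta if m.tissue == "liver"]

results = differential_expression(
    matrix.select_samples(liver), study.timecourse_meta,
    rin_cutoff=6.0, fold_change=2.0, alpha=0.05,
)
sig = [r for r in results if r.significant]
up = sum(r.log2fc > 0 for r in sig)
down = sum(r.log2fc < 0 for r in sig)
print(f"{len(sig)} miRNAs pass WMW p < 0.05 with a >= 2-fold median shift")
print(f"  {up} elevated in low-integrity samples (degradation artifacts)")
print(f"  {down} reduced in low-integrity samples (degradation-sensitive)")

strongest = max(sig, key=lambda r: r.log2fc)
print(f"largest gain: {strongest.mirna_id} "
      f"(log2 FC {strongest.log2fc:+.2f}, p = {strongest.p:.2e})")
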