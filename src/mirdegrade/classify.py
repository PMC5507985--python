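"""Integrate control-experiment evidence into per-miRNA degradation labels.

Each miRNA receives an :class:`EvidenceVector` summarising the control
design: how its signal shifts between degraded and intact small-RNA-containing
samples (``delta_degraded``), whether it is detected in small-RNA-depleted,
RNase-fragmented RNA (the cross-hybridization control), and how much signal
the omission of DNase digestion adds in degraded samples (``dnase_delta``).
The classifier is a fixed-order rule list — a pure, reproducible function of
evidence and thresholds — rather than a clustering, so the same miRNA always
receives the same label:

1. DNase omission raises the degraded signal ≥ t           → ``dna_background``
2. up in degraded tissue AND seen in depleted+RNase RNA    → ``likely_artifact``
3. up in degraded tissue, absent from depleted+RNase RNA   → ``degradation_associated_unexplained``
4. down in degraded tissue                                 → ``sensitive``
5. detected in intact tissue, |shift| < t                  → ``resilient``
6. otherwise                                               → ``unclassified``

with t = log2(fold_change).  DNA background is tested before the artifact
rule because DNA-driven probes also rise in degraded tissue; the DNase
contrast is what discriminates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    ExpressionMatrix,
    MiRBaseAnnotation,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "EvidenceVector",
    "MiRNAClassification",
    "build_evidence",
    "classify",
    "version_bias_summary",
    "LABELS",
]

LABELS = (
    "resilient",
    "sensitive",
    "likely_artifact",
    "degradation_associated_unexplained",
    "dna_background",
    "unclassified",
)


@dataclass(frozen=True)
class EvidenceVector:
    """Group contrasts for one miRNA from the control experiment.

    Deltas are medians of normalized (log-like) values; a delta is ``None``
    (absent) when neither group contributing to it has a single detected
    replicate, so background-only contrasts never drive a call.
    """

    mirna_id: str
    delta_degraded: Optional[float]  # degraded − intact, with-small-RNA arms
    detected_depleted_degraded: bool  # ≥1 depleted RNase-treated replicate
    detected_depleted_intact: bool  # ≥1 depleted 0 U replicate
    dnase_delta: Optional[float]  # degraded −DNase minus degraded +DNase
    detected_intact: bool  # ≥1 intact with-small-RNA replicate


@dataclass(frozen=True)
class MiRNAClassification:
    mirna_id: str
    label: str
    evidence: EvidenceVector
    first_version: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")


def _median(X: np.ndarray) -> float:
    return float(np.median(X))


def build_evidence(
    control: ExpressionMatrix,
    control_meta: Sequence[SampleMeta],
    timecourse: Optional[ExpressionMatrix] = None,
    detection_rule: str = "any",
) -> list[EvidenceVector]:
    """Summarise the control experiment per miRNA.

    Group medians are computed over all values in a group (undetected probes
    still carry a background intensity); a delta is marked absent when no
    replicate in either contributing group is detected.  When a *timecourse*
    matrix is given, evidence is restricted to miRNAs present in both
    matrices; miRNAs absent from the control matrix simply yield no evidence
    vector (incomplete, not an error).

    ``detection_rule`` — ``"any"`` (default) requires ≥ 1 detected replicate
    for the depleted-detection booleans, ``"majority"`` requires more than
    half.
    """
    if control.state != "normalized":
        raise ValidationError("build_evidence expects a normalized control matrix")
    if detection_rule not in ("any", "majority"):
        raise ValidationError("detection_rule must be 'any' or 'majority'")
    by_id = {m.sample_id: m for m in control_meta}
    for s in control.sample_ids:
        if s not in by_id:
            raise ValidationError(f"sample {s!r} missing from control metadata")

    def _sel(pred) -> list[str]:
        return [s for s in control.sample_ids if pred(by_id[s])]

    ws = lambda m: m.arm == "control" and m.rna_fraction == "with_small_rna"
    intact_ws = _sel(lambda m: ws(m) and m.time_h == 0)
    degraded_ws = _sel(lambda m: ws(m) and m.time_h > 0)
    degraded_nodnase = _sel(lambda m: ws(m) and m.time_h > 0 and m.dnase == "no")
    degraded_dnase = _sel(lambda m: ws(m) and m.time_h > 0 and m.dnase == "yes")
    depleted_rnase = _sel(
        lambda m: m.rna_fraction == "depleted" and (m.rnase_units or 0) > 0
    )
    depleted_intact = _sel(
        lambda m: m.rna_fraction == "depleted" and (m.rnase_units or 0) == 0
    )

    ids = control.mirna_ids
    if timecourse is not None:
        universe = set(timecourse.mirna_ids)
        ids = [i for i in ids if i in universe]

    V = control.values
    D = control.detected

    def _hit(row_det: pd.Series, cols: list[str]) -> bool:
        if not cols:
            return False
        hits = int(row_det[cols].sum())
        return hits > len(cols) / 2 if detection_rule == "majority" else hits >= 1

    out: list[EvidenceVector] = []
    for mid in ids:
        vals = V.loc[mid]
        det = D.loc[mid]
        det_intact = _hit(det, intact_ws)
        det_degraded = _hit(det, degraded_ws)

        if (det_intact or det_degraded) and intact_ws and degraded_ws:
            delta = _median(vals[degraded_ws].to_numpy()) - _median(
                vals[intact_ws].to_numpy()
            )
        else:
            delta = None

        if degraded_nodnase and degraded_dnase and (
            _hit(det, degraded_nodnase) or _hit(det, degraded_dnase)
        ):
            dnase_delta = _median(vals[degraded_nodnase].to_numpy()) - _median(
                vals[degraded_dnase].to_numpy()
            )
        else:
            dnase_delta = None

        out.append(
            EvidenceVector(
                mirna_id=mid,
                delta_degraded=delta,
                detected_depleted_degraded=_hit(det, depleted_rnase),
                detected_depleted_intact=_hit(det, depleted_intact),
                dnase_delta=dnase_delta,
                detected_intact=det_intact,
            )
        )
    return out


def classify(
    evidence: Sequence[EvidenceVector],
    fold_change: float = 2.0,
    annotation: Optional[Sequence[MiRBaseAnnotation]] = None,
) -> list[MiRNAClassification]:
    """Assign one label per miRNA by first-matching rule (see module docs).

    Deterministic and order-independent; incomplete evidence falls through to
    ``unclassified``.  *annotation*, when given, fills ``first_version``.
    """
    if fold_change < 1:
        raise ValidationError("fold_change must be >= 1")
    t = math.log2(fold_change)
    ann = {a.mirna_id: a.first_version for a in (annotation or [])}

    out = []
    for ev in evidence:
        label = _apply_rules(ev, t)
        out.append(
            MiRNAClassification(ev.mirna_id, label, ev, ann.get(ev.mirna_id))
        )
    return out


def _apply_rules(ev: EvidenceVector, t: float) -> str:
    if ev.dnase_delta is not None and ev.dnase_delta >= t:
        return "dna_background"
    if ev.delta_degraded is not None and ev.delta_degraded >= t:
        if ev.detected_depleted_degraded:
            return "likely_artifact"
        return "degradation_associated_unexplained"
    if ev.delta_degraded is not None and ev.delta_degraded <= -t:
        return "sensitive"
    if (
        ev.detected_intact
        and ev.delta_degraded is not None
        and abs(ev.delta_degraded) < t
    ):
        return "resilient"
    return "unclassified"


def version_bias_summary(
    classifications: Sequence[MiRNAClassification],
    era_bins: Sequence[tuple[int, int]] = ((1, 3), (4, 9), (10, 15), (16, 21)),
) -> pd.DataFrame:
    """Contingency table of label × miRBase era, with a Kruskal-Wallis test
    of first_version across labels in ``df.attrs`` (NaN when undefined)."""
    from .stats import era_label  # local import to avoid cycle

    labels_present = sorted(
        {c.label for c in classifications if c.first_version is not None},
        key=LABELS.index,
    )
    era_names = [f"{lo}-{hi}" for lo, hi in era_bins]
    df = pd.DataFrame(0, index=labels_present, columns=era_names, dtype=int)
    versions_by_label: dict[str, list[int]] = {l: [] for l in labels_present}
    for c in classifications:
        if c.first_version is None:
            continue
        df.loc[c.label, era_label(era_bins, c.first_version)] += 1
        versions_by_label[c.label].append(c.first_version)

    groups = [v for v in versions_by_label.values() if v]
    if len(groups) >= 2 and len({x for g in groups for x in g}) > 1:
        h, p = sps.kruskal(*groups)
        df.attrs["kruskal_h"], df.attrs["kruskal_p"] = float(h), float(p)
    else:
        df.attrs["kruskal_h"] = df.attrs["kruskal_p"] = float("nan")
    df.attrs["median_version_by_label"] = {
        l: float(np.median(v)) for l, v in versions_by_label.items() if v
    }
    return df
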