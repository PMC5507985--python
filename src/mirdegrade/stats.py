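"""Per-miRNA screens: correlation with RIN / storage time, high- vs
low-integrity differential expression, and detected-count summaries by
miRBase annotation era.

All screens operate on a normalized :class:`~mirdegrade.model.ExpressionMatrix`
and return one record per miRNA.  Multiple testing is controlled with the
Benjamini-Hochberg step-up within each screen.  A correlation "call" is made
only when both the magnitude threshold (|r| > r*) and the adjusted
significance threshold (p_adj < alpha) are met; differential expression
follows the two-fold-and-raw-p convention (|log2 FC| ≥ log2(fold_change) and
WMW p < alpha), with the BH-adjusted p reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import (
    AnalysisConfig,
    ExpressionMatrix,
    MiRBaseAnnotation,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "pearson",
    "wmw_test",
    "bh_adjust",
    "CorrelationResult",
    "correlation_screen",
    "DEResult",
    "differential_expression",
    "detected_counts_by_era",
    "era_label",
]


# ---------------------------------------------------------------------------
# kernels


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value.

    Requires equal lengths ≥ 3 and two non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson expects two equal-length vectors")
    if len(x) < 3:
        raise ValidationError("pearson needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


#: total sample size at or below which the WMW p-value is computed by exact
#: enumeration (tie-free data); above it, or with ties, the midrank normal
#: approximation with tie correction is used.
WMW_EXACT_MAX_N = 12


def wmw_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Returns (U statistic of group *a*, two-sided p).  Exact for tie-free data
    with ≤ 12 total observations; otherwise midrank + normal approximation
    with tie correction (no continuity correction, so swapping groups leaves
    p unchanged exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("wmw_test requires two non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= WMW_EXACT_MAX_N) and not has_ties
    if not exact and np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2.0), 1.0  # full ties: no separation
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# correlation screen


@dataclass(frozen=True)
class CorrelationResult:
    mirna_id: str
    covariate: str  # rin | time_4C | time_RT
    r: float
    p: float
    p_adj: float
    call: str  # positive | negative | ns


def _covariate_samples(
    meta: Sequence[SampleMeta], covariate: str
) -> tuple[list[str], np.ndarray]:
    if covariate == "rin":
        sel = [m for m in meta if m.arm == "timecourse"]
        vals = [m.rin for m in sel]
    elif covariate in ("time_4C", "time_RT"):
        temp = covariate.split("_")[1]
        sel = [m for m in meta if m.arm == "timecourse" and m.temperature == temp]
        vals = [m.time_h for m in sel]
    else:
        raise ValidationError(f"unknown covariate {covariate!r}")
    return [m.sample_id for m in sel], np.asarray(vals, dtype=float)


def correlation_screen(
    m: ExpressionMatrix,
    meta: Sequence[SampleMeta],
    covariate: str,
    cfg: Optional[AnalysisConfig] = None,
) -> list[CorrelationResult]:
    """Correlate each miRNA's expression with RIN or storage time.

    ``covariate="rin"`` uses every time-course sample; the storage-time
    screens restrict to one temperature arm.  A miRNA is called ``positive``
    when r > r* with BH-adjusted p < alpha, ``negative`` when r < −r* with
    adjusted p < alpha, else ``ns``.  Constant expression rows get r = NaN
    and are never called.
    """
    cfg = cfg or AnalysisConfig()
    if m.state != "normalized":
        raise ValidationError("correlation_screen expects a normalized matrix")
    all_ids, all_cov = _covariate_samples(meta, covariate)
    keep = [i for i, s in enumerate(all_ids) if s in m.values.columns]
    sample_ids = [all_ids[i] for i in keep]
    cov = all_cov[keep]
    if len(sample_ids) < 3:
        raise ValidationError(
            f"fewer than 3 usable samples for covariate {covariate!r}"
        )
    X = m.values[sample_ids].to_numpy()

    rs = np.full(m.n_mirnas, np.nan)
    ps = np.full(m.n_mirnas, np.nan)
    for i in range(m.n_mirnas):
        if np.ptp(X[i]) == 0:
            continue
        rs[i], ps[i] = pearson(X[i], cov)
    finite = np.isfinite(ps)
    padj = np.full(m.n_mirnas, np.nan)
    if finite.any():
        padj[finite] = bh_adjust(ps[finite])

    out = []
    for i, mid in enumerate(m.mirna_ids):
        if not finite[i]:
            call = "ns"
        elif rs[i] > cfg.corr_threshold and padj[i] < cfg.alpha:
            call = "positive"
        elif rs[i] < -cfg.corr_threshold and padj[i] < cfg.alpha:
            call = "negative"
        else:
            call = "ns"
        out.append(
            CorrelationResult(mid, covariate, float(rs[i]), float(ps[i]),
                              float(padj[i]), call)
        )
    return out


# ---------------------------------------------------------------------------
# differential expression: high- vs low-integrity samples


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    median_low: float
    median_high: float
    log2fc: float  # low-integrity minus high-integrity
    p: float
    p_adj: float
    significant: bool


def differential_expression(
    m: ExpressionMatrix,
    meta: Sequence[SampleMeta],
    rin_cutoff: float = 6.0,
    fold_change: float = 2.0,
    alpha: float = 0.05,
    center: str = "median",
) -> list[DEResult]:
    """Compare low-integrity (RIN ≤ cutoff) against high-integrity samples.

    log2 FC is the low-group center minus the high-group center (``median``
    by default, ``mean`` optionally); significance requires
    |log2 FC| ≥ log2(fold_change) and raw WMW p < alpha.  BH-adjusted
    p-values are reported alongside.
    """
    if m.state != "normalized":
        raise ValidationError("differential_expression expects a normalized matrix")
    if center not in ("median", "mean"):
        raise ValidationError("center must be median or mean")
    by_id = {mm.sample_id: mm for mm in meta}
    low = [s for s in m.sample_ids if by_id[s].rin <= rin_cutoff]
    high = [s for s in m.sample_ids if by_id[s].rin > rin_cutoff]
    if len(low) < 2:
        raise ValidationError(
            f"low-integrity group has {len(low)} sample(s); need >= 2"
        )
    if len(high) < 2:
        raise ValidationError(
            f"high-integrity group has {len(high)} sample(s); need >= 2"
        )
    Xl = m.values[low].to_numpy()
    Xh = m.values[high].to_numpy()
    centerf = np.median if center == "median" else np.mean
    t = np.log2(fold_change)

    ps = np.empty(m.n_mirnas)
    fcs = np.empty(m.n_mirnas)
    ml = np.empty(m.n_mirnas)
    mh = np.empty(m.n_mirnas)
    for i in range(m.n_mirnas):
        _, ps[i] = wmw_test(Xl[i], Xh[i])
        ml[i] = centerf(Xl[i])
        mh[i] = centerf(Xh[i])
        fcs[i] = ml[i] - mh[i]
    padj = bh_adjust(ps)

    return [
        DEResult(
            mid,
            float(ml[i]),
            float(mh[i]),
            float(fcs[i]),
            float(ps[i]),
            float(padj[i]),
            bool(abs(fcs[i]) >= t and ps[i] < alpha),
        )
        for i, mid in enumerate(m.mirna_ids)
    ]


# ---------------------------------------------------------------------------
# detected counts by miRBase annotation era


def era_label(bins: Sequence[tuple[int, int]], version: int) -> str:
    for lo, hi in bins:
        if lo <= version <= hi:
            return f"{lo}-{hi}"
    raise ValidationError(f"first_version {version} not covered by era bins")


def detected_counts_by_era(
    m: ExpressionMatrix,
    annotation: Sequence[MiRBaseAnnotation],
    era_bins: Sequence[tuple[int, int]] = ((1, 3), (4, 9), (10, 15), (16, 21)),
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Count detected miRNAs per annotation era (rows) per sample (columns).

    Column sums equal each sample's total detected count.  Raises if any
    miRNA in the matrix lacks an annotation.
    """
    ann = {a.mirna_id: a for a in annotation}
    missing = [mid for mid in m.mirna_ids if mid not in ann]
    if missing:
        raise ValidationError(
            f"unannotated miRNA(s): {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    cols = list(sample_ids) if sample_ids is not None else m.sample_ids
    labels = [f"{lo}-{hi}" for lo, hi in era_bins]
    eras = pd.Series(
        [era_label(era_bins, ann[mid].first_version) for mid in m.mirna_ids],
        index=m.values.index,
    )
    det = m.detected[cols]
    out = pd.DataFrame(0, index=labels, columns=cols, dtype=int)
    for lab in labels:
        out.loc[lab] = det.loc[eras == lab].sum(axis=0).astype(int)
    return out
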