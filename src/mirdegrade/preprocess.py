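"""Normalization, detection filtering and variance-based feature selection.

Raw background-corrected intensities are put on a common scale by a robust
per-sample multiplicative calibration (each sample is rescaled so its MAD
matches the median per-sample MAD) followed by a generalized-log transform

    g(x) = log2((x + sqrt(x^2 + c^2)) / 2),

which behaves like log2(x) at high intensity and linearly near zero, so the
variance of low-intensity probes is not inflated the way a plain log
transform inflates it.  The offset ``c`` is estimated from the spread of the
low-intensity tail of the calibrated matrix (scaled MAD of values at or
below the 10th percentile) unless given explicitly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, ValidationError

__all__ = [
    "glog",
    "glog_normalize",
    "detection_filter",
    "top_variance",
    "detection_fallback",
]


def glog(x, c: float):
    """Generalized log2: log2((x + sqrt(x² + c²)) / 2); equals log2(x) at c=0."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def _robust_scale(col: np.ndarray) -> float:
    mad = np.median(np.abs(col - np.median(col)))
    if mad > 0:
        return 1.4826 * mad
    return float(np.std(col))


def glog_normalize(
    m: ExpressionMatrix,
    c: Optional[float] = None,
    calibrate: bool = True,
) -> ExpressionMatrix:
    """Calibrate samples and apply the generalized-log transform.

    Calibration is multiplicative: each sample is scaled by the ratio of the
    reference robust scale (the median of per-sample MADs) to its own MAD,
    which corrects between-array brightness differences without the additive
    offsets that would distort low-intensity probes.  The map is strictly
    increasing per sample, so within-sample rank order is preserved.
    Detection flags pass through unchanged and the result is marked
    ``normalized``.

    Raises a :class:`ValidationError` naming the sample if any sample has
    zero variance (no scale to calibrate against).
    """
    if m.state != "raw":
        raise ValidationError("glog_normalize expects a raw matrix")
    X = m.values.to_numpy(dtype=float, copy=True)

    for j, sid in enumerate(m.sample_ids):
        if np.std(X[:, j]) == 0:
            raise ValidationError(f"sample {sid!r} has zero variance")

    if calibrate:
        scales = np.array([_robust_scale(X[:, j]) for j in range(X.shape[1])])
        ref_scale = float(np.median(scales))
        X = X * (ref_scale / scales)[None, :]

    if c is None:
        # c approximates the additive-noise scale; estimate it from the
        # spread of the low-intensity tail (MAD, falling back to the plain
        # SD when the tail is degenerate, e.g. floored values).
        low = X[X <= np.percentile(X, 25.0)]
        mad = np.median(np.abs(low - np.median(low)))
        c = float(1.4826 * mad) if mad > 0 else float(np.std(low))

    out = pd.DataFrame(glog(X, c), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, m.detected.copy(), "normalized")


def detection_filter(m: ExpressionMatrix, min_samples: int = 5) -> ExpressionMatrix:
    """Drop miRNAs detected in fewer than *min_samples* samples.

    Keeps exactly the rows with detected-count ≥ min_samples, preserving row
    order; the sample set is unchanged.  Idempotent.
    """
    if min_samples < 0:
        raise ValidationError("min_samples must be >= 0")
    keep = m.detected.sum(axis=1) >= min_samples
    return ExpressionMatrix(
        m.values.loc[keep], m.detected.loc[keep], m.state
    )


def top_variance(m: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Select the *n* miRNAs with largest row variance (ddof=1).

    Ties are broken by miRNA id (lexicographic) so the selection is
    reproducible; retained rows keep their original matrix order.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if m.state != "normalized":
        raise ValidationError("top_variance expects a normalized matrix")
    if n > m.n_mirnas:
        raise ValidationError(
            f"n={n} exceeds the number of miRNAs ({m.n_mirnas})"
        )
    var = m.values.var(axis=1, ddof=1)
    order = sorted(m.mirna_ids, key=lambda mid: (-var[mid], mid))
    chosen = set(order[:n])
    keep = [mid for mid in m.mirna_ids if mid in chosen]
    return m.select_mirnas(keep)


def detection_fallback(m: ExpressionMatrix, quantile: float = 25.0) -> ExpressionMatrix:
    """Derive detection flags when no flag table accompanies a matrix.

    A cell is flagged detected when its value exceeds the *quantile*-th
    percentile of the whole matrix — a crude stand-in for feature-extraction
    background calls, meant only to keep plain matrices runnable.
    """
    thr = float(np.percentile(m.values.to_numpy(), quantile))
    det = m.values > thr
    return ExpressionMatrix(m.values.copy(), det, m.state)
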