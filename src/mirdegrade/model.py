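"""Domain types and validation shared by all pipeline stages.

The central container is :class:`ExpressionMatrix`, a miRNA × sample intensity
matrix with a boolean detection-flag matrix of identical shape and an explicit
processing-state marker (``raw`` vs ``normalized``).  Sample annotations
(:class:`SampleMeta`) describe the two experimental designs the pipeline
understands: a tissue time-course of post-mortem storage (three tissues, two
temperatures, eight time points) and a control experiment contrasting intact
and degraded RNA, with and without DNase digestion, plus small-RNA-depleted
RNA fragmented in vitro with RNase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "SampleMeta",
    "MiRBaseAnnotation",
    "AnalysisConfig",
    "TISSUES",
    "TEMPERATURES",
    "TIME_POINTS_H",
    "RNASE_DOSES_U",
    "DEFAULT_ERA_BINS",
    "sample_meta_to_frame",
    "frame_to_sample_meta",
    "annotation_to_frame",
    "frame_to_annotation",
]


class ValidationError(ValueError):
    """A record or matrix violates a typed invariant."""


class ParseError(ValueError):
    """A file could not be interpreted; message carries coordinates."""


TISSUES = ("liver", "heart", "brain")
TEMPERATURES = ("4C", "RT")
TIME_POINTS_H = (0, 1, 3, 6, 14, 24, 48, 96)
#: RNase doses (units) applied to small-RNA-depleted RNA: none / partial / full
#: degradation.
RNASE_DOSES_U = (0.0, 0.027, 0.67)
#: miRBase release eras used for version-bias summaries.
DEFAULT_ERA_BINS = ((1, 3), (4, 9), (10, 15), (16, 21))

_STATES = ("raw", "normalized")
_SEQ_ALPHABET = set("ACGT")


@dataclass
class ExpressionMatrix:
    """miRNA × sample intensities plus per-cell detection flags.

    Parameters
    ----------
    values
        DataFrame indexed by miRNA id with sample-id columns.  Non-negative
        intensities when ``state == "raw"``; real numbers on a log-like scale
        when ``state == "normalized"``.
    detected
        Boolean DataFrame of identical shape (probe signal above background).
    state
        ``"raw"`` or ``"normalized"``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.detected = self.detected.astype(bool)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.state not in _STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if self.values.shape != self.detected.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != detected shape "
                f"{self.detected.shape}"
            )
        for name, idx in (
            ("miRNA", self.values.index),
            ("sample", self.values.columns),
        ):
            dup = idx[idx.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {name} id: {dup[0]!r}")
        if not (
            self.values.index.equals(self.detected.index)
            and self.values.columns.equals(self.detected.columns)
        ):
            raise ValidationError("values and detected are not aligned")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise ValidationError(
                f"non-finite value at miRNA {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.state == "raw" and (self.values.to_numpy() < 0).any():
            bad = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative raw intensity at miRNA "
                f"{self.values.index[bad[0]]!r}, sample "
                f"{self.values.columns[bad[1]]!r}"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_mirnas(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(ids)], self.detected.loc[list(ids)], self.state
        )

    def select_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(ids)], self.detected[list(ids)], self.state
        )

    def with_state(self, state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.detected.copy(), state)

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        if self.state != other.state:
            return False
        if self.mirna_ids != other.mirna_ids or self.sample_ids != other.sample_ids:
            return False
        if not (self.detected.to_numpy() == other.detected.to_numpy()).all():
            return False
        return np.allclose(
            self.values.to_numpy(), other.values.to_numpy(), atol=atol, rtol=0.0
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation covering both experimental arms.

    ``arm == "timecourse"`` samples come from the tissue storage series
    (small-RNA-containing total RNA, no in-vitro RNase); ``arm == "control"``
    samples come from the intact/degraded ± DNase design, where
    ``rna_fraction == "depleted"`` marks small-RNA-depleted RNA that was
    treated with an RNase dose (``rnase_units``, 0 / 0.027 / 0.67 U).
    """

    sample_id: str
    tissue: str
    temperature: str
    time_h: int
    rin: float
    replicate: int = 1
    arm: str = "timecourse"
    rna_fraction: str = "with_small_rna"
    dnase: str = "na"
    rnase_units: Optional[float] = None  # None encodes "na"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"{self.sample_id}: unknown tissue {self.tissue!r}"
            )
        if self.temperature not in TEMPERATURES:
            raise ValidationError(
                f"{self.sample_id}: unknown temperature {self.temperature!r}"
            )
        if self.time_h not in TIME_POINTS_H:
            raise ValidationError(
                f"{self.sample_id}: time_h {self.time_h!r} not one of "
                f"{TIME_POINTS_H}"
            )
        if not (1.0 <= float(self.rin) <= 10.0):
            raise ValidationError(
                f"{self.sample_id}: rin {self.rin} outside [1, 10]"
            )
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")
        if self.arm not in ("timecourse", "control"):
            raise ValidationError(f"{self.sample_id}: unknown arm {self.arm!r}")
        if self.rna_fraction not in ("with_small_rna", "depleted"):
            raise ValidationError(
                f"{self.sample_id}: unknown rna_fraction {self.rna_fraction!r}"
            )
        if self.dnase not in ("yes", "no", "na"):
            raise ValidationError(
                f"{self.sample_id}: dnase must be yes/no/na"
            )
        if self.arm == "timecourse":
            if self.rna_fraction != "with_small_rna":
                raise ValidationError(
                    f"{self.sample_id}: timecourse samples carry small RNA"
                )
            if self.rnase_units is not None:
                raise ValidationError(
                    f"{self.sample_id}: timecourse samples have rnase_units=na"
                )
        if self.rna_fraction == "depleted":
            if self.rnase_units is None:
                raise ValidationError(
                    f"{self.sample_id}: depleted samples need an RNase dose"
                )
        if self.rnase_units is not None and not any(
            math.isclose(self.rnase_units, u) for u in RNASE_DOSES_U
        ):
            raise ValidationError(
                f"{self.sample_id}: rnase_units {self.rnase_units} not one of "
                f"{RNASE_DOSES_U}"
            )


@dataclass(frozen=True)
class MiRBaseAnnotation:
    """Mature miRNA id, sequence (normalized to DNA alphabet) and the miRBase
    release (1–21) in which it was first annotated."""

    mirna_id: str
    mature_sequence: str
    first_version: int

    def __post_init__(self) -> None:
        seq = self.mature_sequence.upper().replace("U", "T")
        object.__setattr__(self, "mature_sequence", seq)
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.mirna_id}: sequence has invalid characters {sorted(bad)}"
            )
        if not (16 <= len(seq) <= 30):
            raise ValidationError(
                f"{self.mirna_id}: sequence length {len(seq)} outside [16, 30]"
            )
        if not (1 <= int(self.first_version) <= 21):
            raise ValidationError(
                f"{self.mirna_id}: first_version {self.first_version} outside "
                f"[1, 21]"
            )


@dataclass
class AnalysisConfig:
    """Thresholds for every pipeline stage.

    Defaults mirror the analysis conventions the pipeline is built around:
    miRNAs detected in fewer than ``min_detect_samples`` samples are dropped;
    a correlation is called only when ``|r| > corr_threshold`` and the
    BH-adjusted p-value is below ``alpha``; the differential-expression
    contrast splits samples at ``rin_cutoff`` (low integrity = RIN ≤ cutoff)
    and requires a ``fold_change``-fold shift with raw WMW p < ``alpha``;
    sequence homology needs a contiguous overlap of ``homology_min_frac`` of
    the mature length with at most ``homology_max_mismatch`` mismatches.
    """

    min_detect_samples: int = 5
    corr_threshold: float = 0.5
    alpha: float = 0.05
    rin_cutoff: float = 6.0
    fold_change: float = 2.0
    n_clusters: int = 8
    top_variance_n: int = 50
    homology_min_frac: float = 0.9
    homology_max_mismatch: int = 1
    era_bins: tuple = DEFAULT_ERA_BINS
    fc_center: str = "median"  # median | mean
    detection_fallback_quantile: float = 25.0
    exclude_samples: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.homology_min_frac <= 1):
            raise ValidationError("homology_min_frac must be in (0, 1]")
        if self.fold_change < 1:
            raise ValidationError("fold_change must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.fc_center not in ("median", "mean"):
            raise ValidationError("fc_center must be median or mean")
        self.era_bins = tuple((int(a), int(b)) for a, b in self.era_bins)
        self.exclude_samples = tuple(self.exclude_samples)

    def to_dict(self) -> dict:
        return {
            "min_detect_samples": self.min_detect_samples,
            "corr_threshold": self.corr_threshold,
            "alpha": self.alpha,
            "rin_cutoff": self.rin_cutoff,
            "fold_change": self.fold_change,
            "n_clusters": self.n_clusters,
            "top_variance_n": self.top_variance_n,
            "homology_min_frac": self.homology_min_frac,
            "homology_max_mismatch": self.homology_max_mismatch,
            "era_bins": [list(b) for b in self.era_bins],
            "fc_center": self.fc_center,
            "detection_fallback_quantile": self.detection_fallback_quantile,
            "exclude_samples": list(self.exclude_samples),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# table <-> dataclass helpers (deterministic column order for writers)

_META_COLUMNS = [
    "sample_id",
    "tissue",
    "temperature",
    "time_h",
    "rin",
    "replicate",
    "arm",
    "rna_fraction",
    "dnase",
    "rnase_units",
]


def sample_meta_to_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    rows = []
    for m in meta:
        rows.append(
            {
                "sample_id": m.sample_id,
                "tissue": m.tissue,
                "temperature": m.temperature,
                "time_h": m.time_h,
                "rin": m.rin,
                "replicate": m.replicate,
                "arm": m.arm,
                "rna_fraction": m.rna_fraction,
                "dnase": m.dnase,
                "rnase_units": "na" if m.rnase_units is None else m.rnase_units,
            }
        )
    return pd.DataFrame(rows, columns=_META_COLUMNS)


def frame_to_sample_meta(df: pd.DataFrame) -> list[SampleMeta]:
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        rnase = row["rnase_units"]
        if isinstance(rnase, str):
            rnase = None if rnase.strip().lower() == "na" else float(rnase)
        elif pd.isna(rnase):
            rnase = None
        else:
            rnase = float(rnase)
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                tissue=str(row["tissue"]),
                temperature=str(row["temperature"]),
                time_h=int(row["time_h"]),
                rin=float(row["rin"]),
                replicate=int(row["replicate"]),
                arm=str(row["arm"]),
                rna_fraction=str(row["rna_fraction"]),
                dnase=str(row["dnase"]),
                rnase_units=rnase,
            )
        )
    return out


def annotation_to_frame(ann: Sequence[MiRBaseAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": a.mirna_id,
                "mature_sequence": a.mature_sequence,
                "first_version": a.first_version,
            }
            for a in ann
        ],
        columns=["mirna_id", "mature_sequence", "first_version"],
    )


def frame_to_annotation(df: pd.DataFrame) -> list[MiRBaseAnnotation]:
    missing = {"mirna_id", "mature_sequence", "first_version"} - set(df.columns)
    if missing:
        raise ParseError(f"annotation missing column(s): {sorted(missing)}")
    return [
        MiRBaseAnnotation(
            mirna_id=str(r["mirna_id"]),
            mature_sequence=str(r["mature_sequence"]),
            first_version=int(r["first_version"]),
        )
        for _, r in df.iterrows()
    ]


def meta_by_id(meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    d = {m.sample_id: m for m in meta}
    if len(d) != len(meta):
        seen: set[str] = set()
        for m in meta:
            if m.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {m.sample_id!r}")
            seen.add(m.sample_id)
    return d
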