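"""Synthetic degradation experiments with latent ground truth.

The generator emulates two microarray designs.  The *time course* stores
liver, heart and brain tissue at 4 °C and room temperature for
0/1/3/6/14/24/48/96 h (48 arrays); RNA integrity (RIN) decays according to a
tissue- and temperature-specific :class:`DecayModel` (linear, two-phase with
an initial plateau, or hyperbolic).  The *control experiment* contrasts
intact and 96 h-degraded liver RNA with and without DNase digestion, plus
small-RNA-depleted RNA fragmented in vitro with 0 / 0.027 / 0.67 U RNase
(8 conditions × 3 replicates = 24 arrays).

Each simulated miRNA carries a latent class (:class:`SimTruth`):

``resilient``
    signal independent of degradation;
``sensitive``
    signal falls as RNA degrades (the miRNA itself is destroyed);
``artifact``
    signal *rises* with degradation and persists in small-RNA-depleted,
    RNase-fragmented RNA — the cross-hybridization signature of labelled
    mRNA fragments binding a probe by sequence homology;
``dna_background``
    signal rises in degraded samples only when DNase digestion is omitted.

The per-miRNA log2 signal in the time course is
``baseline + effect · D + ε`` with degradation index ``D = (10 − RIN)/9``
and ε ~ Normal(0, noise_sd); raw intensities are ``2**signal``.  A probe is
flagged detected when its noise-free-scale log2 intensity exceeds the
detection threshold.  Artifact-class mature sequences are planted as exact
substrings of the emitted synthetic transcripts so the homology screen has a
recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    ExpressionMatrix,
    MiRBaseAnnotation,
    SampleMeta,
    TEMPERATURES,
    TIME_POINTS_H,
    TISSUES,
    ValidationError,
)

import pandas as pd

__all__ = [
    "DecayModel",
    "SimTruth",
    "SimConfig",
    "default_decay_models",
    "simulate_rin",
    "draw_truth",
    "simulate_timecourse",
    "simulate_control_experiment",
    "simulate_study",
    "SimulatedStudy",
]

CLASSES = ("resilient", "sensitive", "artifact", "dna_background")


@dataclass(frozen=True)
class DecayModel:
    """RIN decay over storage time for one tissue × temperature arm.

    shapes: ``linear`` RIN(t) = 10 − slope·t; ``two_phase`` holds RIN = 10
    for ``plateau_h`` hours then declines linearly; ``hyperbolic``
    RIN(t) = 1 + 9/(1 + t/τ).  Predictions are clamped to [1, 10].
    """

    tissue: str
    temperature: str
    shape: str
    params: dict
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "two_phase", "hyperbolic"):
            raise ValidationError(f"unknown decay shape {self.shape!r}")

    def predict(self, time_h: float) -> float:
        if time_h < 0:
            raise ValidationError("storage time must be >= 0")
        if self.shape == "linear":
            rin = 10.0 - self.params["slope"] * time_h
        elif self.shape == "two_phase":
            plateau = self.params["plateau_h"]
            rin = 10.0 - self.params["slope"] * max(0.0, time_h - plateau)
        else:  # hyperbolic
            tau = self.params["tau"]
            rin = 1.0 + 9.0 / (1.0 + time_h / tau)
        return float(np.clip(rin, 1.0, 10.0))


def default_decay_models(noise_sd: float = 0.3) -> dict[tuple, DecayModel]:
    """Decay models keyed by (tissue, temperature).

    Liver degrades fastest: hyperbolic at RT (RIN ≈ 4 after 6 h with τ = 3)
    and the steepest linear slope at 4 °C.  Heart at RT shows a 24 h plateau
    followed by linear decline; brain at RT declines linearly over the whole
    course.  Brain and heart at 4 °C degrade slowly (RIN > 7 even at 96 h).
    """
    spec = {
        ("liver", "RT"): ("hyperbolic", {"tau": 3.0}),
        ("liver", "4C"): ("linear", {"slope": 0.12}),
        ("heart", "RT"): ("two_phase", {"plateau_h": 24.0, "slope": 0.1}),
        ("heart", "4C"): ("linear", {"slope": 0.022}),
        ("brain", "RT"): ("linear", {"slope": 0.075}),
        ("brain", "4C"): ("linear", {"slope": 0.02}),
    }
    return {
        key: DecayModel(key[0], key[1], shape, params, noise_sd)
        for key, (shape, params) in spec.items()
    }


def simulate_rin(
    model: DecayModel, time_h: float, seed: Optional[int] = None
) -> float:
    """One noisy RIN draw; deterministic (the model prediction) at noise 0."""
    rin = model.predict(time_h)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        rin += rng.normal(0.0, model.noise_sd)
    return float(np.clip(rin, 1.0, 10.0))


@dataclass(frozen=True)
class SimTruth:
    """Latent ground truth for one simulated miRNA."""

    mirna_id: str
    klass: str
    baseline_log2: float
    effect_log2: float
    first_version: int

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValidationError(f"unknown class {self.klass!r}")
        if self.klass == "resilient" and self.effect_log2 != 0:
            raise ValidationError("resilient miRNAs have effect_log2 == 0")
        if self.klass == "sensitive" and self.effect_log2 >= 0:
            raise ValidationError("sensitive miRNAs have effect_log2 < 0")
        if self.klass in ("artifact", "dna_background") and self.effect_log2 <= 0:
            raise ValidationError(f"{self.klass} miRNAs have effect_log2 > 0")


@dataclass
class SimConfig:
    """Simulation parameters (log2 units throughout).

    Class sizes default to 300 resilient / 200 sensitive / 300 artifact /
    100 dna_background.  Effect sizes are drawn uniformly: sensitive
    U[−4, −1.5], artifact U[1.5, 4], dna_background U[1.5, 3].  Baselines:
    genuine miRNAs (resilient/sensitive) U[6, 12]; artifact and
    dna_background probes sit near background, U[3, 5], so they surface only
    in degraded material.  miRBase first-version mixtures encode the
    annotation-era bias: artifacts draw from releases 16–21 with probability
    0.85 (else uniform 1–15); genuine miRNAs draw from releases 1–9 with
    probability 0.8 (else uniform 10–21); dna_background draws from 16–21
    with probability 0.7.  Detection: log2 intensity > detect_threshold_log2.
    Depletion removes ``depletion_drop_log2`` from every class in
    small-RNA-depleted, RNase-free arms.
    """

    n_resilient: int = 300
    n_sensitive: int = 200
    n_artifact: int = 300
    n_dna_background: int = 100
    effect_sensitive: tuple = (-4.0, -1.5)
    effect_artifact: tuple = (1.5, 4.0)
    effect_dna_background: tuple = (1.5, 3.0)
    baseline_genuine: tuple = (6.0, 12.0)
    baseline_background: tuple = (3.0, 5.0)
    noise_sd_log2: float = 0.5
    detect_threshold_log2: float = 4.0
    depletion_drop_log2: float = 10.0
    p_artifact_recent: float = 0.85
    p_genuine_early: float = 0.8
    p_dna_recent: float = 0.7
    rin_noise_sd: float = 0.3
    n_transcripts: int = 30
    transcript_length: int = 500
    mirna_length_range: tuple = (19, 23)
    seed: int = 0

    def __post_init__(self) -> None:
        for n in self.class_counts().values():
            if n < 0:
                raise ValidationError("class counts must be >= 0")
        for p in (self.p_artifact_recent, self.p_genuine_early, self.p_dna_recent):
            if not (0 <= p <= 1):
                raise ValidationError("mixture probabilities must be in [0, 1]")
        if sum(self.class_counts().values()) == 0:
            raise ValidationError("at least one miRNA class must be non-empty")

    def class_counts(self) -> dict[str, int]:
        return {
            "resilient": self.n_resilient,
            "sensitive": self.n_sensitive,
            "artifact": self.n_artifact,
            "dna_background": self.n_dna_background,
        }

    def to_dict(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# ground truth, annotation and transcripts (one deterministic draw per seed)

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def draw_truth(
    sim: SimConfig,
) -> tuple[list[SimTruth], list[MiRBaseAnnotation], dict[str, str]]:
    """Draw the latent miRNA population and the synthetic transcriptome.

    Deterministic given ``sim.seed``; both experiment simulators call this, so
    a time course and a control experiment generated from the same config
    share miRNAs, classes and sequences.  Artifact mature sequences are
    copied from random transcript windows (they *are* mRNA fragments in the
    generative story); all other sequences are random.
    """
    ss = np.random.SeedSequence(sim.seed)
    rng = np.random.default_rng(ss.spawn(4)[0])

    transcripts = {
        f"tx{t + 1:04d}": _random_seq(rng, sim.transcript_length)
        for t in range(sim.n_transcripts)
    }
    tx_ids = list(transcripts)

    truth: list[SimTruth] = []
    annotation: list[MiRBaseAnnotation] = []
    counts = sim.class_counts()
    lo_len, hi_len = sim.mirna_length_range
    idx = 0
    for klass in CLASSES:
        for _ in range(counts[klass]):
            idx += 1
            mirna_id = f"sim-miR-{idx:04d}"
            if klass == "resilient":
                effect = 0.0
                baseline = rng.uniform(*sim.baseline_genuine)
            elif klass == "sensitive":
                effect = rng.uniform(*sim.effect_sensitive)
                baseline = rng.uniform(*sim.baseline_genuine)
            elif klass == "artifact":
                effect = rng.uniform(*sim.effect_artifact)
                baseline = rng.uniform(*sim.baseline_background)
            else:
                effect = rng.uniform(*sim.effect_dna_background)
                baseline = rng.uniform(*sim.baseline_background)

            version = _draw_version(rng, klass, sim)
            length = int(rng.integers(lo_len, hi_len + 1))
            if klass == "artifact":
                tx = transcripts[tx_ids[int(rng.integers(len(tx_ids)))]]
                start = int(rng.integers(0, len(tx) - length + 1))
                seq = tx[start : start + length]
            else:
                seq = _random_seq(rng, length)
            truth.append(SimTruth(mirna_id, klass, baseline, effect, version))
            annotation.append(MiRBaseAnnotation(mirna_id, seq, version))
    return truth, annotation, transcripts


def _draw_version(rng: np.random.Generator, klass: str, sim: SimConfig) -> int:
    if klass == "artifact":
        recent = rng.random() < sim.p_artifact_recent
        return int(rng.integers(16, 22) if recent else rng.integers(1, 16))
    if klass == "dna_background":
        recent = rng.random() < sim.p_dna_recent
        return int(rng.integers(16, 22) if recent else rng.integers(1, 16))
    early = rng.random() < sim.p_genuine_early
    return int(rng.integers(1, 10) if early else rng.integers(10, 22))


# ---------------------------------------------------------------------------
# time-course experiment (48 arrays)


def simulate_timecourse(
    sim: SimConfig,
    decay_models: Optional[dict[tuple, DecayModel]] = None,
) -> tuple[
    ExpressionMatrix, list[SampleMeta], list[MiRBaseAnnotation], list[SimTruth]
]:
    """Simulate the 3-tissue × 2-temperature × 8-time-point design.

    Per-cell log2 signal = baseline + effect·D + ε with D = (10 − RIN)/9;
    raw intensity = 2**signal.  Fully reproducible given ``sim.seed``.
    """
    if decay_models is None:
        decay_models = default_decay_models(sim.rin_noise_sd)
    for tissue in TISSUES:
        for temp in TEMPERATURES:
            if (tissue, temp) not in decay_models:
                raise ValidationError(f"no decay model for ({tissue}, {temp})")

    truth, annotation, _ = draw_truth(sim)
    ss = np.random.SeedSequence(sim.seed)
    rng = np.random.default_rng(ss.spawn(4)[1])

    meta: list[SampleMeta] = []
    for tissue in TISSUES:
        for temp in TEMPERATURES:
            model = decay_models[(tissue, temp)]
            for t in TIME_POINTS_H:
                rin = model.predict(t)
                if model.noise_sd > 0:
                    rin = float(
                        np.clip(rin + rng.normal(0.0, model.noise_sd), 1.0, 10.0)
                    )
                meta.append(
                    SampleMeta(
                        sample_id=f"tc_{tissue}_{temp}_{t:03d}h",
                        tissue=tissue,
                        temperature=temp,
                        time_h=t,
                        rin=round(rin, 2),
                        replicate=1,
                        arm="timecourse",
                        rna_fraction="with_small_rna",
                        dnase="no",
                        rnase_units=None,
                    )
                )

    d_index = np.array([(10.0 - m.rin) / 9.0 for m in meta])
    baseline = np.array([t.baseline_log2 for t in truth])
    effect = np.array([t.effect_log2 for t in truth])
    signal = baseline[:, None] + effect[:, None] * d_index[None, :]
    if sim.noise_sd_log2 > 0:
        signal = signal + rng.normal(0.0, sim.noise_sd_log2, size=signal.shape)
    detected = signal > sim.detect_threshold_log2
    values = pd.DataFrame(
        np.exp2(signal),
        index=[t.mirna_id for t in truth],
        columns=[m.sample_id for m in meta],
    )
    det = pd.DataFrame(detected, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, det, "raw"), meta, annotation, truth


# ---------------------------------------------------------------------------
# control experiment (8 conditions × 3 replicates = 24 arrays)

#: (tag, degraded, rna_fraction, dnase, rnase_units, typical RIN)
_CONTROL_CONDITIONS = [
    ("mirna_intact_dnase", False, "with_small_rna", "yes", None, 9.6),
    ("mirna_intact_nodnase", False, "with_small_rna", "no", None, 9.6),
    ("mirna_degraded_dnase", True, "with_small_rna", "yes", None, 2.5),
    ("mirna_degraded_nodnase", True, "with_small_rna", "no", None, 2.5),
    ("depleted_0u_dnase", False, "depleted", "yes", 0.0, 9.8),
    ("depleted_0u_nodnase", False, "depleted", "no", 0.0, 9.8),
    ("depleted_low_dnase", True, "depleted", "yes", 0.027, 5.0),
    ("depleted_high_dnase", True, "depleted", "yes", 0.67, 2.0),
]


def _control_signal(t: SimTruth, cond, sim: SimConfig) -> float:
    """Noise-free log2 signal of one miRNA class under one control condition."""
    _, degraded, fraction, dnase, rnase, _ = cond
    b, e = t.baseline_log2, t.effect_log2
    if fraction == "with_small_rna":
        if t.klass == "sensitive":
            return b + e if degraded else b
        if t.klass == "artifact":
            return b + e if degraded else b
        if t.klass == "dna_background":
            return b + e if (degraded and dnase == "no") else b
        return b  # resilient
    # depleted arms: small RNAs removed for every class; artifacts reappear
    # once RNase fragments the carrier RNA (half effect at the low dose).
    if t.klass == "artifact" and rnase and rnase > 0:
        return b + e * (0.5 if rnase < 0.1 else 1.0)
    return b - sim.depletion_drop_log2


def simulate_control_experiment(
    sim: SimConfig,
) -> tuple[ExpressionMatrix, list[SampleMeta], list[SimTruth]]:
    """Simulate the intact/degraded ± DNase and depleted+RNase design."""
    truth, _, _ = draw_truth(sim)
    ss = np.random.SeedSequence(sim.seed)
    rng = np.random.default_rng(ss.spawn(4)[2])

    meta: list[SampleMeta] = []
    cols = []
    for cond in _CONTROL_CONDITIONS:
        tag, degraded, fraction, dnase, rnase, rin0 = cond
        for rep in (1, 2, 3):
            rin = float(np.clip(rng.normal(rin0, sim.rin_noise_sd), 1.0, 10.0))
            meta.append(
                SampleMeta(
                    sample_id=f"ctl_{tag}_r{rep}",
                    tissue="liver",
                    temperature="RT",
                    time_h=96 if degraded and fraction == "with_small_rna" else 0,
                    rin=round(rin, 2),
                    replicate=rep,
                    arm="control",
                    rna_fraction=fraction,
                    dnase=dnase,
                    rnase_units=rnase,
                )
            )
            cols.append(cond)

    signal = np.empty((len(truth), len(meta)))
    for j, cond in enumerate(cols):
        for i, t in enumerate(truth):
            signal[i, j] = _control_signal(t, cond, sim)
    if sim.noise_sd_log2 > 0:
        signal = signal + rng.normal(0.0, sim.noise_sd_log2, size=signal.shape)
    detected = signal > sim.detect_threshold_log2
    values = pd.DataFrame(
        np.exp2(signal),
        index=[t.mirna_id for t in truth],
        columns=[m.sample_id for m in meta],
    )
    det = pd.DataFrame(detected, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, det, "raw"), meta, truth


@dataclass
class SimulatedStudy:
    """Both simulated experiments plus shared truth/annotation/transcripts."""

    timecourse: ExpressionMatrix
    timecourse_meta: list[SampleMeta]
    control: ExpressionMatrix
    control_meta: list[SampleMeta]
    annotation: list[MiRBaseAnnotation]
    truth: list[SimTruth]
    transcripts: dict[str, str] = field(default_factory=dict)

    def truth_by_id(self) -> dict[str, SimTruth]:
        return {t.mirna_id: t for t in self.truth}


def simulate_study(sim: SimConfig) -> SimulatedStudy:
    """Generate the full study (time course + control experiment)."""
    tc, tc_meta, annotation, truth = simulate_timecourse(sim)
    ctl, ctl_meta, _ = simulate_control_experiment(sim)
    _, _, transcripts = draw_truth(sim)
    return SimulatedStudy(tc, tc_meta, ctl, ctl_meta, annotation, truth, transcripts)
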