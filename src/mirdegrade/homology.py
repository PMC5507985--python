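"""Approximate-substring screen of mature miRNA sequences against transcripts.

A labelled mRNA fragment can occupy a microarray capture probe when it shares
the probe's (i.e. the miRNA's) sequence.  The screen therefore looks, on the
sense strand, for the longest contiguous block of the mature sequence that
matches a transcript window with at most ``max_mismatch`` substitutions (no
indels).  A miRNA is flagged homologous when that block covers at least
``min_frac`` of its length, i.e. window_length ≥ ceil(min_frac · L).
Coordinates are 0-based, half-open on the transcript.

The implementation walks alignment diagonals with cumulative mismatch counts
(vectorised over all window placements), which is exact and fast enough for
desk-scale transcript sets; reverse-complement scanning is available behind
a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .model import MiRBaseAnnotation, ValidationError

__all__ = [
    "HomologyHit",
    "best_window",
    "homology_screen",
    "group_homology_fraction",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HomologyHit:
    """Best qualifying match of one miRNA to one transcript."""

    mirna_id: str
    transcript_id: str
    window_start: int  # 0-based, half-open on the transcript
    window_length: int
    mismatches: int
    overlap_frac: float  # window_length / miRNA length
    strand: str = "+"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_scan(
    mi: np.ndarray, tx: np.ndarray, max_mismatch: int, lengths: Sequence[int]
) -> Optional[tuple[int, int, int, int]]:
    """Best window among the given candidate lengths (descending order).

    Returns (window_length, tx_start, mismatches, mi_start) of the first
    (longest) feasible length; within a length, ties prefer the smallest
    transcript start, then the fewest mismatches, then the smallest miRNA
    offset.  None when no candidate length is feasible.
    """
    L, T = len(mi), len(tx)
    # pad the transcript so every diagonal is index-safe; pad byte never matches
    pad = np.zeros(L, dtype=np.uint8)
    txp = np.concatenate([pad, tx, pad])
    diags = np.arange(-(L - 1), T)  # transcript offset of miRNA position 0
    idx = diags[:, None] + np.arange(L)[None, :] + L
    match = mi[None, :] == txp[idx]
    mism = (~match).astype(np.int32)
    C = np.concatenate(
        [np.zeros((len(diags), 1), dtype=np.int32), np.cumsum(mism, axis=1)],
        axis=1,
    )
    starts = np.arange(L)
    for w in lengths:
        if w < 1 or w > L:
            continue
        a = starts[: L - w + 1]  # miRNA window start
        counts = C[:, a + w] - C[:, a]  # (n_diag, n_starts)
        tx_start = diags[:, None] + a[None, :]
        valid = (tx_start >= 0) & (tx_start + w <= T)
        feas = valid & (counts <= max_mismatch)
        if not feas.any():
            continue
        di, ai = np.nonzero(feas)
        ts = tx_start[di, ai]
        ms = counts[di, ai]
        order = np.lexsort((a[ai], ms, ts))
        bi = order[0]
        return int(w), int(ts[bi]), int(ms[bi]), int(a[ai[bi]])
    return None


def best_window(
    mirna_seq: str, transcript_seq: str, max_mismatch: int = 1
) -> tuple[int, int, int]:
    """Longest contiguous miRNA block matching a transcript window.

    Returns (window_length, transcript_start, mismatches); the window is the
    longest sub-sequence of the miRNA whose Hamming distance to some
    transcript window is ≤ max_mismatch.  Ties prefer the leftmost transcript
    position, then the fewest mismatches.
    """
    mirna_seq = _norm(mirna_seq)
    transcript_seq = _norm(transcript_seq)
    if not mirna_seq or not transcript_seq:
        raise ValidationError("sequences must be non-empty")
    mi = _encode(mirna_seq)
    tx = _encode(transcript_seq)
    res = _window_scan(mi, tx, max_mismatch, range(len(mi), 0, -1))
    if res is None:  # only possible when max_mismatch < 0
        return 0, 0, 0
    w, ts, ms, _ = res
    return w, ts, ms


def homology_screen(
    annotation: Sequence[MiRBaseAnnotation],
    transcripts: Dict[str, str],
    min_frac: float = 0.9,
    max_mismatch: int = 1,
    scan_reverse_complement: bool = False,
) -> list[HomologyHit]:
    """Flag miRNAs whose sequence is near-contained in some transcript.

    Returns the best qualifying hit per flagged miRNA (window_length ≥
    ceil(min_frac · L) with ≤ max_mismatch substitutions); unflagged miRNAs
    yield no hit.  Matching is sense-strand by default.
    """
    if not transcripts:
        return []
    if not (0 < min_frac <= 1):
        raise ValidationError("min_frac must be in (0, 1]")
    tx_items = [( tid, _encode(_norm(seq))) for tid, seq in transcripts.items()]

    hits: list[HomologyHit] = []
    for a in annotation:
        L = len(a.mature_sequence)
        w_min = math.ceil(min_frac * L)
        candidates = []
        for strand, seq in (
            [("+", a.mature_sequence)]
            + ([("-", _revcomp(a.mature_sequence))] if scan_reverse_complement else [])
        ):
            mi = _encode(seq)
            for tid, tx in tx_items:
                res = _window_scan(mi, tx, max_mismatch, range(L, w_min - 1, -1))
                if res is not None:
                    w, ts, ms, _ = res
                    candidates.append((-w, ts, ms, tid, strand))
        if candidates:
            negw, ts, ms, tid, strand = min(candidates)
            w = -negw
            hits.append(
                HomologyHit(
                    mirna_id=a.mirna_id,
                    transcript_id=tid,
                    window_start=ts,
                    window_length=w,
                    mismatches=ms,
                    overlap_frac=w / L,
                    strand=strand,
                )
            )
    return hits


def group_homology_fraction(
    flags: Dict[str, bool], grouping: Dict[str, object]
) -> Dict[object, float]:
    """Fraction of homology-flagged miRNAs per group.

    Every grouped miRNA must carry a flag; groups are whatever labels the
    grouping maps to (cluster numbers, classification labels, truth classes).
    """
    missing = [i for i in grouping if i not in flags]
    if missing:
        raise ValidationError(f"no homology flag for {missing[:5]}")
    out: Dict[object, float] = {}
    totals: Dict[object, int] = {}
    hits: Dict[object, int] = {}
    for mid, group in grouping.items():
        totals[group] = totals.get(group, 0) + 1
        hits[group] = hits.get(group, 0) + int(bool(flags[mid]))
    for group in totals:
        out[group] = hits[group] / totals[group]
    return out
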