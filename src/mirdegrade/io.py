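"""Readers and writers for the tab-delimited tables the pipeline exchanges.

Conventions: UTF-8, tab-separated, "." decimal.  An expression matrix TSV has
miRNA ids in the first column and sample ids in the header row; an optional
leading comment line ``# state: raw|normalized`` records the processing state.
Detection flags travel in a companion file (same table shape, cells 0/1)
located by replacing the matrix suffix with ``.flags.tsv``; when absent all
cells are treated as detected (a percentile fallback lives in
:func:`mirdegrade.preprocess.detection_fallback`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ExpressionMatrix,
    MiRBaseAnnotation,
    ParseError,
    SampleMeta,
    ValidationError,
    annotation_to_frame,
    frame_to_annotation,
    frame_to_sample_meta,
    sample_meta_to_frame,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_mirbase_annotation",
    "write_mirbase_annotation",
    "read_transcripts",
    "write_transcripts",
    "flags_path_for",
]

PathLike = Union[str, Path]


def flags_path_for(path: PathLike) -> Path:
    """Companion detection-flag file for a matrix at *path*."""
    p = Path(path)
    return p.with_suffix(".flags.tsv") if p.suffix else Path(str(p) + ".flags.tsv")


def _read_table(path: Path) -> tuple[pd.DataFrame, Optional[str]]:
    """Read a matrix TSV, returning (string-typed frame, state comment)."""
    state = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "state:" in first:
                state = first.split("state:", 1)[1].strip()
            rest = fh.read()
        else:
            rest = first + fh.read()
    df = pd.read_csv(_io.StringIO(rest), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df, state


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    if num.isna().to_numpy().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at row {df.index[i]!r}, column "
            f"{df.columns[j]!r}"
        )
    return num.astype(float)


def read_expression_matrix(
    path: PathLike,
    format: str = "tsv",
    flags_path: Optional[PathLike] = None,
) -> ExpressionMatrix:
    """Read a miRNA × sample matrix; row/column order is preserved.

    ``format="geo_series_matrix"`` accepts a GEO series-matrix text file
    (the table between the ``series_matrix_table_begin/end`` markers).
    Detection flags come from *flags_path*, or the ``.flags.tsv`` companion
    if it exists; otherwise every cell is marked detected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        raw, state = _read_table(path)
    elif format == "geo_series_matrix":
        raw, state = _read_geo_series_matrix(path), None
    else:
        raise ValueError(f"unknown format {format!r}")

    values = _to_numeric(raw, path)

    if flags_path is None and format == "tsv":
        candidate = flags_path_for(path)
        flags_path = candidate if candidate.exists() else None
    if flags_path is not None:
        fdf, _ = _read_table(Path(flags_path))
        fnum = _to_numeric(fdf, Path(flags_path))
        if list(fnum.index) != list(values.index) or list(fnum.columns) != list(
            values.columns
        ):
            raise ValidationError(
                f"{flags_path}: flag table ids do not match matrix ids"
            )
        detected = fnum.astype(bool)
    else:
        detected = pd.DataFrame(
            True, index=values.index, columns=values.columns
        )
    return ExpressionMatrix(values, detected, state=state or "raw")


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    lines = []
    in_table = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            low = line.strip().lower()
            if low.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                lines.append(line)
    if not lines:
        raise ParseError(f"{path}: no series_matrix_table section found")
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", index_col=0, dtype=str)
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def write_expression_matrix(
    m: ExpressionMatrix, path: PathLike, write_flags: bool = True
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# state: {m.state}\n")
        m.values.to_csv(fh, sep="\t", index_label="mirna_id", lineterminator="\n")
    if write_flags:
        fpath = flags_path_for(path)
        with open(fpath, "w", encoding="utf-8") as fh:
            fh.write("# state: flags\n")
            m.detected.astype(int).to_csv(
                fh, sep="\t", index_label="mirna_id", lineterminator="\n"
            )


def read_sample_metadata(path: PathLike) -> list[SampleMeta]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, comment="#")
    return frame_to_sample_meta(df)


def write_sample_metadata(meta: Sequence[SampleMeta], path: PathLike) -> None:
    sample_meta_to_frame(meta).to_csv(
        Path(path), sep="\t", index=False, lineterminator="\n"
    )


def read_mirbase_annotation(path: PathLike) -> list[MiRBaseAnnotation]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, comment="#")
    try:
        df["first_version"] = df["first_version"].astype(int)
    except KeyError:
        raise ParseError(f"{path}: missing column 'first_version'")
    except ValueError as e:
        raise ParseError(f"{path}: non-integer first_version ({e})")
    return frame_to_annotation(df)


def write_mirbase_annotation(
    ann: Sequence[MiRBaseAnnotation], path: PathLike
) -> None:
    annotation_to_frame(ann).to_csv(
        Path(path), sep="\t", index=False, lineterminator="\n"
    )


def read_transcripts(path: PathLike) -> dict[str, str]:
    """Read a transcript FASTA into {id: sequence}, U→T normalized."""
    path = Path(path)
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in out:
                raise ValidationError(f"{path}: duplicate transcript id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper().replace("U", "T")
    except ValueError as e:  # malformed record
        raise ParseError(f"{path}: FASTA parse failure ({e})")
    return out


def write_transcripts(transcripts: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in transcripts.items()
    ]
    SeqIO.write(records, str(Path(path)), "fasta")
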