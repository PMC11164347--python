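"""Reading and writing the on-disk formats.

Tab-separated files are the primary dialect (UTF-8, header required); comma
separation is accepted for ``.csv`` paths. Score matrices carry a
``protein_id`` column plus one column per EC code; annotation files are
two-column (``protein_id``, ``ec_numbers`` with comma-separated codes);
embedding tables are ``protein_id`` plus ``v1..vd``. Calibration results and
evaluation reports are JSON with stable key order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .conformal import CalibrationResult, ScoreMatrix
from .ontology import AnnotationSet, parse_ec
from .predictor import EmbeddingTable

__all__ = [
    "read_score_matrix",
    "write_score_matrix",
    "read_annotations",
    "write_annotations",
    "read_embeddings",
    "write_embeddings",
    "read_calibration",
    "write_calibration",
    "write_json",
]

PathLike = Union[str, Path]


def _sep(path: PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_score_matrix(path: PathLike) -> ScoreMatrix:
    """Read a protein x EC score table; validates range and uniqueness."""
    df = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    if df.columns[0] != "protein_id":
        raise ValueError(
            f"{path}: first column must be 'protein_id', got {df.columns[0]!r}"
        )
    if df["protein_id"].duplicated().any():
        dup = df["protein_id"][df["protein_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate protein ID {dup!r}")
    df = df.set_index("protein_id")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing score at protein {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: score {values[i, j]} out of [0, 1] at protein "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    labels = [parse_ec(c) for c in df.columns]
    return ScoreMatrix(list(df.index), labels, values)


def write_score_matrix(scores: ScoreMatrix, path: PathLike) -> None:
    scores.to_frame().to_csv(path, sep=_sep(path))


def read_annotations(path: PathLike) -> AnnotationSet:
    """Read a two-column annotation table (protein_id, ec_numbers)."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    expected = ["protein_id", "ec_numbers"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(df.columns[:2])}"
        )
    if df["protein_id"].duplicated().any():
        dup = df["protein_id"][df["protein_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate protein ID {dup!r}")
    labels_of = {}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        raw = row["ec_numbers"]
        if not isinstance(raw, str) or not raw.strip():
            raise ValueError(f"{path}: protein {pid!r} has no EC numbers")
        labels_of[pid] = {parse_ec(tok) for tok in raw.split(",")}
    return AnnotationSet(labels_of)


def write_annotations(ann: AnnotationSet, path: PathLike) -> None:
    sep = _sep(path)
    with open(path, "w") as fh:
        fh.write(f"protein_id{sep}ec_numbers\n")
        for pid in ann.proteins:
            ecs = ",".join(str(ec) for ec in sorted(ann[pid]))
            fh.write(f"{pid}{sep}{ecs}\n")


def read_embeddings(path: PathLike) -> EmbeddingTable:
    """Read a protein embedding table (protein_id, v1..vd)."""
    df = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    if df.columns[0] != "protein_id":
        raise ValueError(
            f"{path}: first column must be 'protein_id', got {df.columns[0]!r}"
        )
    df = df.set_index("protein_id")
    vectors = df.to_numpy(dtype=float)
    if not np.isfinite(vectors).all():
        raise ValueError(f"{path}: embedding table contains non-finite entries")
    return EmbeddingTable(list(df.index), vectors)


def write_embeddings(emb: EmbeddingTable, path: PathLike) -> None:
    emb.to_frame().to_csv(path, sep=_sep(path))


def write_calibration(result: CalibrationResult, path: PathLike) -> None:
    write_json(result.to_dict(), path)


def read_calibration(path: PathLike) -> CalibrationResult:
    with open(path) as fh:
        return CalibrationResult.from_dict(json.load(fh))


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
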