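"""Readers and writers for fixation, AOI and rater-assignment tables.

All tabular formats are plain text.  Fixation CSVs carry columns
``x,y,duration`` (header required) plus optional ``ground_truth_line`` and
``assigned_line`` columns; the JSON variant is a bare list of
``[x, y, duration]`` triplets.  AOI CSVs carry
``x,y,width,height,line[,token]`` with 0-based line indices.  Rater
matrices are wide CSVs: first column ``fixation_id``, one column per
rater, empty cells for missing assignments.

Round trips are lossless: floats are written with full ``repr`` precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import AreaOfInterest, FixationSequence, LayoutError, RaterMatrix, TextLayout

__all__ = [
    "ParseError",
    "read_fixations",
    "write_fixations",
    "read_ground_truth",
    "read_assigned_lines",
    "read_layout",
    "write_layout",
    "read_rater_matrix",
    "write_rater_matrix",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A table could not be parsed; the message names the column and row."""


def _infer_format(path: PathLike, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "json" if str(path).lower().endswith(".json") else "csv"


def _numeric(df: pd.DataFrame, col: str, path: PathLike, positive: bool = False) -> np.ndarray:
    if col not in df.columns:
        raise ParseError(f"{path}: missing required column {col!r}")
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        # +2: header line plus 1-based counting
        raise ParseError(f"{path}: non-numeric or missing value in column {col!r} at row {bad[0] + 2}")
    if positive:
        nonpos = vals.index[vals <= 0]
        if len(nonpos):
            raise ParseError(
                f"{path}: column {col!r} must be positive, got {vals[nonpos[0]]} at row {nonpos[0] + 2}"
            )
    return vals.to_numpy(float)


# ---------------------------------------------------------------------------
# fixations
# ---------------------------------------------------------------------------


def read_fixations(path: PathLike, fmt: Optional[str] = None) -> FixationSequence:
    """Read a fixation sequence from CSV (columns x, y, duration) or JSON.

    The format is inferred from the file suffix unless ``fmt`` ("csv" or
    "json") is given.  The trial id is the file stem.
    """
    fmt = _infer_format(path, fmt)
    trial_id = Path(path).stem
    if fmt == "json":
        with open(path) as fh:
            triplets = json.load(fh)
        try:
            return FixationSequence(triplets, trial_id=trial_id)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
    df = pd.read_csv(path, float_precision="round_trip")
    x = _numeric(df, "x", path)
    y = _numeric(df, "y", path)
    duration = _numeric(df, "duration", path, positive=True)
    return FixationSequence.from_arrays(x, y, duration, trial_id=trial_id)


def write_fixations(
    seq: FixationSequence,
    path: PathLike,
    fmt: Optional[str] = None,
    ground_truth_line: Optional[np.ndarray] = None,
    assigned_line: Optional[np.ndarray] = None,
) -> None:
    """Write a fixation sequence; optional line-label columns for CSV."""
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        data = [[x, y, d] for x, y, d in zip(seq.x, seq.y, seq.duration)]
        with open(path, "w") as fh:
            json.dump(data, fh)
        return
    df = seq.to_frame()
    if ground_truth_line is not None:
        df["ground_truth_line"] = np.asarray(ground_truth_line, int)
    if assigned_line is not None:
        df["assigned_line"] = np.asarray(assigned_line, int)
    df.to_csv(path, index=False)


def _line_column(path: PathLike, col: str) -> np.ndarray:
    df = pd.read_csv(path)
    vals = _numeric(df, col, path)
    if np.any(vals != np.round(vals)) or np.any(vals < 0):
        raise ParseError(f"{path}: column {col!r} must hold non-negative integer line indices")
    return vals.astype(int)


def read_ground_truth(path: PathLike) -> np.ndarray:
    """Read the ``ground_truth_line`` column of a synthetic-trial CSV."""
    return _line_column(path, "ground_truth_line")


def read_assigned_lines(path: PathLike) -> np.ndarray:
    """Read the ``assigned_line`` column of a corrected-trial CSV."""
    return _line_column(path, "assigned_line")


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------


def read_layout(path: PathLike) -> TextLayout:
    """Read an AOI table (columns x, y, width, height, line[, token]).

    Line positions are derived as the vertical centers of each line's
    AOIs; AOIs declared on one line must agree on y and height.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    x = _numeric(df, "x", path)
    y = _numeric(df, "y", path)
    w = _numeric(df, "width", path, positive=True)
    h = _numeric(df, "height", path, positive=True)
    line = _numeric(df, "line", path)
    if np.any(line != np.round(line)) or np.any(line < 0):
        raise ParseError(f"{path}: column 'line' must hold non-negative integer indices")
    tokens = df["token"].astype("string") if "token" in df.columns else None
    aois = []
    for i in range(len(df)):
        token = None
        if tokens is not None and pd.notna(tokens.iloc[i]):
            token = str(tokens.iloc[i])
        aois.append(AreaOfInterest(x[i], y[i], w[i], h[i], int(line[i]), token))
    try:
        return TextLayout(aois)
    except LayoutError as exc:
        raise LayoutError(f"{path}: {exc}") from exc


def write_layout(layout: TextLayout, path: PathLike) -> None:
    layout.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rater matrices
# ---------------------------------------------------------------------------


def read_rater_matrix(path: PathLike) -> RaterMatrix:
    """Read a wide rater table: first column fixation_id, one column per rater."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: rater matrix has no rater columns")
    try:
        return RaterMatrix(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_rater_matrix(matrix: RaterMatrix, path: PathLike) -> None:
    df = matrix.assignments
    df.index.name = "fixation_id"
    df.to_csv(path)
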