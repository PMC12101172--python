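"""Core domain types for reading eye-tracking drift correction.

Coordinate conventions used throughout the package:

* positions are in screen pixels with the origin at the top-left corner,
  x increasing rightward and y increasing **downward**;
* text lines are indexed 0-based from top to bottom;
* a line's position (an entry of ``line_ys``) is the vertical center of
  the words on that line, which is where an accurately recorded fixation
  rests;
* fixation durations are milliseconds, carried as floats.

The central container is :class:`FixationSequence`, an ordered, immutable
record of (x, y, duration) triplets for one trial.  :class:`TextLayout`
holds the word rectangles (areas of interest, AOIs) of the stimulus and
derives the sorted line positions and word centers that the correction
algorithms consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayoutError",
    "Fixation",
    "FixationSequence",
    "AreaOfInterest",
    "TextLayout",
    "DistortionSpec",
    "CorrectionResult",
    "RaterMatrix",
    "nearest_line",
    "nearest_lines",
    "as_line_ys",
]


class LayoutError(ValueError):
    """Raised when a text layout (or a line_ys array) is invalid."""


# ---------------------------------------------------------------------------
# fixations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixation:
    """A single fixation: position in pixels plus duration in milliseconds."""

    x: float
    y: float
    duration: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"fixation position must be finite, got ({self.x}, {self.y})")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"fixation duration must be positive and finite, got {self.duration}")


class FixationSequence:
    """An ordered sequence of fixations belonging to one trial.

    Internally stored as contiguous float arrays.  Instances are
    value-immutable: the coordinate arrays are read-only and operations
    that change coordinates (distortion, correction) return new sequences,
    preserving order and length.

    Parameters
    ----------
    fixations
        Iterable of :class:`Fixation` objects or (x, y, duration) triplets.
    trial_id
        Optional identifier carried through distortion and correction.
    """

    __slots__ = ("_x", "_y", "_duration", "trial_id")

    def __init__(self, fixations: Iterable = (), trial_id: Optional[str] = None):
        xs, ys, ds = [], [], []
        for f in fixations:
            if isinstance(f, Fixation):
                xs.append(f.x), ys.append(f.y), ds.append(f.duration)
            else:
                x, y, d = f
                xs.append(float(x)), ys.append(float(y)), ds.append(float(d))
        self._init_arrays(np.asarray(xs, float), np.asarray(ys, float), np.asarray(ds, float))
        self.trial_id = trial_id

    @classmethod
    def from_arrays(
        cls,
        x: np.ndarray,
        y: np.ndarray,
        duration: np.ndarray,
        trial_id: Optional[str] = None,
    ) -> "FixationSequence":
        obj = cls.__new__(cls)
        obj._init_arrays(
            np.asarray(x, float).copy(),
            np.asarray(y, float).copy(),
            np.asarray(duration, float).copy(),
        )
        obj.trial_id = trial_id
        return obj

    def _init_arrays(self, x: np.ndarray, y: np.ndarray, duration: np.ndarray) -> None:
        if not (x.shape == y.shape == duration.shape) or x.ndim != 1:
            raise ValueError("x, y and duration must be 1-D arrays of equal length")
        if x.size and not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("fixation positions must be finite")
        if duration.size and not (np.isfinite(duration).all() and (duration > 0).all()):
            bad = int(np.flatnonzero(~(np.isfinite(duration) & (duration > 0)))[0])
            raise ValueError(f"fixation durations must be positive and finite (fixation {bad})")
        for a in (x, y, duration):
            a.setflags(write=False)
        self._x, self._y, self._duration = x, y, duration

    # -- array views --------------------------------------------------------

    @property
    def x(self) -> np.ndarray:
        """Horizontal positions in pixels (read-only array)."""
        return self._x

    @property
    def y(self) -> np.ndarray:
        """Vertical positions in pixels, y growing downward (read-only)."""
        return self._y

    @property
    def duration(self) -> np.ndarray:
        """Durations in milliseconds (read-only array)."""
        return self._duration

    def with_y(self, new_y: np.ndarray) -> "FixationSequence":
        """Return a copy with replaced y-values; x and duration are shared values."""
        return FixationSequence.from_arrays(self._x, new_y, self._duration, self.trial_id)

    def with_xy(self, new_x: np.ndarray, new_y: np.ndarray) -> "FixationSequence":
        return FixationSequence.from_arrays(new_x, new_y, self._duration, self.trial_id)

    # -- sequence protocol ---------------------------------------------------

    def __len__(self) -> int:
        return self._x.size

    def __iter__(self) -> Iterator[Fixation]:
        for x, y, d in zip(self._x, self._y, self._duration):
            yield Fixation(float(x), float(y), float(d))

    def __getitem__(self, i):
        if isinstance(i, slice):
            return FixationSequence.from_arrays(
                self._x[i], self._y[i], self._duration[i], self.trial_id
            )
        return Fixation(float(self._x[i]), float(self._y[i]), float(self._duration[i]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FixationSequence):
            return NotImplemented
        return (
            np.array_equal(self._x, other._x)
            and np.array_equal(self._y, other._y)
            and np.array_equal(self._duration, other._duration)
        )

    def __repr__(self) -> str:
        tid = f", trial_id={self.trial_id!r}" if self.trial_id else ""
        return f"FixationSequence(n={len(self)}{tid})"

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns x, y, duration."""
        return pd.DataFrame({"x": self._x, "y": self._y, "duration": self._duration})


# ---------------------------------------------------------------------------
# text layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AreaOfInterest:
    """A word rectangle: top-left corner, extent, and 0-based line index."""

    x: float
    y: float
    width: float
    height: float
    line: int
    token: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"AOI width and height must be positive, got {self.width}x{self.height}")
        if self.line < 0 or int(self.line) != self.line:
            raise ValueError(f"AOI line index must be a non-negative integer, got {self.line}")

    @property
    def center(self) -> tuple:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


class TextLayout:
    """The word AOIs of a reading stimulus, in reading order.

    Derives ``line_ys`` — the strictly increasing vertical centers of the
    text lines — and per-word centers.  AOIs declared on the same line must
    share the same top y and height, and line indices must form a
    contiguous 0..m-1 range ordered top to bottom.
    """

    def __init__(self, aois: Sequence[AreaOfInterest]):
        aois = list(aois)
        if not aois:
            raise LayoutError("layout must contain at least one AOI")
        lines = sorted({a.line for a in aois})
        if lines != list(range(len(lines))):
            raise LayoutError(f"line indices must be contiguous 0..m-1, got {lines}")
        line_ys = np.empty(len(lines), float)
        for li in lines:
            members = [a for a in aois if a.line == li]
            ys = {a.y for a in members}
            hs = {a.height for a in members}
            if len(ys) > 1 or len(hs) > 1:
                raise LayoutError(
                    f"AOIs on line {li} disagree on vertical position: y={sorted(ys)}, height={sorted(hs)}"
                )
            line_ys[li] = members[0].y + members[0].height / 2.0
        if not np.all(np.diff(line_ys) > 0):
            raise LayoutError("line y-positions must strictly increase with line index")
        line_ys.setflags(write=False)
        self._aois = aois
        self._line_ys = line_ys
        centers = np.array([a.center for a in aois], float)
        centers.setflags(write=False)
        self._word_centers = centers

    @property
    def aois(self) -> list:
        return list(self._aois)

    @property
    def line_ys(self) -> np.ndarray:
        """Vertical center of each text line, sorted ascending (read-only)."""
        return self._line_ys

    @property
    def word_centers(self) -> np.ndarray:
        """(n_words, 2) array of word center coordinates, reading order."""
        return self._word_centers

    @property
    def n_lines(self) -> int:
        return self._line_ys.size

    @property
    def line_spacing(self) -> float:
        """Vertical distance between the first two lines (the ``line_height``
        used by the shift distortion).  Requires at least two lines."""
        if self.n_lines < 2:
            raise LayoutError("line spacing is undefined for a single-line layout")
        return float(self._line_ys[1] - self._line_ys[0])

    def aois_on_line(self, line: int) -> list:
        return [a for a in self._aois if a.line == line]

    def __len__(self) -> int:
        return len(self._aois)

    def __repr__(self) -> str:
        return f"TextLayout(n_words={len(self)}, n_lines={self.n_lines})"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": [a.x for a in self._aois],
                "y": [a.y for a in self._aois],
                "width": [a.width for a in self._aois],
                "height": [a.height for a in self._aois],
                "line": [a.line for a in self._aois],
                "token": [a.token for a in self._aois],
            }
        )


# ---------------------------------------------------------------------------
# distortion / correction records
# ---------------------------------------------------------------------------

_DISTORTION_PARAMS = {
    "noise": {"ynoise"},
    "slope": {"slope_factor"},
    "shift": {"y_shift_factor"},
    "offset": {"x_offset", "y_offset"},
}


@dataclass(frozen=True)
class DistortionSpec:
    """A named drift distortion with its magnitude parameters.

    ``kind`` is one of ``noise`` (vertical Gaussian noise with SD
    ``ynoise``), ``slope`` (vertical drift linear in x, ``slope_factor``),
    ``shift`` (drift growing with distance from the first line,
    ``y_shift_factor``) or ``offset`` (a constant translation,
    ``x_offset``/``y_offset``).  ``seed`` fixes the output of the
    stochastic ``noise`` kind exactly.
    """

    kind: str
    params: dict
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _DISTORTION_PARAMS:
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        required = _DISTORTION_PARAMS[self.kind]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"{self.kind} distortion requires parameters {sorted(missing)}")
        for k in required:
            v = self.params[k]
            if not math.isfinite(v):
                raise ValueError(f"{self.kind} parameter {k} must be finite, got {v}")
        if self.kind == "noise" and self.params["ynoise"] < 0:
            raise ValueError("ynoise must be non-negative")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}


@dataclass(frozen=True)
class CorrectionResult:
    """Output of a correction algorithm.

    ``corrected`` has the input's x and durations with every y snapped to a
    member of the layout's line positions; ``line_assignment[i]`` is the
    0-based index of that line.
    """

    corrected: FixationSequence
    line_assignment: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        la = np.asarray(self.line_assignment, dtype=int)
        la.setflags(write=False)
        object.__setattr__(self, "line_assignment", la)
        if len(la) != len(self.corrected):
            raise ValueError("line_assignment length must match the corrected sequence")


# ---------------------------------------------------------------------------
# rater matrices
# ---------------------------------------------------------------------------


class RaterMatrix:
    """Fixations x raters table of line assignments for agreement analysis.

    Rows are fixations (unique IDs), columns are raters; cells hold 0-based
    line indices, with NaN marking a fixation a rater did not assign.
    """

    def __init__(self, assignments: pd.DataFrame):
        df = assignments.astype(float)
        if df.index.has_duplicates:
            raise ValueError("fixation IDs must be unique")
        if df.columns.has_duplicates:
            raise ValueError("rater IDs must be unique")
        values = df.to_numpy()
        finite = values[np.isfinite(values)]
        if finite.size and (np.any(finite < 0) or np.any(finite != np.round(finite))):
            raise ValueError("rater matrix cells must be non-negative line indices or missing")
        self._df = df

    @classmethod
    def from_dict(cls, data: dict, fixation_ids: Optional[Sequence] = None) -> "RaterMatrix":
        """Build from a mapping rater_id -> list of line indices (None = missing)."""
        df = pd.DataFrame({k: [np.nan if v is None else v for v in col] for k, col in data.items()})
        if fixation_ids is not None:
            df.index = pd.Index(fixation_ids)
        return cls(df)

    @property
    def assignments(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def fixation_ids(self) -> list:
        return list(self._df.index)

    @property
    def rater_ids(self) -> list:
        return list(self._df.columns)

    @property
    def n_fixations(self) -> int:
        return self._df.shape[0]

    @property
    def n_raters(self) -> int:
        return self._df.shape[1]

    def __repr__(self) -> str:
        return f"RaterMatrix(n_fixations={self.n_fixations}, n_raters={self.n_raters})"


# ---------------------------------------------------------------------------
# nearest-line mapping
# ---------------------------------------------------------------------------


def as_line_ys(line_ys) -> np.ndarray:
    """Coerce a TextLayout or array-like into a validated line_ys array."""
    if isinstance(line_ys, TextLayout):
        return line_ys.line_ys
    arr = np.asarray(line_ys, float)
    if arr.ndim != 1 or arr.size == 0:
        raise LayoutError("line_ys must be a non-empty 1-D array")
    if np.any(np.diff(arr) <= 0):
        raise LayoutError("line_ys must be strictly increasing")
    return arr


def nearest_line(y: float, line_ys) -> int:
    """Index of the line position closest to ``y``.

    Binary search over the sorted line positions followed by a single
    neighbor comparison; exact ties resolve to the lower index.
    """
    arr = as_line_ys(line_ys)
    hi = int(np.searchsorted(arr, y))
    if hi >= arr.size:
        return arr.size - 1
    if hi == 0:
        return 0
    # tie (equidistant) goes to the lower index
    return hi - 1 if (y - arr[hi - 1]) <= (arr[hi] - y) else hi


def nearest_lines(ys, line_ys) -> np.ndarray:
    """Vectorized :func:`nearest_line` for an array of y-values."""
    arr = as_line_ys(line_ys)
    ys = np.asarray(ys, float)
    hi = np.searchsorted(arr, ys)
    hi = np.clip(hi, 0, arr.size - 1)
    lo = np.maximum(hi - 1, 0)
    pick_lo = (ys - arr[lo]) <= (arr[hi] - ys)
    return np.where(pick_lo, lo, hi).astype(int)
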