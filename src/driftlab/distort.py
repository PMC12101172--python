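"""The four parametric drift distortions applied to fixation sequences.

Each distortion models a failure mode of eye-tracking recordings in
reading experiments:

* **noise** — independent vertical Gaussian perturbation of each fixation
  (measurement jitter), SD ``ynoise`` pixels;
* **slope** — vertical drift growing linearly with horizontal distance
  from the first fixation (one-sided calibration error),
  ``adjusted_y = y + (x - first_x) / 100 * slope_factor``;
* **shift** — vertical drift growing with a fixation's distance from the
  first text line, in units of the line height (progressive vertical
  miscalibration), ``adjusted_y = y + |y - line_ys[0]| / line_height *
  y_shift_factor``;
* **offset** — a constant translation of every fixation (systematic
  drift).

All four preserve sequence length, order and durations; only ``offset``
touches x.  The distance term of ``shift`` is computed from the input
y-values, not iteratively.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .core import DistortionSpec, FixationSequence, TextLayout, as_line_ys

__all__ = ["error_noise", "error_slope", "error_shift", "error_offset", "apply_spec"]


def error_noise(
    seq: FixationSequence,
    ynoise: float,
    seed: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
) -> FixationSequence:
    """Add vertical Gaussian noise N(0, ynoise) to each fixation's y.

    ``mask``, if given, restricts the perturbation to a boolean subset of
    fixations (all fixations are perturbed by default).  A fixed ``seed``
    reproduces the output exactly; ``ynoise=0`` is the identity.
    """
    if ynoise < 0:
        raise ValueError(f"ynoise must be non-negative, got {ynoise}")
    rng = np.random.default_rng(seed)
    perturbation = rng.normal(0.0, ynoise, size=len(seq))
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != (len(seq),):
            raise ValueError("mask must be a boolean array matching the sequence length")
        perturbation = np.where(mask, perturbation, 0.0)
    return seq.with_y(seq.y + perturbation)


def error_slope(seq: FixationSequence, slope_factor: float) -> FixationSequence:
    """Tilt y-values linearly in x, anchored at the first fixation's x."""
    if len(seq) == 0:
        raise ValueError("cannot apply a slope distortion to an empty sequence")
    first_x = seq.x[0]
    return seq.with_y(seq.y + (seq.x - first_x) / 100.0 * slope_factor)


def error_shift(
    seq: FixationSequence,
    line_ys: Union[np.ndarray, TextLayout],
    y_shift_factor: float,
) -> FixationSequence:
    """Shift y-values in proportion to their distance from the first line."""
    arr = as_line_ys(line_ys)
    if arr.size < 2:
        raise ValueError("shift distortion requires at least two lines (line height undefined)")
    line_height = arr[1] - arr[0]
    distance = np.abs(seq.y - arr[0])
    return seq.with_y(seq.y + distance / line_height * y_shift_factor)


def error_offset(seq: FixationSequence, x_offset: float, y_offset: float) -> FixationSequence:
    """Translate every fixation by (x_offset, y_offset)."""
    return seq.with_xy(seq.x + x_offset, seq.y + y_offset)


def apply_spec(
    seq: FixationSequence,
    spec: DistortionSpec,
    line_ys: Optional[Union[np.ndarray, TextLayout]] = None,
) -> FixationSequence:
    """Apply a :class:`DistortionSpec`; ``shift`` requires ``line_ys``."""
    if spec.kind == "noise":
        return error_noise(seq, spec.params["ynoise"], seed=spec.seed)
    if spec.kind == "slope":
        return error_slope(seq, spec.params["slope_factor"])
    if spec.kind == "shift":
        if line_ys is None:
            raise ValueError("the shift distortion needs the layout's line positions")
        return error_shift(seq, line_ys, spec.params["y_shift_factor"])
    if spec.kind == "offset":
        return error_offset(seq, spec.params["x_offset"], spec.params["y_offset"])
    raise ValueError(f"unknown distortion kind {spec.kind!r}")  # pragma: no cover
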