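"""The nine automated drift-correction algorithms.

Every algorithm maps a fixation sequence plus the text-line positions (or
the full word layout, for Warp) to a :class:`~driftlab.core.CorrectionResult`:
the input sequence with each y-value snapped to a member of ``line_ys``
and the matching 0-based line assignment.  None of them alters x or
duration, and all preserve length and order.

* **attach** — snap each fixation to its nearest line (binary search).
* **chain** — group consecutive fixations into chains wherever the x and
  y steps stay below thresholds; snap each chain by its mean y.
* **cluster** — k-means (k = number of lines) on the y-values; clusters
  are matched to lines in vertical order.
* **merge** — split at x-backtracks / large y-jumps, then merge sequence
  pairs whose joint regression line is flat and tight, over four
  progressively relaxed phases, until one sequence per line remains.
* **regress** — fit slope/offset/spread of a Gaussian mixture centered on
  the candidate lines by bounded maximum likelihood; assign each fixation
  to its most probable line.
* **segment** — treat the m-1 most negative x-displacements (return
  sweeps) as line breaks and assign lines top to bottom.
* **split** — 2-means on the x-displacements; the lower-mean cluster
  marks segment boundaries, segments snap by mean y.
* **stretch** — bounded optimization of a scale+offset transform of the
  y-values minimizing the distance to the nearest lines.
* **warp** — dynamic time warping of the fixation sequence onto the word
  centers; each fixation takes the modal line of its matched words.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.cluster import KMeans

from .core import (
    CorrectionResult,
    FixationSequence,
    TextLayout,
    as_line_ys,
    nearest_line,
    nearest_lines,
)

__all__ = [
    "ChainParams",
    "RegressParams",
    "StretchParams",
    "attach",
    "chain",
    "cluster",
    "merge",
    "regress",
    "segment",
    "split",
    "stretch",
    "warp",
    "dtw_path",
    "run_all",
    "ALGORITHM_NAMES",
]

ALGORITHM_NAMES = (
    "attach",
    "chain",
    "cluster",
    "merge",
    "regress",
    "segment",
    "split",
    "stretch",
    "warp",
)


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainParams:
    """Spatial thresholds that end a chain of consecutive fixations."""

    x_thresh: float = 192.0
    y_thresh: float = 32.0

    def __post_init__(self) -> None:
        if not (self.x_thresh > 0 and self.y_thresh > 0):
            raise ValueError("chain thresholds must be positive")


@dataclass(frozen=True)
class RegressParams:
    """Bounds of the regress likelihood fit: slope, vertical offset, spread.

    ``offset_bounds=None`` defaults to +/- half the line spacing of the
    layout the algorithm is run on.
    """

    slope_bounds: Tuple[float, float] = (-0.1, 0.1)
    offset_bounds: Optional[Tuple[float, float]] = None
    sd_bounds: Tuple[float, float] = (1.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("slope_bounds", "offset_bounds", "sd_bounds"):
            b = getattr(self, name)
            if b is not None and not b[0] < b[1]:
                raise ValueError(f"{name} must satisfy lo < hi, got {b}")


@dataclass(frozen=True)
class StretchParams:
    """Bounds of the stretch transform; must bracket the identity."""

    scale_bounds: Tuple[float, float] = (0.9, 1.1)
    offset_bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.scale_bounds[0] <= 1.0 <= self.scale_bounds[1]:
            raise ValueError("scale_bounds must contain 1.0")
        if self.offset_bounds is not None and not self.offset_bounds[0] <= 0.0 <= self.offset_bounds[1]:
            raise ValueError("offset_bounds must contain 0.0")


def _default_offset_bounds(line_ys: np.ndarray) -> Tuple[float, float]:
    half = (line_ys[1] - line_ys[0]) / 2.0 if line_ys.size >= 2 else 25.0
    return (-half, half)


def _result(
    seq: FixationSequence,
    line_idx: np.ndarray,
    line_ys: np.ndarray,
    algorithm: str,
    params: dict,
) -> CorrectionResult:
    line_idx = np.asarray(line_idx, int)
    return CorrectionResult(
        corrected=seq.with_y(line_ys[line_idx]),
        line_assignment=line_idx,
        algorithm=algorithm,
        params=params,
    )


def _require_nonempty(seq: FixationSequence, algorithm: str) -> None:
    if len(seq) == 0:
        raise ValueError(f"{algorithm} requires a non-empty fixation sequence")


# ---------------------------------------------------------------------------
# positional algorithms
# ---------------------------------------------------------------------------


def attach(seq: FixationSequence, line_ys) -> CorrectionResult:
    """Snap each fixation to the closest line (binary search, O(n log m))."""
    _require_nonempty(seq, "attach")
    arr = as_line_ys(line_ys)
    idx = nearest_lines(seq.y, arr)
    return _result(seq, idx, arr, "attach", {})


def chain(seq: FixationSequence, line_ys, params: Optional[ChainParams] = None) -> CorrectionResult:
    """Snap chains of spatially contiguous fixations by their mean y.

    A chain ends wherever the step to the next fixation exceeds
    ``x_thresh`` horizontally or ``y_thresh`` vertically.
    """
    _require_nonempty(seq, "chain")
    params = params or ChainParams()
    arr = as_line_ys(line_ys)
    dist_x = np.abs(np.diff(seq.x))
    dist_y = np.abs(np.diff(seq.y))
    ends = list(np.where((dist_x > params.x_thresh) | (dist_y > params.y_thresh))[0] + 1)
    ends.append(len(seq))
    idx = np.empty(len(seq), int)
    start = 0
    for end in ends:
        mean_y = float(seq.y[start:end].mean())
        idx[start:end] = nearest_line(mean_y, arr)
        start = end
    return _result(seq, idx, arr, "chain", {"x_thresh": params.x_thresh, "y_thresh": params.y_thresh})


def cluster(seq: FixationSequence, line_ys, seed: int = 0, n_init: int = 10) -> CorrectionResult:
    """k-means on the y-values with one cluster per line.

    Clusters are sorted by mean y and matched, top to bottom, to the
    lines; deterministic under a fixed seed.
    """
    arr = as_line_ys(line_ys)
    m = arr.size
    if len(seq) < m:
        raise ValueError(f"cluster needs at least as many fixations ({len(seq)}) as lines ({m})")
    km = KMeans(n_clusters=m, n_init=n_init, random_state=seed)
    labels = km.fit_predict(seq.y.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    rank = np.empty(m, int)
    rank[order] = np.arange(m)
    idx = rank[labels]
    return _result(seq, idx, arr, "cluster", {"seed": seed, "n_init": n_init})


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


def _line_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Least-squares line through points; returns (gradient, rms residual).

    Degenerate inputs (fewer than two points, or no x spread) get a flat
    gradient and the rms spread around the mean y.
    """
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0, float(np.sqrt(np.mean((y - y.mean()) ** 2))) if x.size else 0.0
    slope = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    return slope, float(np.sqrt(np.mean(resid**2)))


def merge(
    seq: FixationSequence,
    line_ys,
    gradient_thresh: float = 0.1,
    error_thresh: float = 20.0,
    x_thresh: float = 192.0,
    y_thresh: float = 32.0,
) -> CorrectionResult:
    """Iteratively merge fixation subsequences until one per line remains.

    The sequence is first split at large x-backtracks (dx < -x_thresh) and
    large vertical jumps (|dy| > y_thresh).  Pairs of subsequences are then
    merged — best (lowest joint rms error) first — whenever the regression
    line through their union is acceptably flat and tight, over four
    phases that relax the constraints: both thresholds, gradient only,
    error only, and finally unconstrained.  The surviving sequences are
    sorted by mean y and matched to the lines in order.
    """
    _require_nonempty(seq, "merge")
    arr = as_line_ys(line_ys)
    m = arr.size
    x, y = seq.x, seq.y
    dx = np.diff(x)
    dy = np.abs(np.diff(y))
    breaks = list(np.where((dx < -x_thresh) | (dy > y_thresh))[0] + 1)
    bounds = [0, *breaks, len(seq)]
    sequences: List[List[int]] = [
        list(range(a, b)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]

    phases = ((True, True), (True, False), (False, True), (False, False))
    for check_gradient, check_error in phases:
        while len(sequences) > m:
            best: Optional[Tuple[int, int]] = None
            best_error = np.inf
            for i in range(len(sequences) - 1):
                for j in range(i + 1, len(sequences)):
                    union = sequences[i] + sequences[j]
                    gradient, error = _line_fit(x[union], y[union])
                    if check_gradient and abs(gradient) > gradient_thresh:
                        continue
                    if check_error and error > error_thresh:
                        continue
                    if error < best_error:
                        best_error, best = error, (i, j)
            if best is None:
                break
            i, j = best
            sequences[i] = sequences[i] + sequences[j]
            del sequences[j]

    mean_ys = np.array([y[s].mean() for s in sequences])
    order = np.argsort(mean_ys, kind="stable")
    idx = np.empty(len(seq), int)
    if len(sequences) == m:
        for line_i, seq_i in enumerate(order):
            idx[sequences[seq_i]] = line_i
    else:  # fewer initial sequences than lines: snap each by its mean y
        for seq_i, members in enumerate(sequences):
            idx[members] = nearest_line(float(mean_ys[seq_i]), arr)
    return _result(
        seq,
        idx,
        arr,
        "merge",
        {
            "gradient_thresh": gradient_thresh,
            "error_thresh": error_thresh,
            "x_thresh": x_thresh,
            "y_thresh": y_thresh,
        },
    )


# ---------------------------------------------------------------------------
# regress
# ---------------------------------------------------------------------------


def regress(seq: FixationSequence, line_ys, params: Optional[RegressParams] = None) -> CorrectionResult:
    """Maximum-likelihood line assignment under a slope+offset+spread model.

    Each line predicts fixation y-values ``line_y + slope * x + offset``
    with Gaussian spread ``sd``; the three parameters are fitted within
    bounds by minimizing the negative log-likelihood of each fixation's
    best line, and fixations are then assigned to their most probable
    line.
    """
    _require_nonempty(seq, "regress")
    arr = as_line_ys(line_ys)
    params = params or RegressParams()
    offset_bounds = params.offset_bounds or _default_offset_bounds(arr)
    x, y = seq.x, seq.y

    def log_density(theta: np.ndarray) -> np.ndarray:
        k, o, s = theta
        predicted = arr[None, :] + k * x[:, None] + o  # (n, m)
        return norm.logpdf(y[:, None], predicted, s)

    def objective(theta: np.ndarray) -> float:
        return -float(log_density(theta).max(axis=1).sum())

    bounds = [params.slope_bounds, offset_bounds, params.sd_bounds]
    mid_sd = 0.5 * (params.sd_bounds[0] + params.sd_bounds[1])
    # The likelihood is multimodal in the offset (each whole-line shift of the
    # assignment is a mode), so refine from a coarse offset grid and keep the
    # best local optimum; deterministic.
    starts = [np.array([0.0, o, mid_sd]) for o in np.linspace(*offset_bounds, 7)]
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        warnings.warn(
            "regress optimizer did not converge; using best evaluated point",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = log_density(best.x).argmax(axis=1)
    fitted = {"slope": float(best.x[0]), "offset": float(best.x[1]), "sd": float(best.x[2])}
    return _result(
        seq,
        idx,
        arr,
        "regress",
        {
            "slope_bounds": params.slope_bounds,
            "offset_bounds": tuple(offset_bounds),
            "sd_bounds": params.sd_bounds,
            "fitted": fitted,
        },
    )


# ---------------------------------------------------------------------------
# sequential algorithms
# ---------------------------------------------------------------------------


def segment(seq: FixationSequence, line_ys, convention: str = "most_negative") -> CorrectionResult:
    """Assign lines top-to-bottom, breaking at the m-1 return sweeps.

    Return sweeps are identified from the consecutive x-displacements:
    by default the m-1 most negative ones (the long leftward jumps that
    start a new line).  ``convention="largest"`` instead takes the m-1
    largest-magnitude displacements.  Line indices are non-decreasing by
    construction.
    """
    _require_nonempty(seq, "segment")
    arr = as_line_ys(line_ys)
    m = arr.size
    if m - 1 > len(seq) - 1:
        raise ValueError(f"segment needs at least {m} fixations for {m} lines")
    diff_x = np.diff(seq.x)
    if convention == "most_negative":
        order = np.argsort(diff_x, kind="stable")
    elif convention == "largest":
        order = np.argsort(-np.abs(diff_x), kind="stable")
    else:
        raise ValueError(f"unknown segment convention {convention!r}")
    break_after = set(order[: m - 1].tolist())
    idx = np.empty(len(seq), int)
    line_i = 0
    for i in range(len(seq)):
        idx[i] = line_i
        if i in break_after:
            line_i += 1
    return _result(seq, idx, arr, "segment", {"convention": convention})


def split(seq: FixationSequence, line_ys, seed: int = 0, n_init: int = 10) -> CorrectionResult:
    """Split at sweep saccades found by 2-means on the x-displacements.

    The cluster with the lower mean displacement holds the (leftward)
    sweep saccades; each resulting segment snaps to the line nearest its
    mean y.
    """
    if len(seq) < 3:
        raise ValueError("split needs at least three fixations")
    arr = as_line_ys(line_ys)
    diff_x = np.diff(seq.x)
    if np.ptp(diff_x) == 0:
        raise ValueError("split is undefined when all x-displacements are identical")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(diff_x.reshape(-1, 1))
    sweep_cluster = int(np.argmin(km.cluster_centers_.ravel()))
    boundaries = list(np.where(labels == sweep_cluster)[0] + 1)
    bounds = [0, *boundaries, len(seq)]
    idx = np.empty(len(seq), int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            idx[a:b] = nearest_line(float(seq.y[a:b].mean()), arr)
    return _result(seq, idx, arr, "split", {"seed": seed, "n_init": n_init})


# ---------------------------------------------------------------------------
# stretch
# ---------------------------------------------------------------------------


def stretch(seq: FixationSequence, line_ys, params: Optional[StretchParams] = None) -> CorrectionResult:
    """Fit a bounded scale+offset of the y-values onto the lines.

    Minimizes the summed absolute distance between the transformed
    y-values and their nearest lines (a piecewise-linear objective, hence
    a derivative-free bounded search), then snaps the transformed values.
    """
    _require_nonempty(seq, "stretch")
    arr = as_line_ys(line_ys)
    params = params or StretchParams()
    offset_bounds = params.offset_bounds or _default_offset_bounds(arr)
    y = seq.y

    def cost(v: np.ndarray) -> float:
        ty = v[0] * y + v[1]
        return float(np.abs(ty - arr[nearest_lines(ty, arr)]).sum())

    res = minimize(
        cost,
        np.array([1.0, 0.0]),
        method="Powell",
        bounds=[params.scale_bounds, tuple(offset_bounds)],
    )
    scale, offset = res.x
    idx = nearest_lines(scale * y + offset, arr)
    return _result(
        seq,
        idx,
        arr,
        "stretch",
        {
            "scale_bounds": params.scale_bounds,
            "offset_bounds": tuple(offset_bounds),
            "fitted": {"scale": float(scale), "offset": float(offset), "cost": float(res.fun)},
        },
    )


# ---------------------------------------------------------------------------
# warp
# ---------------------------------------------------------------------------


def dtw_path(cost: np.ndarray) -> Tuple[List[Tuple[int, int]], float]:
    """Dynamic time warping over a pairwise cost matrix.

    Classic cost-matrix recursion with unit steps (down, right, diagonal);
    returns the minimum-cost monotone alignment path from (0, 0) to
    (n-1, m-1) and its total cost (the sum of cell costs along the path).
    Ties prefer the diagonal predecessor, then the vertical one.
    """
    n, m = cost.shape
    if n == 0 or m == 0:
        raise ValueError("DTW requires non-empty sequences")
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(n):
        for j in range(m):
            acc[i + 1, j + 1] = cost[i, j] + min(acc[i, j], acc[i, j + 1], acc[i + 1, j])
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while i > 0 or j > 0:
        options = [(acc[i, j], i - 1, j - 1), (acc[i, j + 1], i - 1, j), (acc[i + 1, j], i, j - 1)]
        options = [(v, pi, pj) for v, pi, pj in options if pi >= 0 and pj >= 0]
        _, i, j = min(options, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return path, float(acc[n, m])


def warp(seq: FixationSequence, layout: TextLayout) -> CorrectionResult:
    """Align fixations to word centers with DTW; snap to the modal line.

    The cost matrix is the pairwise Euclidean distance between fixation
    positions and word centers.  Each fixation takes the most frequent
    line among the words its path cell(s) match; a frequency tie resolves
    to the earliest (topmost) line.
    """
    _require_nonempty(seq, "warp")
    if len(layout) == 0:
        raise ValueError("warp requires a layout with at least one word")
    arr = layout.line_ys
    fix_xy = np.column_stack([seq.x, seq.y])
    word_xy = layout.word_centers
    cost = np.sqrt(((fix_xy[:, None, :] - word_xy[None, :, :]) ** 2).sum(axis=2))
    path, _ = dtw_path(cost)
    word_lines = np.array([a.line for a in layout.aois], int)
    matched: List[List[int]] = [[] for _ in range(len(seq))]
    for i, j in path:
        matched[i].append(int(word_lines[j]))
    idx = np.empty(len(seq), int)
    for i, lines in enumerate(matched):
        counts = np.bincount(lines, minlength=arr.size)
        idx[i] = int(np.argmax(counts))  # argmax tie -> lowest line index
    return _result(seq, idx, arr, "warp", {})


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_all(
    seq: FixationSequence,
    layout: TextLayout,
    config: Optional[Dict[str, dict]] = None,
    seed: int = 0,
) -> Dict[str, CorrectionResult]:
    """Run all nine algorithms; returns a name -> result mapping.

    ``config`` maps algorithm names to keyword arguments (e.g.
    ``{"chain": {"params": ChainParams(100, 30)}}``).  The stochastic
    initializations of cluster and split derive from ``seed`` unless
    overridden.  An individual algorithm failure is recorded as a warning
    and the remaining algorithms proceed.
    """
    config = config or {}
    line_ys = layout.line_ys
    results: Dict[str, CorrectionResult] = {}
    runners = {
        "attach": lambda kw: attach(seq, line_ys, **kw),
        "chain": lambda kw: chain(seq, line_ys, **kw),
        "cluster": lambda kw: cluster(seq, line_ys, **{"seed": seed, **kw}),
        "merge": lambda kw: merge(seq, line_ys, **kw),
        "regress": lambda kw: regress(seq, line_ys, **kw),
        "segment": lambda kw: segment(seq, line_ys, **kw),
        "split": lambda kw: split(seq, line_ys, **{"seed": seed, **kw}),
        "stretch": lambda kw: stretch(seq, line_ys, **kw),
        "warp": lambda kw: warp(seq, layout, **kw),
    }
    for name in ALGORITHM_NAMES:
        try:
            results[name] = runners[name](dict(config.get(name, {})))
        except Exception as exc:  # noqa: BLE001 - isolate per-algorithm failures
            warnings.warn(f"correction algorithm {name!r} failed: {exc}", RuntimeWarning, stacklevel=2)
    return results
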