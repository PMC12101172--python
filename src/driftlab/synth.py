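"""Synthetic reading-trial generation with known ground truth.

The generator walks the word AOIs of a :class:`~driftlab.core.TextLayout`
in reading order and emits one fixation per visited word:

* the fixation lands near the word's optimal viewing position — one third
  of the word width from its left edge — and at the vertical center of
  its line, with small Gaussian jitter on both axes;
* the duration grows with word width: ``100 + (width / 15) * 40`` ms, so
  wider (longer) words receive proportionally longer fixations;
* short words may be skipped, with a skip probability that decays
  linearly in word length;
* at probabilistically chosen indexes the walk jumps back to an earlier
  word (a regression), either on a previous line (between-line) or on the
  same line (within-line), and re-reads forward from there.

Because every emitted fixation records the line of the word it was
generated from, trials carry exact ground-truth line labels, which is
what makes objective accuracy measurement of drift correction possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import AreaOfInterest, DistortionSpec, Fixation, FixationSequence, TextLayout
from . import distort as _distort

__all__ = [
    "GeneratorParams",
    "SyntheticTrial",
    "grid_layout",
    "base_fixation",
    "skip_probability",
    "apply_skipping",
    "select_regression_indexes",
    "generate_between_line",
    "generate_within_line",
    "default_magnitudes",
    "generate_suite",
    "SUITE_CONDITIONS",
    "LEVEL_NAMES",
]

LEVEL_NAMES = ("low", "medium", "high")
SUITE_CONDITIONS = ("noise", "slope", "shift", "offset", "within_regression", "between_regression")


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the synthetic reading-trial generator.

    regression_probability
        Per-eligible-index probability of a regression (indices > 2).
    jitter_sd_x, jitter_sd_y
        SD in pixels of the Gaussian landing-position jitter; small
        relative to the line spacing so undistorted trials are perfectly
        recoverable.
    skip_enabled, skip_base, skip_decay
        Word skipping: a word of c characters is skipped with probability
        ``clamp(skip_base - skip_decay * (c - 1), 0, skip_base)`` so short
        words are skipped more often.  The first word of a line is never
        skipped.
    est_char_width
        Pixels per character, used to estimate word length when an AOI
        carries no token text.
    max_regression_retries
        Bounded retries when drawing a regression target.
    seed
        Fixes the generated trial exactly.
    """

    regression_probability: float = 0.2
    jitter_sd_x: float = 2.0
    jitter_sd_y: float = 2.0
    skip_enabled: bool = True
    skip_base: float = 0.5
    skip_decay: float = 0.08
    est_char_width: float = 10.0
    max_regression_retries: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("regression_probability", "skip_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("jitter_sd_x", "jitter_sd_y", "skip_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.est_char_width <= 0:
            raise ValueError("est_char_width must be positive")


@dataclass
class SyntheticTrial:
    """A generated trial: fixations plus per-fixation ground-truth lines."""

    fixations: FixationSequence
    ground_truth_line: np.ndarray
    layout: TextLayout
    params: GeneratorParams
    distortions_applied: List[DistortionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ground_truth_line = np.asarray(self.ground_truth_line, int)
        if len(self.ground_truth_line) != len(self.fixations):
            raise ValueError("ground_truth_line must match the number of fixations")

    @property
    def trial_id(self) -> Optional[str]:
        return self.fixations.trial_id

    def with_distortion(self, spec: DistortionSpec) -> "SyntheticTrial":
        """Return a copy with the distortion applied; ground truth is kept."""
        distorted = _distort.apply_spec(self.fixations, spec, line_ys=self.layout.line_ys)
        return SyntheticTrial(
            fixations=distorted,
            ground_truth_line=self.ground_truth_line,
            layout=self.layout,
            params=self.params,
            distortions_applied=[*self.distortions_applied, spec],
        )


# ---------------------------------------------------------------------------
# stimulus construction
# ---------------------------------------------------------------------------


def grid_layout(
    n_lines: int = 3,
    words_per_line: int = 5,
    x0: float = 100.0,
    y0: float = 100.0,
    line_spacing: float = 50.0,
    word_height: float = 20.0,
    word_gap: float = 20.0,
    word_widths: Optional[Sequence[float]] = None,
    tokens: Optional[Sequence[Sequence[str]]] = None,
) -> TextLayout:
    """A rectangular multi-line stimulus of word AOIs.

    ``word_widths`` gives per-column widths (default 60 px each);
    ``tokens`` optionally labels each word (list of per-line lists).
    """
    if word_widths is None:
        word_widths = [60.0] * words_per_line
    if len(word_widths) != words_per_line:
        raise ValueError("word_widths must have one entry per word of a line")
    aois = []
    for li in range(n_lines):
        x = x0
        for wi in range(words_per_line):
            token = tokens[li][wi] if tokens is not None else None
            aois.append(
                AreaOfInterest(
                    x=x,
                    y=y0 + li * line_spacing,
                    width=float(word_widths[wi]),
                    height=word_height,
                    line=li,
                    token=token,
                )
            )
            x += word_widths[wi] + word_gap
    return TextLayout(aois)


# ---------------------------------------------------------------------------
# fixation placement
# ---------------------------------------------------------------------------


def base_fixation(
    aoi: AreaOfInterest, params: GeneratorParams, rng: np.random.Generator
) -> Tuple[Fixation, int]:
    """One fixation on a word: OVP landing position, width-scaled duration.

    x = aoi.x + width/3 + jitter, y = line vertical center + jitter,
    duration = 100 + (width / 15) * 40 ms.  Returns the fixation and the
    word's line index (the ground-truth label).
    """
    jx = rng.normal(0.0, params.jitter_sd_x) if params.jitter_sd_x > 0 else 0.0
    jy = rng.normal(0.0, params.jitter_sd_y) if params.jitter_sd_y > 0 else 0.0
    x = aoi.x + aoi.width / 3.0 + jx
    y = aoi.y + aoi.height / 2.0 + jy
    duration = 100.0 + (aoi.width / 15.0) * 40.0
    return Fixation(x, y, duration), aoi.line


def skip_probability(aoi: AreaOfInterest, params: GeneratorParams) -> float:
    """Skip probability of a word: linear decay in its character count."""
    if aoi.token is not None:
        n_chars = max(1, len(aoi.token))
    else:
        n_chars = max(1, round(aoi.width / params.est_char_width))
    p = params.skip_base - params.skip_decay * (n_chars - 1)
    return float(np.clip(p, 0.0, params.skip_base))


def apply_skipping(
    layout: TextLayout, params: GeneratorParams, rng: np.random.Generator
) -> List[AreaOfInterest]:
    """Drop skipped words from the reading walk.

    Each word is skipped independently with :func:`skip_probability`,
    except the first word of every line, which is always fixated so that
    no line is left empty.
    """
    walk: List[AreaOfInterest] = []
    seen_lines = set()
    for aoi in layout.aois:
        first_of_line = aoi.line not in seen_lines
        seen_lines.add(aoi.line)
        if not first_of_line and rng.random() < skip_probability(aoi, params):
            continue
        walk.append(aoi)
    return walk


# ---------------------------------------------------------------------------
# regression walks
# ---------------------------------------------------------------------------


def select_regression_indexes(
    n_aois: int, regression_probability: float, rng: np.random.Generator
) -> List[int]:
    """Choose walk indexes at which a regression will be attempted.

    Each index > 2 is included independently with the given probability;
    if none is selected and the probability is positive, one uniformly
    random eligible index is added so at least one regression is attempted.
    """
    eligible = list(range(3, n_aois))
    chosen = [i for i in eligible if rng.random() < regression_probability]
    if not chosen and regression_probability > 0 and eligible:
        chosen = [int(rng.choice(eligible))]
    return sorted(chosen)


def _pick_target(
    walk: Sequence[AreaOfInterest],
    index: int,
    same_line: bool,
    params: GeneratorParams,
    rng: np.random.Generator,
    force_valid: bool,
) -> Optional[int]:
    """Draw a prior walk index to regress to, or None if retries fail."""
    line = walk[index].line
    for _ in range(params.max_regression_retries):
        cand = int(rng.integers(0, index))
        if (walk[cand].line == line) == same_line:
            return cand
    if force_valid:
        valid = [j for j in range(index) if (walk[j].line == line) == same_line]
        if valid:
            return int(rng.choice(valid))
    return None


def _walk(
    walk: Sequence[AreaOfInterest],
    regression_indexes: Iterable[int],
    params: GeneratorParams,
    rng: np.random.Generator,
    same_line: bool,
    force_valid: bool = False,
) -> Tuple[List[Fixation], List[int], int]:
    """Reading walk with jump-back regressions; regression indexes fire once."""
    pending = set(regression_indexes)
    fixations: List[Fixation] = []
    lines: List[int] = []
    executed = 0
    index = 0
    while index < len(walk):
        fix, line = base_fixation(walk[index], params, rng)
        fixations.append(fix)
        lines.append(line)
        if index in pending:
            pending.discard(index)
            target = _pick_target(walk, index, same_line, params, rng, force_valid)
            if target is not None:
                executed += 1
                index = target
                continue
        index += 1
    return fixations, lines, executed


def _generate(
    layout: TextLayout,
    params: GeneratorParams,
    same_line: bool,
    trial_id: Optional[str],
) -> SyntheticTrial:
    rng = np.random.default_rng(params.seed)
    walk = apply_skipping(layout, params, rng) if params.skip_enabled else layout.aois
    indexes = select_regression_indexes(len(walk), params.regression_probability, rng)
    fixations, lines, executed = _walk(walk, indexes, params, rng, same_line)
    if executed == 0 and params.regression_probability > 0 and not same_line:
        # Guarantee a between-line regression whenever one is possible: re-walk
        # once with a forced regression at an index that has a valid prior.
        candidates = [
            i
            for i in range(3, len(walk))
            if any(walk[j].line != walk[i].line for j in range(i))
        ]
        if candidates:
            forced = int(rng.choice(candidates))
            fixations, lines, executed = _walk(
                walk, [forced], params, rng, same_line, force_valid=True
            )
    seq = FixationSequence(fixations, trial_id=trial_id)
    return SyntheticTrial(seq, np.asarray(lines, int), layout, params)


def generate_between_line(
    layout: TextLayout,
    params: Optional[GeneratorParams] = None,
    trial_id: Optional[str] = None,
) -> SyntheticTrial:
    """Generate a trial whose regressions jump to a previous line.

    With ``regression_probability`` > 0 the layout must have at least two
    lines, and the trial is guaranteed to contain at least one executed
    between-line regression whenever a valid target exists.
    """
    params = params or GeneratorParams()
    if params.regression_probability > 0 and layout.n_lines < 2:
        raise ValueError("between-line regressions need a layout with at least two lines")
    return _generate(layout, params, same_line=False, trial_id=trial_id)


def generate_within_line(
    layout: TextLayout,
    params: Optional[GeneratorParams] = None,
    trial_id: Optional[str] = None,
) -> SyntheticTrial:
    """Generate a trial whose regressions jump back within the same line.

    Identical to :func:`generate_between_line` except for the regression
    target rule; a regression index whose bounded retries find no
    same-line prior target is skipped and the walk continues.
    """
    params = params or GeneratorParams()
    return _generate(layout, params, same_line=True, trial_id=trial_id)


# ---------------------------------------------------------------------------
# the 18-trial suite
# ---------------------------------------------------------------------------


def default_magnitudes(layout: TextLayout) -> dict:
    """Low/medium/high distortion magnitudes, scaled to the layout.

    Stated as fractions of the line spacing L: the noise SD is
    {0.1, 0.25, 0.4} L; slope and shift factors are set so the maximum
    displacement (at the far horizontal edge / the last line) is
    {0.25, 0.5, 0.75} L; the constant offset is {0.3, 0.6, 0.9} L
    vertically with no horizontal component.
    """
    L = layout.line_spacing
    centers_x = layout.word_centers[:, 0]
    x_extent = float(centers_x.max() - centers_x.min())
    if x_extent <= 0:
        raise ValueError("layout has no horizontal extent")
    m = layout.n_lines
    return {
        "noise": [0.1 * L, 0.25 * L, 0.4 * L],
        "slope": [f * L * 100.0 / x_extent for f in (0.25, 0.5, 0.75)],
        "shift": [f * L / (m - 1) for f in (0.25, 0.5, 0.75)],
        "offset": [0.3 * L, 0.6 * L, 0.9 * L],
    }


def _child_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def _make_spec(kind: str, magnitude: float, seed: int) -> DistortionSpec:
    if kind == "noise":
        return DistortionSpec("noise", {"ynoise": magnitude}, seed=seed)
    if kind == "slope":
        return DistortionSpec("slope", {"slope_factor": magnitude})
    if kind == "shift":
        return DistortionSpec("shift", {"y_shift_factor": magnitude})
    if kind == "offset":
        return DistortionSpec("offset", {"x_offset": 0.0, "y_offset": magnitude})
    raise ValueError(f"unknown distortion kind {kind!r}")


def generate_suite(
    layout: TextLayout,
    magnitudes: Optional[dict] = None,
    seed: int = 0,
    params: Optional[GeneratorParams] = None,
    regression_levels: Sequence[float] = (0.1, 0.2, 0.3),
    conditions: Sequence[str] = SUITE_CONDITIONS,
) -> List[SyntheticTrial]:
    """The 6-condition x 3-level trial suite (18 trials by default).

    Four distortion conditions (noise, slope, shift, offset) at three
    magnitudes each, applied to regression-free base trials, plus
    within-line and between-line regression conditions at three
    regression probabilities, with no distortion.  Deterministic under
    ``seed``; every trial retains its ground-truth line labels.
    """
    params = params or GeneratorParams()
    magnitudes = magnitudes if magnitudes is not None else default_magnitudes(layout)
    unknown = set(conditions) - set(SUITE_CONDITIONS)
    if unknown:
        raise ValueError(f"unknown suite conditions: {sorted(unknown)}")
    seeds = iter(_child_seeds(seed, 2 * len(SUITE_CONDITIONS) * len(LEVEL_NAMES)))
    trials: List[SyntheticTrial] = []
    for kind in ("noise", "slope", "shift", "offset"):
        for level, magnitude in zip(LEVEL_NAMES, magnitudes[kind]):
            gen_seed, noise_seed = next(seeds), next(seeds)
            if kind not in conditions:
                continue
            base_params = replace(params, regression_probability=0.0, seed=gen_seed)
            trial = generate_between_line(layout, base_params, trial_id=f"{kind}-{level}")
            trials.append(trial.with_distortion(_make_spec(kind, magnitude, noise_seed)))
    generators: List[Tuple[str, Callable]] = [
        ("within_regression", generate_within_line),
        ("between_regression", generate_between_line),
    ]
    for condition, generator in generators:
        for level, prob in zip(LEVEL_NAMES, regression_levels):
            gen_seed, _ = next(seeds), next(seeds)
            if condition not in conditions:
                continue
            reg_params = replace(params, regression_probability=prob, seed=gen_seed)
            trials.append(generator(layout, reg_params, trial_id=f"{condition}-{level}"))
    return trials
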