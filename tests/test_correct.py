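import itertools

import numpy as np
import pytest

import driftlab as dl
from driftlab.correct import ALGORITHM_NAMES, dtw_path

from conftest import clean_params, random_sequence


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------


def naive_attach_lines(ys, line_ys):
    """O(n*m) linear-scan nearest line, first minimum wins."""
    return [int(np.argmin([abs(l - y) for l in line_ys])) for y in ys]


def naive_chain_lines(xs, ys, line_ys, x_thresh, y_thresh):
    chains, current = [], [0]
    for i in range(1, len(xs)):
        if abs(xs[i] - xs[i - 1]) > x_thresh or abs(ys[i] - ys[i - 1]) > y_thresh:
            chains.append(current)
            current = []
        current.append(i)
    chains.append(current)
    out = [None] * len(xs)
    for members in chains:
        mean_y = float(np.mean([ys[i] for i in members]))
        line = int(np.argmin([abs(l - mean_y) for l in line_ys]))
        for i in members:
            out[i] = line
    return out


def brute_force_dtw_cost(cost):
    """Minimum path cost over every monotone alignment, by enumeration."""
    n, m = cost.shape

    def walk(i, j):
        here = cost[i, j]
        if i == n - 1 and j == m - 1:
            return here
        options = []
        if i + 1 < n:
            options.append(walk(i + 1, j))
        if j + 1 < m:
            options.append(walk(i, j + 1))
        if i + 1 < n and j + 1 < m:
            options.append(walk(i + 1, j + 1))
        return here + min(options)

    return walk(0, 0)


def run_algorithm(name, seq, layout):
    if name == "warp":
        return getattr(dl, name)(seq, layout)
    return getattr(dl, name)(seq, layout.line_ys)


# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", ALGORITHM_NAMES)
def test_output_contract(name, big_layout):
    """All nine algorithms preserve length, order, x and duration, and emit
    y-values that are members of line_ys."""
    params = clean_params(regression_probability=0.2, jitter_sd_x=2, jitter_sd_y=2, seed=3)
    trial = dl.generate_between_line(big_layout, params)
    seq = dl.error_noise(trial.fixations, 8.0, seed=1)
    res = run_algorithm(name, seq, big_layout)
    assert res.algorithm == name
    assert len(res.corrected) == len(seq)
    assert np.array_equal(res.corrected.x, seq.x)
    assert np.array_equal(res.corrected.duration, seq.duration)
    assert np.all(np.isin(res.corrected.y, big_layout.line_ys))
    assert np.array_equal(big_layout.line_ys[res.line_assignment], res.corrected.y)


@pytest.mark.parametrize("name", ALGORITHM_NAMES)
def test_perfect_recovery_on_clean_trial(name, clean_trial, layout):
    res = run_algorithm(name, clean_trial.fixations, layout)
    assert dl.line_accuracy(res, clean_trial.ground_truth_line).accuracy == 1.0


class TestAttach:
    def test_on_line_input_unchanged(self):
        seq = dl.FixationSequence([(0, 50, 100), (10, 100, 100)])
        res = dl.attach(seq, [50, 100])
        assert res.corrected == seq
        assert res.line_assignment.tolist() == [0, 1]

    def test_recovers_sub_half_spacing_offsets(self, clean_trial, layout):
        L = layout.line_spacing
        for c in (-0.49 * L, -0.2 * L, 0.2 * L, 0.49 * L):
            shifted = dl.error_offset(clean_trial.fixations, 0, c)
            res = dl.attach(shifted, layout.line_ys)
            assert np.array_equal(res.line_assignment, clean_trial.ground_truth_line)

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            lines = np.sort(rng.choice(np.arange(0, 600, 7.0), rng.integers(2, 9), replace=False))
            seq = random_sequence(rng, y_range=(-50, 650))
            res = dl.attach(seq, lines)
            assert res.line_assignment.tolist() == naive_attach_lines(seq.y, lines)

    def test_idempotent(self, big_layout):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, n=30, y_range=(100, 300))
        once = dl.attach(seq, big_layout.line_ys)
        twice = dl.attach(once.corrected, big_layout.line_ys)
        assert once.corrected == twice.corrected


class TestChain:
    def test_large_y_step_splits_chains(self):
        seq = dl.FixationSequence([(0, 10, 100), (10, 60, 100)])
        res = dl.chain(seq, [10, 60], dl.ChainParams(x_thresh=192, y_thresh=32))
        assert res.corrected.y.tolist() == [10, 60]

    def test_chain_mean_snaps_members_together(self):
        seq = dl.FixationSequence([(0, 48, 100), (10, 52, 100)])
        res = dl.chain(seq, [10, 50])
        assert res.corrected.y.tolist() == [50, 50]

    def test_matches_naive_implementation(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            lines = np.sort(rng.choice(np.arange(0, 600, 11.0), rng.integers(2, 7), replace=False))
            seq = random_sequence(rng, y_range=(0, 600))
            params = dl.ChainParams(
                x_thresh=float(rng.uniform(20, 300)), y_thresh=float(rng.uniform(5, 80))
            )
            res = dl.chain(seq, lines, params)
            expected = naive_chain_lines(seq.x, seq.y, lines, params.x_thresh, params.y_thresh)
            assert res.line_assignment.tolist() == expected

    def test_idempotent(self, big_layout):
        rng = np.random.default_rng(4)
        seq = random_sequence(rng, n=30, y_range=(100, 300))
        once = dl.chain(seq, big_layout.line_ys)
        twice = dl.chain(once.corrected, big_layout.line_ys)
        assert once.corrected == twice.corrected


class TestCluster:
    def test_separated_clusters(self):
        seq = dl.FixationSequence([(0, 10, 1), (1, 11, 1), (2, 50, 1), (3, 51, 1)])
        res = dl.cluster(seq, [10, 50], seed=0)
        assert res.corrected.y.tolist() == [10, 10, 50, 50]

    def test_fewer_fixations_than_lines_rejected(self):
        seq = dl.FixationSequence([(0, 10, 1)])
        with pytest.raises(ValueError):
            dl.cluster(seq, [10, 50], seed=0)

    def test_seed_reproducibility_and_idempotence(self, big_layout):
        rng = np.random.default_rng(5)
        seq = random_sequence(rng, n=40, y_range=(100, 280))
        a = dl.cluster(seq, big_layout.line_ys, seed=1)
        b = dl.cluster(seq, big_layout.line_ys, seed=1)
        assert a.corrected == b.corrected
        again = dl.cluster(a.corrected, big_layout.line_ys, seed=1)
        assert again.corrected == a.corrected


class TestMerge:
    def test_single_line_input_maps_to_first_line(self):
        seq = dl.FixationSequence([(x, 12.0 + (x % 3), 100) for x in range(0, 200, 20)])
        res = dl.merge(seq, [10.0])
        assert np.all(res.corrected.y == 10.0)

    def test_output_on_lines(self, big_layout):
        rng = np.random.default_rng(6)
        seq = random_sequence(rng, n=35, y_range=(100, 280))
        res = dl.merge(seq, big_layout.line_ys)
        assert np.all(np.isin(res.corrected.y, big_layout.line_ys))


class TestRegress:
    def test_constant_offset_recovered(self, clean_trial, layout):
        L = layout.line_spacing
        for c in (-0.4 * L, 0.3 * L):
            shifted = dl.error_offset(clean_trial.fixations, 0, c)
            res = dl.regress(shifted, layout.line_ys)
            assert np.array_equal(res.line_assignment, clean_trial.ground_truth_line)

    def test_beats_attach_on_slope_distortion(self, big_layout):
        params = clean_params(seed=9)
        trial = dl.generate_between_line(big_layout, params, trial_id="slope")
        factor = 0.6 * big_layout.line_spacing * 100.0 / 400.0
        seq = dl.error_slope(trial.fixations, factor)
        acc_regress = dl.line_accuracy(dl.regress(seq, big_layout.line_ys), trial.ground_truth_line)
        acc_attach = dl.line_accuracy(dl.attach(seq, big_layout.line_ys), trial.ground_truth_line)
        assert acc_regress.accuracy >= acc_attach.accuracy

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            dl.RegressParams(slope_bounds=(0.1, -0.1))


class TestSegment:
    def test_single_line(self):
        seq = dl.FixationSequence([(x, 40, 100) for x in range(0, 100, 10)])
        res = dl.segment(seq, [50.0])
        assert np.all(res.corrected.y == 50.0)

    def test_return_sweep_break(self):
        # two lines read left to right with one long leftward sweep
        xs = [0, 50, 100, 150, 5, 55, 105, 155]
        seq = dl.FixationSequence([(x, 0, 100) for x in xs])
        res = dl.segment(seq, [100, 150])
        assert res.line_assignment.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_line_indices_non_decreasing(self, big_layout):
        rng = np.random.default_rng(8)
        seq = random_sequence(rng, n=30)
        res = dl.segment(seq, big_layout.line_ys)
        assert np.all(np.diff(res.line_assignment) >= 0)

    def test_largest_magnitude_convention(self):
        xs = [0, 500, 10, 20]  # the largest |dx| is the forward jump
        seq = dl.FixationSequence([(x, 0, 100) for x in xs])
        neg = dl.segment(seq, [10, 20], convention="most_negative")
        mag = dl.segment(seq, [10, 20], convention="largest")
        assert neg.line_assignment.tolist() == [0, 0, 1, 1]
        assert mag.line_assignment.tolist() == [0, 1, 1, 1]

    def test_too_few_fixations_rejected(self):
        seq = dl.FixationSequence([(0, 0, 100)])
        with pytest.raises(ValueError):
            dl.segment(seq, [10, 20])


class TestSplit:
    def test_sweep_boundary_found(self):
        xs = [0, 20, 40, 60, -340, -320, -300, -280]
        ys = [100, 100, 100, 100, 150, 150, 150, 150]
        seq = dl.FixationSequence([(x, y, 100) for x, y in zip(xs, ys)])
        res = dl.split(seq, [100, 150], seed=0)
        assert res.line_assignment.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_identical_displacements_rejected(self):
        seq = dl.FixationSequence([(0, 0, 100), (10, 0, 100), (20, 0, 100)])
        with pytest.raises(ValueError):
            dl.split(seq, [10], seed=0)

    def test_seed_reproducibility(self, big_layout):
        rng = np.random.default_rng(12)
        seq = random_sequence(rng, n=30, y_range=(100, 280))
        assert dl.split(seq, big_layout.line_ys, seed=2).corrected == dl.split(
            seq, big_layout.line_ys, seed=2
        ).corrected


class TestStretch:
    def test_on_line_input_has_zero_cost(self, clean_trial, layout):
        res = dl.stretch(clean_trial.fixations, layout.line_ys)
        assert res.params["fitted"]["cost"] == pytest.approx(0.0, abs=1e-6)
        assert res.corrected == clean_trial.fixations

    def test_offset_within_bounds_recovered(self, clean_trial, layout):
        L = layout.line_spacing
        for c in (-0.4 * L, 0.45 * L):
            shifted = dl.error_offset(clean_trial.fixations, 0, c)
            res = dl.stretch(shifted, layout.line_ys)
            assert np.array_equal(res.line_assignment, clean_trial.ground_truth_line)

    def test_no_worse_than_identity_transform(self, big_layout):
        rng = np.random.default_rng(13)
        seq = random_sequence(rng, n=25, y_range=(100, 280))
        res = dl.stretch(seq, big_layout.line_ys)
        arr = big_layout.line_ys
        identity_cost = float(np.abs(seq.y - arr[dl.nearest_lines(seq.y, arr)]).sum())
        assert res.params["fitted"]["cost"] <= identity_cost + 1e-9

    def test_idempotent(self, big_layout):
        rng = np.random.default_rng(14)
        seq = random_sequence(rng, n=25, y_range=(100, 280))
        once = dl.stretch(seq, big_layout.line_ys)
        twice = dl.stretch(once.corrected, big_layout.line_ys)
        assert once.corrected == twice.corrected

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            dl.StretchParams(scale_bounds=(1.1, 1.2))


class TestWarp:
    def test_single_fixation_single_word(self):
        layout = dl.TextLayout([dl.AreaOfInterest(0, 40, 60, 20, 0)])
        seq = dl.FixationSequence([(500, 500, 100)])
        res = dl.warp(seq, layout)
        assert res.corrected.y.tolist() == [50.0]

    def test_dtw_cost_matches_enumeration_small(self):
        rng = np.random.default_rng(15)
        for n, m in itertools.product(range(1, 5), range(1, 5)):
            cost = rng.uniform(0, 10, (n, m))
            _, total = dtw_path(cost)
            assert total == pytest.approx(brute_force_dtw_cost(cost))

    def test_path_is_monotone_and_complete(self):
        rng = np.random.default_rng(16)
        cost = rng.uniform(0, 5, (6, 4))
        path, _ = dtw_path(cost)
        assert path[0] == (0, 0) and path[-1] == (5, 3)
        steps = set(map(tuple, np.diff(np.array(path), axis=0)))
        assert steps <= {(1, 0), (0, 1), (1, 1)}


class TestRunAll:
    def test_returns_nine_results(self, big_layout):
        trial = dl.generate_between_line(big_layout, clean_params(seed=2))
        seq = dl.error_offset(trial.fixations, 0, 10)
        results = dl.run_all(seq, big_layout, seed=0)
        assert set(results) == set(ALGORITHM_NAMES)

    def test_deterministic_under_seed(self, big_layout):
        trial = dl.generate_between_line(big_layout, clean_params(seed=2))
        seq = dl.error_noise(trial.fixations, 10.0, seed=5)
        a = dl.run_all(seq, big_layout, seed=7)
        b = dl.run_all(seq, big_layout, seed=7)
        for name in ALGORITHM_NAMES:
            assert a[name].corrected == b[name].corrected

    def test_failure_is_isolated(self, big_layout):
        # two fixations: too few for cluster (m=4) and split, others proceed
        seq = dl.FixationSequence([(0, 110, 100), (30, 110, 100)])
        with pytest.warns(RuntimeWarning):
            results = dl.run_all(seq, big_layout, seed=0)
        assert "attach" in results
        assert "cluster" not in results
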