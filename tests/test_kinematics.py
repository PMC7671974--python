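import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from surgmotion.errors import ConfigurationError, DomainError
from surgmotion.io_jigsaws import KinematicStream
from surgmotion.kinematics import (
    compute_metrics,
    count_movements,
    find_signal_peaks,
    gaussian_kernel,
    interpoint_distances,
    path_length,
    smooth_gaussian,
    trajectory_export,
    trial_time,
)
from surgmotion.synthetic import SyntheticTrialSpec, generate_trial, minimum_jerk_displacement

finite_points = hnp.arrays(
    float, st.tuples(st.integers(2, 50), st.just(3)),
    elements=st.floats(-100, 100, allow_nan=False),
)


def brute_force_path_length(points):
    """Independent oracle: explicit pairwise-distance summation."""
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        total += math.sqrt(sum((bb - aa) ** 2 for aa, bb in zip(a, b)))
    return total


class TestInterpointDistances:
    def test_3_4_5_triangle(self):
        np.testing.assert_allclose(
            interpoint_distances([(0, 0, 0), (3, 4, 0)]), [5.0]
        )

    def test_identical_points(self):
        np.testing.assert_allclose(
            interpoint_distances([(1, 1, 1), (1, 1, 1)]), [0.0]
        )

    def test_unit_cube_diagonal(self):
        np.testing.assert_allclose(
            interpoint_distances([(0, 0, 0), (1, 1, 1)]), [math.sqrt(3)]
        )

    def test_single_point_empty(self):
        assert interpoint_distances([(1, 2, 3)]).size == 0

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            interpoint_distances([(0, 0, 0), (np.nan, 0, 0)])


class TestPathLength:
    def test_unit_square_walk(self):
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        assert path_length(pts) == pytest.approx(3.0)

    def test_single_point_zero(self):
        assert path_length([(5, 5, 5)]) == 0.0

    def test_minimum_jerk_equals_amplitude(self):
        # monotone path => PL equals net displacement
        t = np.linspace(0, 1.0, 1000)
        x = minimum_jerk_displacement(0.2, 1.0, t)
        pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        assert path_length(pts) == pytest.approx(0.2, abs=1e-9)
        assert path_length(pts) == pytest.approx(brute_force_path_length(pts), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(finite_points)
    def test_matches_brute_force_oracle(self, pts):
        assert path_length(pts) == pytest.approx(
            brute_force_path_length(pts), rel=1e-9, abs=1e-9
        )

    @settings(max_examples=30, deadline=None)
    @given(finite_points, st.integers(0, 2**32 - 1))
    def test_rigid_transform_invariance(self, pts, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3)
        moved = pts @ rot.T + shift
        pl = path_length(pts)
        assert path_length(moved) == pytest.approx(pl, rel=1e-9, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(finite_points, st.floats(0.01, 100))
    def test_linear_scaling(self, pts, c):
        assert path_length(np.asarray(pts) * c) == pytest.approx(
            c * path_length(pts), rel=1e-12, abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(finite_points)
    def test_at_least_endpoint_distance(self, pts):
        direct = float(np.linalg.norm(np.asarray(pts)[-1] - np.asarray(pts)[0]))
        assert path_length(pts) >= direct - 1e-9

    @settings(max_examples=30, deadline=None)
    @given(finite_points, finite_points)
    def test_additive_over_concatenation(self, a, b):
        b = np.asarray(b) - b[0] + a[-1]  # share an endpoint
        joined = np.vstack([a, b[1:]])
        assert path_length(joined) == pytest.approx(
            path_length(a) + path_length(b), rel=1e-9, abs=1e-9
        )


class TestTrialTime:
    @pytest.mark.parametrize("n,rate,expected", [
        (300, 30.0, 10.0), (0, 30.0, 0.0), (4110, 30.0, 137.0),
    ])
    def test_values(self, n, rate, expected):
        assert trial_time(n, rate) == expected

    def test_negative_count(self):
        with pytest.raises(DomainError):
            trial_time(-1, 30.0)

    def test_bad_rate(self):
        with pytest.raises(DomainError):
            trial_time(10, 0.0)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_additivity(self, n1, n2):
        assert trial_time(n1 + n2, 30.0) == pytest.approx(
            trial_time(n1, 30.0) + trial_time(n2, 30.0)
        )


class TestSmoothGaussian:
    def test_constant_preserved(self):
        sig = np.full(50, 3.7)
        for sigma in (0.5, 2.0, 10.0):
            np.testing.assert_allclose(smooth_gaussian(sig, sigma), sig, atol=1e-12)

    def test_impulse_mass_conserved(self):
        sig = np.zeros(101)
        sig[50] = 1.0
        assert smooth_gaussian(sig, 2.0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_linear_ramp_interior_unchanged(self):
        sig = np.arange(200, dtype=float)
        out = smooth_gaussian(sig, 3.0)
        radius = (gaussian_kernel(3.0).size - 1) // 2
        np.testing.assert_allclose(
            out[radius:-radius], sig[radius:-radius], atol=1e-9
        )

    def test_sigma_must_be_positive(self):
        with pytest.raises(DomainError):
            smooth_gaussian(np.ones(10), 0.0)

    def test_matches_scipy_oracle_interior(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=300)
        ours = smooth_gaussian(sig, 4.0)
        ref = gaussian_filter1d(sig, 4.0, truncate=4.0, mode="reflect")
        radius = (gaussian_kernel(4.0).size - 1) // 2
        # identical kernels; edge padding conventions differ only at edges
        np.testing.assert_allclose(ours[radius:-radius], ref[radius:-radius],
                                   atol=1e-10)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=40)
        sigma = 2.5
        kernel = gaussian_kernel(sigma)
        radius = (kernel.size - 1) // 2
        expected = np.empty_like(sig)
        for i in range(sig.size):
            acc = 0.0
            for k in range(-radius, radius + 1):
                j = i + k
                if j < 0:
                    j = -j - 1  # symmetric reflection
                elif j >= sig.size:
                    j = 2 * sig.size - j - 1
                acc += sig[j] * kernel[k + radius]
            expected[i] = acc
        np.testing.assert_allclose(smooth_gaussian(sig, sigma), expected, atol=1e-12)


def brute_force_peaks(signal, min_height, min_sep):
    """Oracle: scan strict local maxima, then greedy highest-first pruning."""
    cands = [
        i for i in range(1, len(signal) - 1)
        if signal[i] > signal[i - 1] and signal[i] > signal[i + 1]
        and signal[i] > min_height
    ]
    kept = []
    for i in sorted(cands, key=lambda i: (-signal[i], i)):
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    return sorted(kept)


class TestFindSignalPeaks:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10_000))
        sig = rng.normal(size=n)  # continuous => no ties, a.s.
        min_h = float(rng.uniform(-1, 1))
        min_sep = float(rng.integers(1, 20))
        got = find_signal_peaks(sig, min_h, min_sep).tolist()
        assert got == brute_force_peaks(sig, min_h, min_sep)

    def test_plateau_counted_once_at_first_index(self):
        sig = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.0])
        assert find_signal_peaks(sig, 0.5, 1).tolist() == [2]

    def test_equal_close_peaks_keep_earlier(self):
        sig = np.array([0.0, 5.0, 0.0, 5.0, 0.0])
        assert find_signal_peaks(sig, 1.0, 3).tolist() == [1]

    def test_close_peaks_keep_higher(self):
        sig = np.array([0.0, 4.0, 0.0, 5.0, 0.0])
        assert find_signal_peaks(sig, 1.0, 3).tolist() == [3]


class TestCountMovements:
    def test_static_trajectory_zero_movements(self):
        pts = np.ones((300, 3))
        assert count_movements(pts).count == 0

    def test_fewer_than_two_points(self):
        seg = count_movements(np.zeros((1, 3)))
        assert seg.count == 0
        assert seg.peak_indices.size == 0

    def test_five_noiseless_movements(self):
        spec = SyntheticTrialSpec(n_movements=5, amplitudes_m=0.1,
                                  noise_sd_m=0.0, seed=11)
        stream, _ = generate_trial(spec, hands=("master_left",))
        assert count_movements(stream.positions["master_left"]).count == 5

    def test_single_movement_with_noise(self):
        # noise sd = 1% of peak speed per sample interval
        peak_speed_m_per_interval = 1.875 * 0.1 / 1.0 / 30.0
        spec = SyntheticTrialSpec(
            n_movements=1, amplitudes_m=0.1, durations_s=1.0,
            noise_sd_m=0.01 * peak_speed_m_per_interval, seed=5,
        )
        stream, _ = generate_trial(spec, hands=("master_left",))
        assert count_movements(stream.positions["master_left"]).count == 1

    @pytest.mark.parametrize("k", [1, 2, 5, 10, 20])
    def test_noiseless_k_movements_exact(self, k):
        spec = SyntheticTrialSpec(n_movements=k, amplitudes_m=0.08,
                                  durations_s=0.8, pauses_s=0.7,
                                  noise_sd_m=0.0, seed=k)
        stream, _ = generate_trial(spec, hands=("master_left",))
        assert count_movements(stream.positions["master_left"]).count == k

    def test_peak_indices_strictly_increasing(self):
        spec = SyntheticTrialSpec(n_movements=8, noise_sd_m=0.001, seed=2)
        stream, _ = generate_trial(spec, hands=("master_left",))
        seg = count_movements(stream.positions["master_left"])
        assert np.all(np.diff(seg.peak_indices) > 0)
        assert seg.count == seg.peak_indices.size


class TestComputeMetrics:
    def test_static_stream(self):
        stream = KinematicStream(
            positions={"master_left": np.ones((300, 3)),
                       "master_right": np.ones((300, 3))},
            sample_rate_hz=30.0,
        )
        m = compute_metrics(stream)
        assert m.time_s == pytest.approx(10.0)
        for mm in m.per_manipulator.values():
            assert mm.path_length_m == 0.0
            assert mm.movements == 0

    def test_motion_only_on_left(self):
        spec = SyntheticTrialSpec(n_movements=3, noise_sd_m=0.0, seed=9)
        stream, _ = generate_trial(spec, hands=("master_left",))
        n = stream.n_samples
        stream.positions["master_right"] = np.zeros((n, 3))
        m = compute_metrics(stream)
        assert m.per_manipulator["master_right"].path_length_m == 0.0
        assert m.per_manipulator["master_left"].path_length_m > 0.0

    def test_unknown_manipulator(self, simple_stream):
        with pytest.raises(ConfigurationError):
            compute_metrics(simple_stream, manipulators=("slave_left",))

    def test_synthetic_trial_matches_ground_truth(self):
        spec = SyntheticTrialSpec(n_movements=6, amplitudes_m=0.1,
                                  noise_sd_m=0.0, seed=13)
        stream, truth = generate_trial(spec)
        m = compute_metrics(stream)
        for hand in ("master_left", "master_right"):
            assert m.per_manipulator[hand].movements == truth[hand].n_movements
            assert m.per_manipulator[hand].path_length_m == pytest.approx(
                truth[hand].path_length_m, rel=1e-6
            )
        assert m.time_s == truth["master_left"].time_s


class TestTrajectoryExport:
    def test_points_in_order(self):
        pts = np.arange(9, dtype=float).reshape(3, 3)
        stream = KinematicStream(positions={"master_left": pts.copy()})
        np.testing.assert_array_equal(trajectory_export(stream, "master_left"), pts)

    def test_path_length_consistent_with_metrics(self, simple_stream):
        exported = trajectory_export(simple_stream, "master_left")
        m = compute_metrics(simple_stream)
        assert path_length(exported) == pytest.approx(
            m.per_manipulator["master_left"].path_length_m
        )

    def test_empty_stream(self):
        stream = KinematicStream(positions={"master_left": np.empty((0, 3))})
        assert trajectory_export(stream, "master_left").shape == (0, 3)

    def test_unknown_manipulator(self, simple_stream):
        with pytest.raises(ConfigurationError):
            trajectory_export(simple_stream, "slave_right")

    def test_export_is_a_copy(self, simple_stream):
        out = trajectory_export(simple_stream, "master_left")
        out[0, 0] = 1e9
        assert simple_stream.positions["master_left"][0, 0] != 1e9


class TestNoiseMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_pl_at_least_noiseless(self, seed):
        base = SyntheticTrialSpec(n_movements=4, amplitudes_m=0.1,
                                  noise_sd_m=0.0, seed=seed)
        noisy = SyntheticTrialSpec(n_movements=4, amplitudes_m=0.1,
                                   noise_sd_m=0.002, seed=seed)
        s0, _ = generate_trial(base, hands=("master_left",))
        s1, _ = generate_trial(noisy, hands=("master_left",))
        assert (path_length(s1.positions["master_left"])
                >= path_length(s0.positions["master_left"]))
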