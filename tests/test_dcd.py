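import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcdmotion.dcd import (
    DCDConfig,
    average_velocities,
    dcd_histogram,
    directionality_probability,
    pool_angles,
    relative_angles,
    speed_distribution,
)
from dcdmotion.io import trackset_from_arrays

TAU = 1.5


def cfg(delta_steps=1, **kw):
    return DCDConfig(delta=delta_steps * TAU, **kw)


class TestAverageVelocities:
    def test_constant_velocity_single_step_window(self):
        pos = np.array([[0.0, 0.0], [0.15, 0.0], [0.30, 0.0]])
        traj = trackset_from_arrays([pos], TAU).trajectories[0]
        vel = average_velocities(traj, cfg(1))
        assert vel.vectors.shape == (2, 2)
        np.testing.assert_allclose(vel.vectors, [[0.1, 0.0], [0.1, 0.0]])

    def test_two_step_window_uses_endpoint_difference(self):
        pos = np.array([[0.0, 0.0], [0.15, 0.0], [0.30, 0.0]])
        traj = trackset_from_arrays([pos], TAU).trajectories[0]
        vel = average_velocities(traj, cfg(2))
        np.testing.assert_allclose(vel.vectors, [[0.1, 0.0]])

    def test_stationary_track_gives_zero_vectors(self, stationary_track):
        vel = average_velocities(stationary_track.trajectories[0], cfg(1))
        np.testing.assert_array_equal(vel.vectors, 0.0)

    def test_short_track_raises_with_minimum_length(self):
        pos = np.zeros((3, 2))
        traj = trackset_from_arrays([pos], TAU).trajectories[0]
        with pytest.raises(ValueError, match="minimum"):
            average_velocities(traj, cfg(3))


class TestRelativeAngles:
    @pytest.mark.parametrize(
        "v0,v1,expected",
        [((1, 0), (0, 1), np.pi / 2), ((1, 0), (2, 0), 0.0), ((1, 0), (-1, 0), np.pi)],
    )
    def test_known_geometries(self, v0, v1, expected):
        pos = np.vstack([[0, 0], np.array(v0), np.array(v0) + np.array(v1)]) * 1.0
        traj = trackset_from_arrays([pos], TAU).trajectories[0]
        ang = relative_angles(average_velocities(traj, cfg(1)), cfg(1))
        assert ang.valid_thetas[0] == pytest.approx(expected, abs=1e-12)

    def test_pure_reversal_gives_pi_everywhere(self, zigzag_track):
        traj = zigzag_track.trajectories[0]
        ang = relative_angles(average_velocities(traj, cfg(1)), cfg(1))
        np.testing.assert_allclose(ang.valid_thetas, np.pi)

    def test_zero_velocity_pairs_flagged_invalid(self):
        pos = np.array([[0, 0], [1, 0], [1, 0], [2, 0]], dtype=float)
        traj = trackset_from_arrays([pos], TAU).trajectories[0]
        ang = relative_angles(average_velocities(traj, cfg(1)), cfg(1))
        assert list(ang.valid_mask) == [False, False]
        assert len(ang.valid_thetas) == 0

    def test_all_invalid_warns_not_raises(self, stationary_track):
        vel = average_velocities(stationary_track.trajectories[0], cfg(1))
        with pytest.warns(UserWarning, match="empty"):
            ang = relative_angles(vel, cfg(1))
        assert len(ang.valid_thetas) == 0

    def test_brute_force_arctangent_oracle(self):
        """Dot-product angles match direct atan2 geometry on short tracks."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = rng.normal(size=(rng.integers(4, 13), 2))
            traj = trackset_from_arrays([pos], TAU).trajectories[0]
            ang = relative_angles(average_velocities(traj, cfg(1)), cfg(1))
            d = np.diff(pos, axis=0)
            heading = np.arctan2(d[:, 1], d[:, 0])
            turn = np.abs(
                np.angle(np.exp(1j * (heading[1:] - heading[:-1])))
            )
            np.testing.assert_allclose(ang.thetas, turn, atol=1e-9)


class TestHistogram:
    def test_all_zero_angles_concentrate_mass(self):
        h = dcd_histogram(np.zeros(1000), cfg(1))
        # unit mean density over 100 bins, all mass in bin 0 and its mirror
        assert h.rho[0] == pytest.approx(50.0)
        assert h.rho[-1] == pytest.approx(50.0)
        assert np.count_nonzero(h.rho) == 2

    def test_uniform_angles_give_flat_density(self):
        rng = np.random.default_rng(11)
        h = dcd_histogram(rng.uniform(0, np.pi, size=10**6), cfg(1))
        assert np.all(np.abs(h.rho - 1.0) < 0.02)

    @pytest.mark.parametrize("n,seed", [(10, 0), (1000, 1), (50000, 2)])
    def test_normalization_and_mirror_symmetry(self, n, seed):
        rng = np.random.default_rng(seed)
        h = dcd_histogram(rng.uniform(0, np.pi, size=n), cfg(1))
        assert h.integral() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_array_equal(h.rho, h.rho[::-1])
        assert np.all(h.rho >= 0)

    def test_zero_angles_rejected(self):
        with pytest.raises(ValueError):
            dcd_histogram(np.empty(0), cfg(1))

    def test_edge_angle_falls_into_higher_bin_and_pi_into_last(self):
        w = 2 * np.pi / 100
        h = dcd_histogram(np.array([w, np.pi]), cfg(1))
        assert h.rho[0] == 0.0
        assert h.rho[1] > 0  # angle exactly on the first edge
        assert h.rho[49] > 0  # theta = pi in last half-domain bin


class TestDirectionality:
    def test_straight_line_gives_one(self):
        est = directionality_probability(np.zeros(50), 0.1)
        assert est.probability == 1.0
        assert est.n_in == est.n_total == 50

    def test_reversal_gives_zero(self):
        est = directionality_probability(np.full(50, np.pi), 0.25)
        assert est.probability == 0.0

    def test_uniform_angles_follow_alpha_over_pi_law(self):
        rng = np.random.default_rng(3)
        thetas = rng.uniform(0, np.pi, size=10**5)
        est = directionality_probability(thetas, np.pi / 2)
        assert est.probability == pytest.approx(0.5, abs=0.01)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            directionality_probability(np.zeros(5), 0.0)
        with pytest.raises(ValueError):
            directionality_probability(np.zeros(5), 4.0)

    def test_monotone_in_alpha_and_exact_at_pi(self):
        rng = np.random.default_rng(9)
        thetas = rng.uniform(0, np.pi, size=2000)
        alphas = np.linspace(0.05, np.pi, 12)
        probs = [directionality_probability(thetas, a).probability for a in alphas]
        assert all(a <= b + 1e-15 for a, b in zip(probs, probs[1:]))
        assert probs[-1] == 1.0

    def test_count_estimate_matches_histogram_integral(self):
        rng = np.random.default_rng(13)
        thetas = np.abs(rng.normal(0.4, 0.5, size=20000))
        thetas = thetas[thetas <= np.pi]
        c = cfg(1)
        h = dcd_histogram(thetas, c)
        alpha = 0.25
        est = directionality_probability(thetas, alpha)
        w = 2 * np.pi / 100
        n_bins = int(np.round(alpha / w))
        # integral over [-alpha, alpha] = 2 * sum of first bins / (2 pi)
        integral = 2 * np.sum(h.rho[:n_bins]) * w / (2 * np.pi)
        one_bin_mass = np.max(h.rho) * w / np.pi
        assert abs(est.probability - integral) <= one_bin_mass


class TestInvariancesAndPooling:
    def test_rotation_leaves_angles_and_probability_unchanged(self, diffusive_tracks):
        c = cfg(2)
        th = pool_angles(diffusive_tracks, c)
        rot = np.array(
            [[np.cos(0.7), -np.sin(0.7)], [np.sin(0.7), np.cos(0.7)]]
        )
        rotated = trackset_from_arrays(
            [t.positions @ rot.T for t in diffusive_tracks], TAU
        )
        th_rot = pool_angles(rotated, c)
        np.testing.assert_allclose(np.sort(th), np.sort(th_rot), atol=1e-9)

    def test_rescaling_preserves_angles_scales_speeds(self, diffusive_tracks):
        c = cfg(1)
        th = pool_angles(diffusive_tracks, c)
        scaled = trackset_from_arrays(
            [3.0 * t.positions for t in diffusive_tracks], TAU
        )
        np.testing.assert_allclose(pool_angles(scaled, c), th, atol=1e-9)
        sp = speed_distribution(diffusive_tracks, c)
        sp_scaled = speed_distribution(scaled, c)
        assert sp_scaled.mean == pytest.approx(3.0 * sp.mean)

    def test_pooling_skips_too_short_tracks(self):
        long = np.cumsum(np.ones((30, 2)) * 0.1, axis=0)
        short = np.cumsum(np.ones((5, 2)) * 0.1, axis=0)
        ts = trackset_from_arrays([long, short], TAU)
        th = pool_angles(ts, cfg(10))
        # only the long track can contribute: 30 - 10 - 1 angles
        assert len(th) == 19

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_histogram_mass_is_one_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        thetas = rng.uniform(0, np.pi, size=rng.integers(1, 500))
        h = dcd_histogram(thetas, cfg(1))
        assert h.integral() == pytest.approx(1.0, abs=1e-9)


class TestSpeedDistribution:
    def test_constant_speed(self, straight_track):
        sp = speed_distribution(straight_track, cfg(1))
        assert sp.mean == pytest.approx(0.05 / TAU)
        assert sp.sd == pytest.approx(0.0, abs=1e-15)

    def test_two_populations_pool_to_arithmetic_mean(self):
        a = np.column_stack([0.15 * np.arange(11), np.zeros(11)])  # 0.1 um/s
        b = np.column_stack([0.45 * np.arange(11), np.zeros(11)])  # 0.3 um/s
        ts = trackset_from_arrays([a, b], TAU)
        sp = speed_distribution(ts, cfg(1))
        assert sp.mean == pytest.approx(0.2)

    def test_mean_matches_brute_force_resummation(self, diffusive_tracks):
        c = cfg(3)
        sp = speed_distribution(diffusive_tracks, c)
        pooled = []
        for t in diffusive_tracks:
            for k in range(len(t) - 3):
                d = t.positions[k + 3] - t.positions[k]
                pooled.append(np.hypot(*d) / (3 * TAU))
        assert sp.mean == pytest.approx(np.mean(pooled), abs=1e-12)
        assert sp.sd > 0
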