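"""Head-direction samplers, ring attractor, spiking HD network, reset."""

import numpy as np
import pytest

from ringsampler import hd, scn
from ringsampler.experiments import hd_default_readout
from ringsampler.hd import (
    HDConfig,
    Landmark,
    angle_error,
    build_hd_network,
    decode_angle,
    decode_series,
    encode_velocity,
    hd_step_1d,
    hd_step_2d,
    multimodal_compose,
    reset_update,
    run_hd_map,
    stable_radius,
    wrap_angle,
)


@pytest.fixture
def config():
    return HDConfig()


class TestConfig:
    def test_alpha_exceeds_one(self, config):
        assert config.alpha == pytest.approx(1.0 + config.dt * config.beta @ config.beta)
        assert config.alpha >= 1.0

    def test_rejects_bad_mode_and_gain(self):
        with pytest.raises(ValueError):
            HDConfig(attractor_mode="soft")
        with pytest.raises(ValueError):
            HDConfig(attractor_gain=0.0)

    def test_stable_radius_by_mode(self):
        assert stable_radius(HDConfig(rho=2.0)) == pytest.approx(2 * np.sqrt(2))
        assert stable_radius(HDConfig(rho=2.0, attractor_mode="exact")) == pytest.approx(2.0)


class TestWrap:
    def test_wrap_into_interval(self):
        assert wrap_angle(np.pi + 0.1) == pytest.approx(-np.pi + 0.1)
        assert wrap_angle(-np.pi - 0.1) == pytest.approx(np.pi - 0.1)

    def test_shortest_arc_error(self):
        assert angle_error(np.pi - 0.01, -np.pi + 0.01) == pytest.approx(0.02)


class TestStep1D:
    def test_balanced_count_is_fixed_point(self, config):
        theta = hd_step_1d(0.3, np.ones(2), config)
        assert theta == pytest.approx(0.3)

    def test_update_matches_formula(self):
        cfg = HDConfig(beta=np.array([1.0]), dt=0.01)
        theta = hd_step_1d(0.0, np.array([2]), cfg)
        assert theta == pytest.approx(0.01 / cfg.alpha)

    def test_positive_update_wraps_at_pi(self):
        cfg = HDConfig(beta=np.array([1.0]), dt=0.01)
        theta = hd_step_1d(np.pi - 1e-4, np.array([2]), cfg)
        assert theta < 0  # wrapped to near -pi

    def test_noise_scale(self):
        cfg = HDConfig(beta=np.array([1.0]), dt=0.01)
        theta = hd_step_1d(0.0, np.array([1]), cfg, noise_increment=1.0)
        assert theta == pytest.approx(np.sqrt(2 * cfg.dt) / cfg.alpha)


class TestStep2D:
    def test_on_ring_balanced_is_fixed_point(self, config):
        xy = np.array([stable_radius(config), 0.0])
        out = hd_step_2d(xy, np.ones(2), config)
        assert np.allclose(out, xy, atol=1e-12)

    def test_radial_map_matches_closed_form(self, config):
        """One noise-free step: s changes by -2 gamma dt s (s - 2 rho^2)/alpha."""
        xy = np.array([0.6, 0.8])  # radius 1 < sqrt(2) rho
        out = hd_step_2d(xy, np.ones(2), config)
        s = xy @ xy
        expected_ds = -2 * config.attractor_gain * config.dt * s * (s - 2 * config.rho**2) / config.alpha
        assert out @ out - s == pytest.approx(expected_ds, rel=1e-3)
        assert out @ out > s  # pulled outward toward the ring

    def test_rotation_advances_angle_and_preserves_radius(self, config):
        k = 3
        xy = np.array([stable_radius(config), 0.0])
        m = 200
        for _ in range(m):
            xy = hd_step_2d(xy, np.array([1 + k, 1]), config)
        beta = config.beta[0]
        expected = m * config.dt * beta * k / config.alpha
        theta, radius = decode_angle(xy)
        assert theta == pytest.approx(expected, rel=0.02)
        assert radius == pytest.approx(stable_radius(config), rel=0.01)

    def test_divergence_guard(self, config):
        with pytest.raises(FloatingPointError):
            hd_step_2d(np.array([140.0, 0.0]), np.ones(2), config)

    def test_exact_mode_fixed_point_at_rho(self):
        config = HDConfig(attractor_mode="exact")
        xy = np.array([config.rho, 0.0])
        out = hd_step_2d(xy, np.ones(2), config)
        assert np.allclose(out, xy, atol=1e-12)


class TestRadiusConvergence:
    @pytest.mark.parametrize("start", [0.5, 2.0])
    def test_literal_mode_converges_to_sqrt2_rho(self, config, start):
        counts = np.ones((int(60.0 / config.dt), 2), dtype=int)
        xy0 = np.array([start * stable_radius(config), 0.0])
        xy = run_hd_map(config, counts, rng=0, xy0=xy0, noise_on=False)
        assert np.hypot(*xy[-1]) == pytest.approx(stable_radius(config), rel=0.02)


class TestDecode:
    @pytest.mark.parametrize(
        "z,expected",
        [((1, 0), 0.0), ((0, 1), np.pi / 2), ((-1, -1), -3 * np.pi / 4)],
    )
    def test_angles(self, z, expected):
        theta, radius = decode_angle(np.array(z, dtype=float))
        assert theta == pytest.approx(expected)
        assert radius == pytest.approx(np.linalg.norm(z))

    def test_zero_readout_flagged(self):
        theta, radius = decode_angle(np.zeros(2))
        assert np.isnan(theta) and radius == 0.0

    def test_decode_from_filtered_trains(self, config):
        d = hd_default_readout(config)
        r = np.zeros(d.n)
        r[2] = 1.0
        theta, _ = decode_angle(r, d)
        assert theta == pytest.approx(2 * 2 * np.pi / 8)


class TestEncoder:
    def test_mean_count_one_at_rest(self, config):
        counts = encode_velocity(np.zeros(200000), config, rng=0)
        assert counts.mean() == pytest.approx(1.0, rel=0.01)

    def test_mean_counts_follow_kernel(self, config):
        omega = 4.0
        counts = encode_velocity(np.full(200000, omega), config, rng=1)
        expected = np.exp(config.beta * omega * config.dt)
        assert np.allclose(counts.mean(axis=0), expected, rtol=0.02)

    def test_deterministic_under_seed(self, config):
        a = encode_velocity(np.ones(100), config, rng=3)
        b = encode_velocity(np.ones(100), config, rng=3)
        assert np.array_equal(a, b)


class TestReset:
    @pytest.fixture
    def lm_config(self):
        return HDConfig(landmark=Landmark())

    def test_silent_and_distant_is_negligible(self, lm_config):
        r = stable_radius(lm_config)
        xy = np.array([-r, 0.0])  # opposite the landmark
        term = reset_update(xy, 0.0, lm_config)
        assert np.linalg.norm(term) < 1e-3 * lm_config.dt / 1e-4

    def test_zero_prefactor_at_landmark(self, lm_config):
        r = stable_radius(lm_config)
        term = reset_update(np.array([r, 0.0]), 5.0, lm_config)
        assert np.allclose(term, 0.0)

    def test_requires_landmark(self, config):
        with pytest.raises(ValueError, match="landmark"):
            reset_update(np.array([1.0, 0.0]), 1.0, config)

    def test_strong_reset_pulls_angle_to_landmark(self, lm_config):
        """Bump displaced by pi/2 is pulled monotonically toward angle 0."""
        r = stable_radius(lm_config)
        xy = r * np.array([np.cos(np.pi / 2), np.sin(np.pi / 2)])
        errors = []
        for _ in range(20000):
            xy = hd_step_2d(xy, np.ones(2), lm_config, sigma_reset=1.0)
            errors.append(angle_error(decode_angle(xy)[0], 0.0))
        errors = np.array(errors)
        coarse = errors[::2000]
        assert np.all(np.diff(coarse) < 0)
        assert errors[-1] < 0.1


class TestMultimodal:
    def test_single_term_identity(self):
        term = np.array([0.1, -0.2])
        assert np.array_equal(multimodal_compose(term), term)

    def test_identical_populations_double(self):
        term = np.array([0.1, -0.2])
        assert np.allclose(multimodal_compose(term, term), 2 * term)

    def test_velocity_plus_reset_matches_combined_step(self):
        """Composing the reset term reproduces the full update exactly."""
        config = HDConfig(landmark=Landmark())
        xy = np.array([0.3, 1.2])
        sigma = np.array([2, 0])
        combined = hd_step_2d(xy, sigma, config, sigma_reset=3.0)
        separate = hd_step_2d(xy, sigma, config) + multimodal_compose(
            reset_update(xy, 3.0, config)
        )
        assert np.allclose(combined, separate, atol=1e-14)

    def test_empty_compose_rejected(self):
        with pytest.raises(ValueError):
            multimodal_compose()


class TestSpikingNetwork:
    def test_requires_two_dimensional_readout(self, config):
        params = scn.SCNParams(lambda_leak=10.0, dt=1e-4)
        with pytest.raises(ValueError, match="2-D"):
            build_hd_network(
                config, scn.ring_readout(8, radius_param=1.0, m=1),
                params, np.ones((10, 2), dtype=int),
            )

    def test_noise_free_holds_ring_radius_and_angle(self, config):
        """sigma == 1, no noise: decoded angle constant, radius near sqrt(2) rho."""
        d = hd_default_readout(config)
        counts = np.ones((int(5.0 / config.dt), 2), dtype=int)
        params = scn.SCNParams(lambda_leak=10.0, dt=1e-4)
        net = build_hd_network(config, d, params, counts, noise_on=False)
        z0 = stable_radius(config) * np.array([np.cos(0.7), np.sin(0.7)])
        res = net.run(5.0, rng=0, z0=z0)
        theta, radius = decode_series(res.z)
        assert radius[10000:].mean() == pytest.approx(stable_radius(config), rel=0.1)
        assert np.max(angle_error(theta[10000:], 0.7)) < 0.2

    def test_network_tracks_low_dimensional_map(self, config):
        """Driven by the same spike record, net and map decode similar paths."""
        rng = np.random.default_rng(5)
        duration = 5.0
        omega = 2.0
        counts = encode_velocity(np.full(int(duration / config.dt), omega), config, rng)
        xy = run_hd_map(config, counts, rng=1, noise_on=False)
        theta_map, _ = decode_series(xy)
        d = hd_default_readout(config)
        params = scn.SCNParams(lambda_leak=10.0, dt=1e-4)
        net = build_hd_network(config, d, params, counts, noise_on=False)
        res = net.run(duration, rng=2, z0=np.array([stable_radius(config), 0.0]))
        theta_net, _ = decode_series(res.z)
        err = angle_error(theta_net[5000:], theta_map[5000:])
        assert err.mean() < 0.15

    def test_localized_bump_rotates_with_heading(self, config):
        """Population activity peaks at the decoded angle and moves with it."""
        rng = np.random.default_rng(8)
        duration = 6.0
        omega = 2.0
        counts = encode_velocity(np.full(int(duration / config.dt), omega), config, rng)
        d = hd_default_readout(config)
        params = scn.SCNParams(lambda_leak=10.0, dt=1e-4)
        net = build_hd_network(config, d, params, counts)
        res = net.run(duration, rng=rng, z0=np.array([stable_radius(config), 0.0]),
                      record_r=True)
        theta, _ = decode_series(res.z)
        angles = np.arctan2(d.entries[1], d.entries[0])
        peak_angles = angles[np.argmax(res.r, axis=1)]
        err = angle_error(peak_angles[10000::100], theta[10000::100])
        assert np.median(err) <= 2 * np.pi / 8  # peak neuron within one ring slot
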