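"""Sensory populations: kernels, count emission, posterior gradients."""

import numpy as np
import pytest

from ringsampler import scn
from ringsampler.sensory import (
    SensoryPopulation,
    SpikeRecord,
    build_inference_network,
    emit_spikes,
    firing_rate,
    log_likelihood,
    moment_filter,
    posterior_grad,
    posterior_quadrature,
)


class TestFiringRate:
    def test_exponential_at_origin(self):
        pop = SensoryPopulation(beta=np.array([1.0]), kernel="exponential")
        assert firing_rate(pop, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_linear_kernel(self):
        pop = SensoryPopulation(beta=np.array([2.0]), kernel="linear", r0=1.0)
        assert firing_rate(pop, np.array([0.5]))[0] == pytest.approx(2.0)

    def test_logistic_at_origin(self):
        pop = SensoryPopulation(beta=np.array([3.7]), kernel="logistic")
        assert firing_rate(pop, np.array([0.0]))[0] == pytest.approx(0.5)

    def test_linear_rate_floored(self):
        pop = SensoryPopulation(beta=np.array([1.0]), kernel="linear", r0=0.0)
        assert firing_rate(pop, np.array([-5.0]))[0] == pytest.approx(1e-6)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            SensoryPopulation(beta=np.array([1.0]), kernel="cubic")

    def test_non_finite_stimulus_rejected(self):
        pop = SensoryPopulation(beta=np.array([1.0]))
        with pytest.raises(ValueError):
            firing_rate(pop, np.array([np.nan]))


class TestEmitSpikes:
    def test_zero_rate_gives_empty_record(self):
        pop = SensoryPopulation(beta=np.array([0.0]), kernel="linear", r0=0.0)
        rec = emit_spikes(pop, np.zeros(2000), dt=1e-3, seed=0)
        assert rec.counts.sum() == 0

    def test_poisson_mean_count(self):
        pop = SensoryPopulation(beta=np.array([0.0]), kernel="linear", r0=100.0)
        rec = emit_spikes(pop, np.zeros(100000), dt=1e-3, seed=1)
        assert rec.counts.mean() == pytest.approx(0.1, rel=0.02)

    def test_bernoulli_frequency(self):
        pop = SensoryPopulation(
            beta=np.array([1.0]), kernel="logistic", noise_family="bernoulli"
        )
        rec = emit_spikes(pop, np.zeros(100000), dt=1e-3, seed=2)
        assert set(np.unique(rec.counts)) <= {0, 1}
        assert rec.counts.mean() == pytest.approx(0.5, rel=0.02)

    def test_binomial_requires_n_trials(self):
        with pytest.raises(ValueError, match="n_trials"):
            SensoryPopulation(
                beta=np.array([1.0]), kernel="logistic", noise_family="binomial"
            )

    def test_binomial_counts_bounded(self):
        pop = SensoryPopulation(
            beta=np.array([1.0]), kernel="logistic", noise_family="binomial", n_trials=4
        )
        rec = emit_spikes(pop, np.zeros(5000), dt=1e-3, seed=3)
        assert rec.counts.max() <= 4 and rec.counts.min() >= 0

    def test_reproducible_under_seed(self):
        pop = SensoryPopulation(beta=np.array([1.0, -0.5]), kernel="exponential")
        a = emit_spikes(pop, np.linspace(0, 1, 100), dt=1e-2, seed=11)
        b = emit_spikes(pop, np.linspace(0, 1, 100), dt=1e-2, seed=11)
        assert np.array_equal(a.counts, b.counts)


class TestPosteriorGrad:
    def test_exponential_single_neuron_balanced(self):
        pop = SensoryPopulation(beta=np.array([1.0]), kernel="exponential")
        g = posterior_grad(pop, np.array([0.0]), np.array([1]))
        assert g[0] == pytest.approx(0.0)

    def test_exponential_single_neuron_silent(self):
        pop = SensoryPopulation(beta=np.array([1.0]), kernel="exponential")
        g = posterior_grad(pop, np.array([0.0]), np.array([0]))
        assert g[0] == pytest.approx(1.0)

    def test_linear_truncation_converges_to_exact(self, rng):
        pop = SensoryPopulation(
            beta=np.array([0.5, -0.3, 0.8]), kernel="linear", r0=4.0, taylor_order=12
        )
        counts = np.array([2, 1, 0])
        for _ in range(20):
            z = rng.uniform(-1.0, 1.0, size=1)  # inside |A z / r0| < 1
            approx = posterior_grad(pop, z, counts, exact=False)
            exact = posterior_grad(pop, z, counts, exact=True)
            assert np.allclose(approx, exact, atol=1e-4)

    def test_logistic_truncation_matches_exact_near_origin(self):
        pop = SensoryPopulation(
            beta=np.array([1.2]), kernel="logistic", taylor_order=6
        )
        counts = np.array([2])
        for z in np.linspace(-0.4, 0.4, 9):
            approx = posterior_grad(pop, np.array([z]), counts, exact=False)
            exact = posterior_grad(pop, np.array([z]), counts, exact=True)
            assert np.allclose(approx, exact, atol=1e-3)

    @pytest.mark.parametrize(
        "kernel,family,extra",
        [
            ("exponential", "poisson", {}),
            ("linear", "poisson", {"r0": 5.0}),
            ("logistic", "poisson", {}),
            ("logistic", "bernoulli", {}),
            ("logistic", "binomial", {"n_trials": 5}),
            ("logistic", "geometric", {}),
        ],
    )
    def test_gradient_matches_log_likelihood_finite_differences(
        self, rng, kernel, family, extra
    ):
        """Exact gradients agree with central differences of log P(sigma|z)."""
        beta = rng.normal(size=(4, 2)) * 0.8
        pop = SensoryPopulation(beta=beta, kernel=kernel, noise_family=family, **extra)
        if family == "poisson":
            counts = rng.poisson(1.0, size=4)
        elif family == "bernoulli":
            counts = rng.integers(0, 2, size=4)
        elif family == "binomial":
            counts = rng.integers(0, 6, size=4)
        else:
            counts = rng.integers(0, 4, size=4)
        eps = 1e-6
        for _ in range(25):
            z = rng.uniform(-0.8, 0.8, size=2)
            g = posterior_grad(pop, z, counts, exact=True)
            fd = np.empty(2)
            for k in range(2):
                zp, zm = z.copy(), z.copy()
                zp[k] += eps
                zm[k] -= eps
                fd[k] = -(log_likelihood(pop, zp, counts) - log_likelihood(pop, zm, counts)) / (2 * eps)
            assert np.allclose(g, fd, atol=1e-5)

    def test_counts_length_checked(self):
        pop = SensoryPopulation(beta=np.array([1.0, 2.0]), kernel="exponential")
        with pytest.raises(ValueError):
            posterior_grad(pop, np.array([0.0]), np.array([1]))


class TestPosteriorQuadrature:
    def test_single_neuron_mode_at_log_counts(self):
        pop = SensoryPopulation(beta=np.array([1.0]), kernel="exponential")
        table = posterior_quadrature(pop, np.array([5]), np.linspace(-2, 4, 4001))
        mode = table.grid[np.argmax(table.pdf)]
        assert mode == pytest.approx(np.log(5.0), abs=0.01)

    def test_identical_neurons_factorize(self):
        """Two identical neurons == one likelihood with summed statistics."""
        pop2 = SensoryPopulation(beta=np.array([1.0, 1.0]), kernel="exponential")
        grid = np.linspace(-2, 3, 2001)
        table2 = posterior_quadrature(pop2, np.array([2, 3]), grid)
        logp = -2.0 * np.exp(grid) + 5.0 * grid
        ref = np.exp(logp - logp.max())
        ref = ref / np.trapezoid(ref, grid)
        assert np.allclose(table2.pdf, ref, atol=1e-8)

    def test_population_posterior_normalized(self, rng):
        beta = rng.normal(size=10)
        pop = SensoryPopulation(beta=beta, kernel="exponential")
        counts = rng.poisson(1.5, size=10)
        table = posterior_quadrature(pop, counts, np.linspace(-3, 3, 2001))
        assert np.trapezoid(table.pdf, table.grid) == pytest.approx(1.0, abs=1e-6)
        m = table.moments()
        assert np.isfinite([m["mean"], m["var"], m["skew"]]).all()

    def test_poisson_posterior_skew_flips_with_velocity_sign(self):
        """Exponential-kernel Poisson posteriors are skewed; the skew flips
        (antisymmetrically) when the encoded velocity changes sign."""
        pop = SensoryPopulation(beta=np.array([2.0, -2.0]), kernel="exponential")
        grid = np.linspace(-4, 4, 4001)
        skews = {}
        for omega in (0.5, -0.5):
            counts = np.round(firing_rate(pop, np.array([omega]))).astype(int)
            skews[omega] = posterior_quadrature(pop, counts, grid).moments()["skew"]
        assert abs(skews[0.5]) > 0.005
        assert skews[0.5] * skews[-0.5] < 0
        assert skews[0.5] == pytest.approx(-skews[-0.5], rel=1e-6)


class TestInferenceNetwork:
    def test_zero_counts_push_readout_negative(self):
        """Silent exponential-kernel inputs mean 'low stimulus'."""
        pop = SensoryPopulation(beta=np.array([1.0, 0.7]), kernel="exponential")
        params = scn.SCNParams(lambda_leak=10.0, dt=1e-4, tau_s=0.05)
        record = SpikeRecord(counts=np.zeros((20000, 2), dtype=int), dt=1e-4)
        net = build_inference_network(
            pop, scn.ring_readout(10, radius_param=0.5, m=1), params, record
        )
        net.noise_amp = 0.0
        res = net.run(2.0, rng=0, z0=np.array([0.0]))
        assert res.z[-100:, 0].mean() < -0.5

    def test_record_dt_must_be_multiple_of_network_dt(self):
        pop = SensoryPopulation(beta=np.array([1.0]), kernel="exponential")
        params = scn.SCNParams(lambda_leak=10.0, dt=1e-4)
        record = SpikeRecord(counts=np.zeros((10, 1), dtype=int), dt=2.5e-5)
        with pytest.raises(ValueError, match="multiple"):
            build_inference_network(
                pop, scn.ring_readout(4, radius_param=0.5, m=1), params, record
            )


class TestMomentFilter:
    def test_constant_stream(self):
        out = moment_filter(np.full(200, 3.0), window=0.05, dt=1e-3)
        assert out["mean"].iloc[-1] == pytest.approx(3.0)
        assert out["var"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_stream(self):
        samples = np.tile([1.0, -1.0], 500)
        out = moment_filter(samples, window=0.1, dt=1e-3)
        assert out["mean"].iloc[-1] == pytest.approx(0.0, abs=0.02)
        assert out["var"].iloc[-1] == pytest.approx(1.0, rel=0.02)

    def test_tracks_known_gaussian_moments(self, gaussian_energy):
        from ringsampler.langevin import langevin_oracle

        path = langevin_oracle(gaussian_energy, tau_s=0.05, dt=1e-3, duration=120.0, seed=6)
        out = moment_filter(path[:, 0], window=30.0, dt=1e-3)
        assert out["mean"].iloc[-1] == pytest.approx(0.0, abs=0.15)
        assert out["var"].iloc[-1] == pytest.approx(1.0, rel=0.2)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            moment_filter(np.zeros(10), window=5e-4, dt=1e-3)
        with pytest.raises(ValueError):
            moment_filter(np.zeros(10), window=5e-3, dt=1e-3)


class TestSpikeRecordIO:
    def test_roundtrip(self, tmp_path, rng):
        counts = rng.poisson(0.3, size=(50, 3))
        rec = SpikeRecord(counts=counts, dt=1e-3)
        rec.save(tmp_path / "spikes.csv", meta={"seed": 1})
        back = SpikeRecord.load(tmp_path / "spikes.csv")
        assert np.array_equal(back.counts, counts)
        assert back.dt == 1e-3

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SpikeRecord(counts=np.array([[-1]]), dt=1e-3)
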