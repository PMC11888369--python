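"""Noisy sensory populations and sampling-based posterior inference.

A population of input neurons encodes a stimulus z through a firing-rate
kernel phi_i(z) and a count-noise family (Poisson, Bernoulli, binomial, or
geometric).  Under a flat prior, the posterior over z given observed counts
sigma is P(z | sigma) ~ exp(-U(z)) with U the negative log-likelihood, and
its gradient

    grad U(z) = sum_i grad phi_i(z) * (1 - sigma_i / phi_i(z))        (Poisson)

drives a Langevin sampler.  For the linear and logistic kernels the gradient
is also available as the truncated power-series expansion (order K) that a
multiplicative spiking network can implement with polynomial interactions;
the exact form is kept for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .langevin import DensityTable
from .scn import Network, SCNParams

__all__ = [
    "SensoryPopulation",
    "SpikeRecord",
    "firing_rate",
    "emit_spikes",
    "posterior_grad",
    "log_likelihood",
    "posterior_quadrature",
    "build_inference_network",
    "moment_filter",
]

RATE_FLOOR = 1e-6  # events/s floor for the linear kernel

_KERNELS = ("exponential", "linear", "logistic")
_FAMILIES = ("poisson", "bernoulli", "binomial", "geometric")


@dataclass
class SensoryPopulation:
    """An input population with a rate kernel and a count-noise family.

    beta holds the per-neuron rate parameters (called A_i for the linear and
    logistic kernels), shape (Np,) for scalar stimuli or (Np, M).  r0 is the
    linear kernel's base rate in events/s; n_trials parameterizes the
    binomial family; taylor_order K sets the truncation of the
    network-implementable gradient expansions; c is the landmark gain used by
    reset populations.
    """

    beta: np.ndarray
    kernel: str = "exponential"
    r0: float = 1.0
    noise_family: str = "poisson"
    n_trials: int | None = None
    taylor_order: int = 2
    c: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta.ndim == 1:
            self.beta = self.beta[:, None]
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {_KERNELS}")
        if self.noise_family not in _FAMILIES:
            raise ValueError(
                f"unknown noise family {self.noise_family!r}; choose from {_FAMILIES}"
            )
        if self.noise_family == "binomial" and not self.n_trials:
            raise ValueError("binomial noise requires n_trials")
        if self.kernel == "linear" and self.taylor_order < 1:
            raise ValueError("linear kernel requires taylor_order >= 1")

    @property
    def n_neurons(self) -> int:
        return self.beta.shape[0]

    @property
    def stim_dim(self) -> int:
        return self.beta.shape[1]


@dataclass
class SpikeRecord:
    """Integer spike counts on a regular clock, one column per input neuron."""

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        steps, neurons = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "t": steps * self.dt,
                "neuron": neurons,
                "count": self.counts[steps, neurons],
            }
        )

    def save(self, csv_path, meta: dict | None = None) -> None:
        import json
        from pathlib import Path

        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        header = {"dt": self.dt, "n_steps": int(self.n_steps), "n_neurons": int(self.counts.shape[1])}
        header.update(meta or {})
        csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, csv_path) -> "SpikeRecord":
        import json
        from pathlib import Path

        csv_path = Path(csv_path)
        header = json.loads(csv_path.with_suffix(".json").read_text())
        counts = np.zeros((header["n_steps"], header["n_neurons"]), dtype=np.int64)
        frame = pd.read_csv(csv_path)
        if len(frame):
            steps = np.round(frame["t"].to_numpy(dtype=float) / header["dt"]).astype(int)
            neurons = frame["neuron"].to_numpy(dtype=int)
            counts[steps, neurons] = frame["count"].to_numpy(dtype=np.int64)
        return cls(counts=counts, dt=float(header["dt"]))


def _zcol(z) -> np.ndarray:
    z = np.atleast_1d(np.asarray(z, dtype=float))
    return z


def firing_rate(pop: SensoryPopulation, z) -> np.ndarray:
    """Per-neuron rate phi_i(z); linear rates are floored at RATE_FLOOR."""
    z = _zcol(z)
    if not np.all(np.isfinite(z)):
        raise ValueError("stimulus must be finite")
    u = pop.beta @ z
    if pop.kernel == "exponential":
        return np.exp(u)
    if pop.kernel == "linear":
        return np.maximum(u + pop.r0, RATE_FLOOR)
    return 1.0 / (1.0 + np.exp(-u))


def emit_spikes(
    pop: SensoryPopulation,
    z_series: np.ndarray,
    dt: float,
    seed: int | np.random.Generator | None = None,
) -> SpikeRecord:
    """Draw per-step counts from the configured noise family.

    Poisson counts have mean rate*dt; for the Bernoulli, binomial, and
    geometric families the kernel value is the per-step success probability
    (use the logistic kernel so it lies in (0, 1)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_series = np.asarray(z_series, dtype=float)
    if z_series.ndim == 1:
        z_series = z_series[:, None]
    rates = np.empty((z_series.shape[0], pop.n_neurons))
    for i, z in enumerate(z_series):
        rates[i] = firing_rate(pop, z)
    fam = pop.noise_family
    if fam == "poisson":
        counts = rng.poisson(rates * dt)
    elif fam == "bernoulli":
        counts = rng.binomial(1, np.clip(rates, 0.0, 1.0))
    elif fam == "binomial":
        counts = rng.binomial(pop.n_trials, np.clip(rates, 0.0, 1.0))
    else:  # geometric: support {0, 1, ...}, P(sigma) = f (1-f)^sigma
        p = np.clip(rates, 1e-12, 1.0)
        counts = rng.geometric(p) - 1
    return SpikeRecord(counts=counts.astype(np.int64), dt=dt)


@lru_cache(maxsize=None)
def _logistic_series(order: int) -> tuple[float, ...]:
    """Taylor coefficients of the logistic function around 0, low degree first.

    Computed from the ODE phi' = phi (1 - phi), phi(0) = 1/2, by coefficient
    recursion; no closed form needed.
    """
    c = [0.5]
    for k in range(order):
        conv = sum(c[j] * ((1.0 if k - j == 0 else 0.0) - c[k - j]) for j in range(k + 1))
        c.append(conv / (k + 1))
    return tuple(c)


def _polyval_low_first(coeffs, x: float) -> float:
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def log_likelihood(pop: SensoryPopulation, z, counts) -> float:
    """log P(sigma | z) of the configured kernel/noise pairing (up to constants)."""
    counts = np.asarray(counts, dtype=float).ravel()
    phi = firing_rate(pop, z)
    fam = pop.noise_family
    if fam == "poisson":
        return float(np.sum(counts * np.log(phi) - phi))
    f = np.clip(phi, 1e-12, 1 - 1e-12)
    if fam == "bernoulli":
        return float(np.sum(counts * np.log(f) + (1 - counts) * np.log1p(-f)))
    if fam == "binomial":
        return float(np.sum(counts * np.log(f) + (pop.n_trials - counts) * np.log1p(-f)))
    return float(np.sum(np.log(f) + counts * np.log1p(-f)))


def posterior_grad(
    pop: SensoryPopulation,
    z,
    counts,
    exact: bool | None = None,
) -> np.ndarray:
    """Gradient of the negative log posterior U(z) = -log P(sigma | z).

    ``exact=None`` follows the kernel default: the exponential kernel's
    gradient is evaluated exactly (it is what the Langevin drift needs), while
    the linear and logistic kernels return the truncated expansion of order
    ``pop.taylor_order`` — the form a polynomial-synapse network implements.
    Pass ``exact=True``/``False`` to force either form.
    """
    z = _zcol(z)
    counts = np.asarray(counts, dtype=float).ravel()
    if counts.shape[0] != pop.n_neurons:
        raise ValueError("counts length does not match population size")
    beta = pop.beta
    fam = pop.noise_family
    if fam != "poisson":
        # logistic-probability families: gradients are exact and polynomial-free
        f = firing_rate(pop, z)
        if pop.kernel != "logistic":
            f = np.clip(f, 1e-12, 1 - 1e-12)
        if fam == "bernoulli":
            w = f - counts
        elif fam == "binomial":
            w = pop.n_trials * f - counts
        else:  # geometric
            w = (1.0 + counts) * f - 1.0
        return beta.T @ w

    u = beta @ z
    if pop.kernel == "exponential":
        if exact is None or exact:
            return beta.T @ (np.exp(u) - counts)
        k = pop.taylor_order
        coeffs = [1.0 / _fact(n) for n in range(k + 1)]
        expk = np.array([_polyval_low_first(coeffs, ui) for ui in u])
        return beta.T @ (expk - counts)
    if pop.kernel == "linear":
        phi = firing_rate(pop, z)
        if exact is None:
            exact = False
        if exact:
            if np.any((phi <= RATE_FLOOR) & (counts > 0)):
                import warnings

                warnings.warn("rate at floor with nonzero count; gradient unreliable")
            return beta.T @ (1.0 - counts / phi)
        k = pop.taylor_order
        # 1/(1 + x) ~ sum_{n<K} (-x)^n with x = A.z / r0
        w = np.empty(pop.n_neurons)
        for i in range(pop.n_neurons):
            x = u[i] / pop.r0
            series = sum((-x) ** n for n in range(k))
            w[i] = 1.0 - counts[i] / pop.r0 * series
        return beta.T @ w
    # logistic kernel, Poisson counts
    if exact is None:
        exact = False
    if exact:
        phi = firing_rate(pop, z)
        grad_phi = phi * (1.0 - phi)  # scalar factor per neuron; direction beta_i
        return beta.T @ (grad_phi * (1.0 - counts / phi))
    k = pop.taylor_order
    order = k + 2
    c_phi = np.array(_logistic_series(order))
    # series of phi(1-phi) - sigma (1-phi) in powers of u
    c_phi2 = np.convolve(c_phi, c_phi)[: order + 1]
    c_var = c_phi - c_phi2  # phi (1 - phi)
    c_one_minus = -c_phi.copy()
    c_one_minus[0] += 1.0
    w = np.array(
        [
            _polyval_low_first(c_var, ui) - counts[i] * _polyval_low_first(c_one_minus, ui)
            for i, ui in enumerate(u)
        ]
    )
    return beta.T @ w


def _fact(n: int) -> float:
    out = 1.0
    for i in range(2, n + 1):
        out *= i
    return out


def posterior_quadrature(
    pop: SensoryPopulation,
    counts,
    grid: np.ndarray,
) -> DensityTable:
    """Normalized posterior over a scalar stimulus on a grid, by quadrature."""
    if pop.stim_dim != 1:
        raise ValueError("grid quadrature supports scalar stimuli only")
    grid = np.asarray(grid, dtype=float)
    logp = np.array([log_likelihood(pop, np.array([x]), counts) for x in grid])
    logp -= logp.max()
    p = np.exp(logp)
    z = np.trapezoid(p, grid)
    return DensityTable(grid=grid, pdf=p / z)


def build_inference_network(
    pop: SensoryPopulation,
    d,
    params: SCNParams,
    record: SpikeRecord,
    exact: bool | None = None,
) -> Network:
    """Spike-coding network that samples the posterior over the stimulus.

    The drift is ``-(1/tau_s) grad U(zhat, sigma_t)`` with sigma_t streamed
    from ``record`` (held constant within each sensory bin); the engine adds
    the ``+lam zhat`` compensation and injects D^T-correlated noise.
    """
    d_entries = d.entries if hasattr(d, "entries") else np.atleast_2d(np.asarray(d, float))
    if d_entries.shape[0] != pop.stim_dim:
        raise ValueError("population stimulus dimension must match readout dimension")
    ratio = record.dt / params.dt
    if abs(ratio - round(ratio)) > 1e-9 or record.dt + 1e-12 < params.dt:
        raise ValueError("sensory record dt must be an integer multiple of network dt")
    counts = record.counts
    n_bins = counts.shape[0]
    tau = params.tau_s
    bin_dt = record.dt

    def f(z, t):
        b = min(int(t / bin_dt), n_bins - 1)
        return -posterior_grad(pop, z, counts[b], exact=exact) / tau

    return Network(d_entries, params, drift=f, noise_amp=np.sqrt(2.0 / tau))


def moment_filter(samples: np.ndarray, window: float, dt: float) -> pd.DataFrame:
    """Causal moving-window mean, variance, and skewness of a sample stream.

    Implements the separation-of-timescales readout: when neural sampling is
    much faster than the stimulus, windowed moments track the instantaneous
    posterior.
    """
    if window < dt:
        raise ValueError("window must be at least one sample long")
    if window < 10 * dt:
        raise ValueError("window must cover at least 10 samples")
    samples = np.asarray(samples, dtype=float).ravel()
    w = int(round(window / dt))
    s = pd.Series(samples)
    roll = s.rolling(window=w, min_periods=1)
    out = pd.DataFrame(
        {
            "t": np.arange(samples.size) * dt,
            "mean": roll.mean(),
            "var": roll.var(ddof=0).fillna(0.0),
            "skew": roll.skew(),
        }
    )
    return out
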