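"""Head-direction estimation by sampling-based angular-velocity integration.

The heading estimate is updated by Langevin sampling from the filtered
posterior P(theta_t | sigma_t, theta_{t-1}), where sigma_t are Poisson counts
from a velocity-encoding population and the prior is either flat (1-D) or a
soft ring of radius rho (2-D Cartesian representation, which avoids angular
wraparound).  The resulting update is a noisy angular-velocity integrator
plus an attractor pull toward the ring:

    xy <- xy + (dt/alpha) * beta.(sigma - 1) * (y, -x)
             - (gamma dt/alpha) * xy * (x^2 + y^2 - 2 rho^2)
             + sqrt(2 dt/alpha) * eta,        alpha = 1 + dt beta.beta.

The literal attractor factor (x^2 + y^2 - 2 rho^2) stabilizes radius
sqrt(2)*rho; the exact gradient of the stated ring prior
exp[-(x^2+y^2)(x^2+y^2-2 rho^2)] instead gives the factor (x^2+y^2 - rho^2)
and stable radius rho.  Both conventions are exposed; they are not mutually
consistent in the source dynamics, so each mode is pinned to its own fixed
point.  The same drift, lifted through D^T, runs as a spike-coding network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scn import Network, SCNParams

__all__ = [
    "Landmark",
    "HDConfig",
    "wrap_angle",
    "angle_error",
    "stable_radius",
    "encode_velocity",
    "encode_landmark",
    "hd_step_1d",
    "hd_step_2d",
    "reset_update",
    "multimodal_compose",
    "run_hd_map",
    "build_hd_network",
    "decode_angle",
    "decode_series",
]


@dataclass
class Landmark:
    """A known landmark at angle 0, encoded by a dedicated Poisson population.

    gain is the peak per-bin Poisson rate when the heading points at the
    landmark; radius places the landmark on the readout ring.
    """

    gain: float = 1.0
    radius: float | None = None


@dataclass
class HDConfig:
    """Parameters of the head-direction sampler.

    rho            : ring-radius parameter (readout units)
    attractor_gain : gamma, strength of the soft circular constraint
    beta           : per-input-neuron velocity-encoding rate parameters (1/s);
                     the default +/- pair gives symmetric clockwise and
                     counterclockwise integration with per-bin mean count
                     exp(beta_i * omega * dt), equal to 1 at omega = 0.  The
                     magnitude is sized so dt*beta.beta >> 1 (tight per-step
                     posterior, integration gain dt*beta.beta/alpha near 1)
                     while beta*omega*dt stays small (linear encoding) over
                     the tested velocity range.
    dt             : sampler / sensory-bin step (s)
    attractor_mode : "literal" (published factor, stable radius sqrt(2)*rho)
                     or "exact" (prior gradient, stable radius rho)
    """

    rho: float = 1.0
    attractor_gain: float = 4.0
    beta: np.ndarray = None
    dt: float = 1e-4
    attractor_mode: str = "literal"
    landmark: Landmark | None = None

    def __post_init__(self) -> None:
        if self.beta is None:
            self.beta = np.array([700.0, -700.0])
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.attractor_mode not in ("literal", "exact"):
            raise ValueError(f"unknown attractor mode {self.attractor_mode!r}")
        if self.attractor_gain <= 0:
            raise ValueError("attractor_gain must be positive")

    @property
    def alpha(self) -> float:
        return 1.0 + self.dt * float(self.beta @ self.beta)

    @property
    def ring_constant(self) -> float:
        return 2 * self.rho**2 if self.attractor_mode == "literal" else self.rho**2


def wrap_angle(theta):
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi


def angle_error(theta_hat, theta_true):
    """Shortest-arc absolute angle difference, in [0, pi]."""
    return np.abs(wrap_angle(np.asarray(theta_hat) - np.asarray(theta_true)))


def stable_radius(config: HDConfig) -> float:
    return np.sqrt(config.ring_constant)


def encode_velocity(
    omega: np.ndarray,
    config: HDConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Poisson counts encoding angular velocity, one bin per sampler step.

    Per-bin mean count is exp(beta_i * omega_t * dt): the encoded quantity is
    the per-step angle change, so a stationary head (omega = 0) yields mean
    count 1 and (sigma - 1) is zero on average.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    omega = np.asarray(omega, dtype=float).ravel()
    rates = np.exp(np.outer(omega * config.dt, config.beta))
    return rng.poisson(rates)


def encode_landmark(
    theta_true: np.ndarray,
    config: HDConfig,
    rng: np.random.Generator | int | None = None,
    active: bool = True,
) -> np.ndarray:
    """Reset-population Poisson counts driven by the true heading.

    Rate is gain * exp(-(x-r)^2 - y^2) with (x, y) the true heading on the
    readout ring and the landmark at angle 0, distance r from the origin.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    theta_true = np.asarray(theta_true, dtype=float).ravel()
    if config.landmark is None or not active:
        return np.zeros(theta_true.size, dtype=np.int64)
    lm = config.landmark
    r = lm.radius if lm.radius is not None else stable_radius(config)
    big_r = stable_radius(config)
    x = big_r * np.cos(theta_true)
    y = big_r * np.sin(theta_true)
    rates = lm.gain * np.exp(-((x - r) ** 2) - y**2)
    return rng.poisson(rates)


def hd_step_1d(
    theta_prev: float,
    sigma_count: np.ndarray,
    config: HDConfig,
    noise_increment: float = 0.0,
) -> float:
    """One 1-D sampler update, wrapped to [-pi, pi).

    theta <- theta + (dt/alpha) * beta.(sigma - 1) + sqrt(2 dt)/alpha * eta.
    """
    sigma = np.atleast_1d(np.asarray(sigma_count, dtype=float))
    a = config.alpha
    dtheta = (config.dt / a) * float(config.beta @ (sigma - 1.0))
    dtheta += np.sqrt(2.0 * config.dt) / a * noise_increment
    return float(wrap_angle(theta_prev + dtheta))


def _inference_velocity(xy: np.ndarray, sigma: np.ndarray, config: HDConfig) -> np.ndarray:
    # Rotation direction (-y, x): positive inferred velocity advances the
    # decoded angle counterclockwise, matching omega = d(theta)/dt for
    # theta = atan2(y, x).
    drive = float(config.beta @ (np.asarray(sigma, dtype=float) - 1.0)) / config.alpha
    return drive * np.array([-xy[1], xy[0]])


def _attractor_velocity(xy: np.ndarray, config: HDConfig) -> np.ndarray:
    s = xy[0] ** 2 + xy[1] ** 2
    return -(config.attractor_gain / config.alpha) * xy * (s - config.ring_constant)


def reset_update(
    xy_prev: np.ndarray,
    sigma_reset_count: float,
    config: HDConfig,
) -> np.ndarray:
    """Additive landmark-reset displacement (already scaled by dt).

    The literal term 2 dt (x - r, y) (exp(-(x-r)^2 - y^2) - 2 sigma) pushes
    the estimate toward the landmark whenever the reset population is active,
    and weakly repels it from the landmark's immediate vicinity when silent.
    """
    if config.landmark is None:
        raise ValueError("no landmark configured")
    lm = config.landmark
    r = lm.radius if lm.radius is not None else stable_radius(config)
    x, y = xy_prev
    gauss = np.exp(-((x - r) ** 2) - y**2)
    return 2.0 * config.dt * np.array([x - r, y]) * (gauss - 2.0 * float(sigma_reset_count))


def multimodal_compose(*update_terms: np.ndarray) -> np.ndarray:
    """Combine per-population update terms computed at the same state.

    A product of likelihoods contributes additively to the log-posterior
    gradient, so composition is a plain sum.
    """
    if not update_terms:
        raise ValueError("no update terms to compose")
    out = np.array(update_terms[0], dtype=float)
    for term in update_terms[1:]:
        out = out + np.asarray(term, dtype=float)
    return out


def hd_step_2d(
    xy_prev: np.ndarray,
    sigma_count: np.ndarray,
    config: HDConfig,
    noise_increment: np.ndarray | None = None,
    sigma_reset: float | None = None,
) -> np.ndarray:
    """One 2-D sampler update: rotation by the inferred velocity, attractor
    pull toward the ring, optional landmark reset, and sampling noise."""
    xy = np.asarray(xy_prev, dtype=float)
    vel = _inference_velocity(xy, sigma_count, config) + _attractor_velocity(xy, config)
    out = xy + config.dt * vel
    if sigma_reset is not None:
        out = out + reset_update(xy, sigma_reset, config)
    if noise_increment is not None:
        out = out + np.sqrt(2.0 * config.dt / config.alpha) * np.asarray(noise_increment)
    bound = 10.0 * max(stable_radius(config), 1.0)
    if not np.all(np.abs(out) < bound):
        raise FloatingPointError(f"2-D sampler diverged beyond |xy| = {bound}")
    return out


def run_hd_map(
    config: HDConfig,
    counts: np.ndarray,
    rng: np.random.Generator | int | None = None,
    xy0: np.ndarray | None = None,
    reset_counts: np.ndarray | None = None,
    noise_on: bool = True,
) -> np.ndarray:
    """Iterate the low-dimensional 2-D sampler over a count stream.

    Returns the (steps, 2) Cartesian heading-sample path.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = np.atleast_2d(np.asarray(counts))
    n = counts.shape[0]
    xy = np.array([stable_radius(config), 0.0]) if xy0 is None else np.asarray(xy0, dtype=float).copy()
    noise = rng.standard_normal((n, 2)) if noise_on else None
    out = np.empty((n, 2))
    for i in range(n):
        xy = hd_step_2d(
            xy,
            counts[i],
            config,
            noise_increment=None if noise is None else noise[i],
            sigma_reset=None if reset_counts is None else float(reset_counts[i]),
        )
        out[i] = xy
    return out


def build_hd_network(
    config: HDConfig,
    d,
    params: SCNParams,
    counts: np.ndarray,
    reset_counts: np.ndarray | None = None,
    noise_on: bool = True,
) -> Network:
    """Spiking HD network implementing the 2-D sampler through its readout.

    Drift (readout space) is the inference rotation plus the attractor pull,
    plus the landmark term when configured; fast weights are -D^T D, the slow
    linear weights lam * D^T D enter through the engine's leak compensation,
    and the voltage noise is D^T xi with the alpha-scaled sampling amplitude
    sqrt(2/alpha) so the spiking readout and the low-D map share a stationary
    law.
    """
    d_entries = d.entries if hasattr(d, "entries") else np.atleast_2d(np.asarray(d, float))
    if d_entries.shape[0] != 2:
        raise ValueError("HD network requires a 2-D readout")
    counts = np.atleast_2d(np.asarray(counts))
    n_bins = counts.shape[0]
    bin_dt = config.dt
    ratio = bin_dt / params.dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("sampler bin dt must be an integer multiple of network dt")
    use_reset = reset_counts is not None
    if use_reset and config.landmark is None:
        raise ValueError("reset counts supplied but no landmark configured")

    def f(z, t):
        b = min(int(t / bin_dt), n_bins - 1)
        vel = _inference_velocity(z, counts[b], config) + _attractor_velocity(z, config)
        if use_reset:
            vel = vel + reset_update(z, float(reset_counts[b]), config) / config.dt
        return vel

    amp = np.sqrt(2.0 / config.alpha) if noise_on else 0.0
    return Network(d_entries, params, drift=f, noise_amp=amp)


def decode_angle(r: np.ndarray, d=None):
    """Population-vector decode: (theta_hat, radius) of the readout.

    ``r`` is a filtered-spike-train vector if ``d`` is given, otherwise a
    2-vector readout.  A zero readout has undefined angle: theta_hat is nan
    and radius 0.
    """
    if d is not None:
        d_entries = d.entries if hasattr(d, "entries") else np.atleast_2d(np.asarray(d, float))
        z = d_entries @ np.asarray(r, dtype=float)
    else:
        z = np.asarray(r, dtype=float)
    radius = float(np.hypot(z[0], z[1]))
    if radius == 0.0:
        return float("nan"), 0.0
    return float(np.arctan2(z[1], z[0])), radius


def decode_series(z: np.ndarray):
    """Vectorized decode of a (steps, 2) readout path -> (theta, radius)."""
    z = np.asarray(z, dtype=float)
    theta = np.arctan2(z[:, 1], z[:, 0])
    radius = np.hypot(z[:, 0], z[:, 1])
    theta[radius == 0.0] = np.nan
    return theta, radius
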