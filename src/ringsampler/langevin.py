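"""Langevin sampling from polynomial exponential-family distributions.

Two routes to samples from P(z) ~ exp(-U(z)): a direct (non-spiking)
Euler-Maruyama integration of ``dz = -(1/tau_s) grad U dt + sqrt(2/tau_s)
dW``, used as the reference, and a spike-coding network whose readout follows
the same drift with correlated voltage noise D^T xi.  Quadrature densities
and sample diagnostics close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .poly import EnergyPolynomial, check_normalizable, grad_energy
from .scn import Network, SCNParams, SimulationInstabilityError

__all__ = [
    "langevin_oracle",
    "build_sampler_network",
    "density_quadrature",
    "DensityTable",
    "compare_samples",
    "thin",
    "default_divergence_bound",
]


def default_divergence_bound(u: EnergyPolynomial, factor: float = 10.0) -> float:
    """Abort bound: ``factor`` times the outermost stationary point of U.

    For multivariate energies a fixed fallback of ``5 * factor`` is used.
    """
    if u.m == 1:
        coeffs = np.zeros(u.degree)  # gradient coefficients, low degree first
        for expo, coeff in u.gradient_terms()[0].items():
            coeffs[expo[0]] += coeff
        roots = np.roots(coeffs[::-1]) if np.any(coeffs) else np.array([0.0])
        real = roots[np.abs(roots.imag) < 1e-9].real
        outer = np.max(np.abs(real)) if real.size else 1.0
        return factor * max(outer, 1.0)
    return 5.0 * factor


def langevin_oracle(
    u: EnergyPolynomial,
    tau_s: float,
    dt: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
    z0: np.ndarray | None = None,
    noise_on: bool = True,
    divergence_bound: float | None = None,
) -> np.ndarray:
    """Euler-Maruyama sample path of the overdamped Langevin SDE.

    Returns an array of shape (steps, M).  Refuses non-normalizable energies;
    aborts with a seed-stamped error if the path leaves the divergence bound.
    """
    if not check_normalizable(u):
        raise ValueError("refusing to sample: exp(-U) is not normalizable")
    if dt >= tau_s:
        raise ValueError("require dt << tau_s for a meaningful discretization")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drift = grad_energy(u)
    bound = divergence_bound if divergence_bound is not None else default_divergence_bound(u)
    n_steps = int(round(duration / dt))
    z = np.zeros(u.m) if z0 is None else np.asarray(z0, dtype=float).copy()
    out = np.empty((n_steps, u.m))
    step_drift = dt / tau_s
    noise_scale = np.sqrt(2.0 * dt / tau_s) if noise_on else 0.0
    if u.m == 1:
        coeffs = drift._coeffs_1d[::-1]
        x = float(z[0])
        noise = rng.standard_normal(n_steps) * noise_scale if noise_on else None
        for i in range(n_steps):
            acc = 0.0
            for c in coeffs:
                acc = acc * x + c
            x -= step_drift * acc
            if noise is not None:
                x += noise[i]
            out[i, 0] = x
            if not (-bound < x < bound):
                raise SimulationInstabilityError(
                    f"Langevin path diverged (|z| > {bound}) at step {i}"
                )
        return out
    for i in range(n_steps):
        z = z - step_drift * drift(z)
        if noise_scale:
            z = z + noise_scale * rng.standard_normal(u.m)
        out[i] = z
        if not np.all(np.abs(z) < bound):
            raise SimulationInstabilityError(
                f"Langevin path diverged (|z| > {bound}) at step {i}"
            )
    return out


def build_sampler_network(
    u: EnergyPolynomial,
    d,
    params: SCNParams,
) -> Network:
    """Spike-coding network whose readout samples from exp(-U).

    The per-step readout-space drift is ``-(1/tau_s) grad U(zhat)`` (the
    engine adds the ``+lam zhat`` leak compensation), and the voltage noise is
    ``D^T xi`` with xi of amplitude sqrt(2/tau_s).
    """
    if not check_normalizable(u):
        raise ValueError("refusing to sample: exp(-U) is not normalizable")
    drift = grad_energy(u)
    m = np.atleast_2d(np.asarray(d, float) if not hasattr(d, "entries") else d.entries).shape[0]
    if drift.m != m:
        raise ValueError(
            f"energy dimension {drift.m} does not match readout dimension {m}"
        )
    tau = params.tau_s

    def f(z, t):
        return -drift(z) / tau

    return Network(d, params, drift=f, noise_amp=np.sqrt(2.0 / tau))


@dataclass
class DensityTable:
    """Normalized density on a regular grid (1-D or 2-D)."""

    grid: np.ndarray            # (n,) or (nx, ny, 2)
    pdf: np.ndarray             # (n,) or (nx, ny)

    @property
    def ndim(self) -> int:
        return 1 if self.pdf.ndim == 1 else 2

    def cdf(self) -> np.ndarray:
        if self.ndim != 1:
            raise ValueError("cdf available only for 1-D tables")
        x, p = self.grid, self.pdf
        c = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x))])
        return c / c[-1]

    def moments(self) -> dict[str, float]:
        if self.ndim != 1:
            raise ValueError("moments implemented for 1-D tables")
        x, p = self.grid, self.pdf
        mean = np.trapezoid(x * p, x)
        var = np.trapezoid((x - mean) ** 2 * p, x)
        sd = np.sqrt(var)
        skew = np.trapezoid((x - mean) ** 3 * p, x) / sd**3
        kurt = np.trapezoid((x - mean) ** 4 * p, x) / sd**4
        return {"mean": mean, "var": var, "skew": skew, "kurtosis": kurt}

    def mode_count(self, rel_height: float = 0.05) -> int:
        p = self.pdf if self.ndim == 1 else self.pdf.ravel()
        if self.ndim != 1:
            raise ValueError("mode_count implemented for 1-D tables")
        thr = rel_height * p.max()
        interior = (p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:]) & (p[1:-1] > thr)
        return int(np.count_nonzero(interior))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws (1-D), used for self-consistency checks."""
        c = self.cdf()
        x, keep = self.grid, np.concatenate([[True], np.diff(self.cdf()) > 0])
        return np.interp(rng.uniform(size=n), c[keep], x[keep])


def density_quadrature(
    u,
    grid: np.ndarray | tuple,
) -> DensityTable:
    """exp(-U)/Z on a grid, normalized by trapezoidal quadrature.

    ``u`` may be an EnergyPolynomial or any callable U(z); grids are a 1-D
    point array or an (x_axis, y_axis) pair for 2-D energies.
    """
    if isinstance(u, EnergyPolynomial):
        if not check_normalizable(u):
            raise ValueError("exp(-U) is not normalizable")
        if u.m > 2:
            raise ValueError(
                "grid quadrature supports m <= 2; use importance sampling "
                "for higher dimensions"
            )
        fn = u
        m = u.m
    else:
        fn = u
        m = 1 if isinstance(grid, np.ndarray) and np.ndim(grid) == 1 else 2
    if m == 1:
        x = np.asarray(grid, dtype=float)
        logp = -np.asarray([fn(np.array([xi])) for xi in x]).ravel() \
            if not isinstance(fn, EnergyPolynomial) else -fn(x[:, None])
        logp = logp - logp.max()
        p = np.exp(logp)
        z = np.trapezoid(p, x)
        return DensityTable(grid=x, pdf=p / z)
    xa, ya = (np.asarray(g, dtype=float) for g in grid)
    mx, my = np.meshgrid(xa, ya, indexing="ij")
    pts = np.stack([mx.ravel(), my.ravel()], axis=-1)
    logp = -fn(pts).reshape(mx.shape)
    logp = logp - logp.max()
    p = np.exp(logp)
    z = np.trapezoid(np.trapezoid(p, ya, axis=1), xa)
    return DensityTable(grid=np.stack([mx, my], axis=-1), pdf=p / z)


def thin(samples: np.ndarray, dt: float, interval: float) -> np.ndarray:
    """Keep one sample per ``interval`` seconds to mitigate autocorrelation."""
    stride = max(1, int(round(interval / dt)))
    return samples[::stride]


def compare_samples(samples: np.ndarray, density: DensityTable) -> dict:
    """Distribution-matching diagnostics of a 1-D sample stream.

    Returns the Kolmogorov-Smirnov distance to the table's CDF, the first
    four sample moments, and the mode counts of the sample histogram and of
    the density table.  Deterministic given fixed inputs.
    """
    from scipy import stats

    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty sample set")
    cdf = density.cdf()
    xs = np.sort(samples)
    f_theory = np.interp(xs, density.grid, cdf)
    n = xs.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    ks = float(np.max(np.maximum(emp_hi - f_theory, f_theory - emp_lo)))
    mean = float(np.mean(samples))
    var = float(np.var(samples))
    if var > 0:
        kde = stats.gaussian_kde(samples)
        smooth = kde(density.grid)
    else:
        smooth = np.zeros_like(density.grid)
    thr = 0.1 * smooth.max() if smooth.size else 0.0
    interior = (smooth[1:-1] > smooth[:-2]) & (smooth[1:-1] >= smooth[2:]) & (smooth[1:-1] > thr)
    return {
        "ks": ks,
        "n": int(n),
        "mean": mean,
        "var": var,
        "skew": float(stats.skew(samples)) if var > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(samples, fisher=False)) if var > 0 else 0.0,
        "mode_count_samples": int(np.count_nonzero(interior)),
        "mode_count_density": density.mode_count(),
    }
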