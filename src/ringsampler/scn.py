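"""Leaky spike-coding network engine.

A spike-coding network (SCN) represents a low-dimensional signal z through a
linear readout zhat = D r of filtered spike trains r.  Each neuron's voltage
tracks the projection of the readout error onto its decoding column, and the
greedy spike rule (fire when v_i exceeds the threshold T_i = ||D_i||^2 / 2,
spike costs aside) guarantees every spike reduces the instantaneous
reconstruction error.  Fast recurrent weights -D^T D implement the post-spike
balance/reset; slow weights (or an arbitrary readout-space drift callback)
implement the target dynamics; correlated voltage noise eta = D^T xi drives
Langevin exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReadoutMatrix",
    "SCNParams",
    "NetworkState",
    "Connectivity",
    "NoiseModel",
    "SimulationInstabilityError",
    "build_fast_weights",
    "thresholds",
    "spike_rule",
    "step",
    "readout",
    "Network",
    "SimResult",
    "ring_readout",
]


class SimulationInstabilityError(RuntimeError):
    """Raised when voltages or readouts become non-finite or diverge."""


class ReadoutMatrix:
    """Decoding matrix with one row per readout dimension, one column per neuron.

    Every neuron must decode to something: all-zero columns are rejected, so
    the thresholds ||D_i||^2 / 2 derived from the columns are strictly
    positive.
    """

    def __init__(self, entries: np.ndarray):
        entries = np.atleast_2d(np.asarray(entries, dtype=float))
        if entries.size == 0:
            raise ValueError("empty decoding matrix")
        norms = np.linalg.norm(entries, axis=0)
        if np.any(norms == 0.0):
            bad = int(np.flatnonzero(norms == 0.0)[0])
            raise ValueError(f"decoding column {bad} is all zeros")
        self.entries = entries

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]

    @property
    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.entries, axis=0)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.entries, dtype=dtype)


def _as_matrix(d) -> np.ndarray:
    return d.entries if isinstance(d, ReadoutMatrix) else np.atleast_2d(np.asarray(d, float))


@dataclass
class SCNParams:
    """Simulation parameters.

    lambda_leak : voltage/filter leak (1/s)
    dt          : integration step (s)
    nu, mu      : linear and quadratic spike costs
    tau_s       : sampling timescale (s) for Langevin drifts
    filter_convention : "main" (r' = -lam r + o, zhat = D r) or
        "methods" (r' = -lam r + lam o, zhat = D r / lam); the two differ
        only by a fixed rescaling of r.
    """

    lambda_leak: float
    dt: float = 1e-4
    nu: float = 0.0
    mu: float = 0.0
    tau_s: float = 0.05
    filter_convention: str = "main"

    def __post_init__(self) -> None:
        if self.lambda_leak <= 0 or self.dt <= 0 or self.tau_s <= 0:
            raise ValueError("lambda_leak, dt and tau_s must all be positive")
        if self.filter_convention not in ("main", "methods"):
            raise ValueError(f"unknown filter convention {self.filter_convention!r}")
        if abs(self.lambda_leak * self.dt) >= 1:
            raise ValueError("dt too coarse: require |lambda*dt| < 1")


@dataclass
class NetworkState:
    v: np.ndarray
    r: np.ndarray
    o: np.ndarray
    t: float = 0.0


@dataclass
class Connectivity:
    omega_fast: np.ndarray
    omega_slow: list = field(default_factory=list)


@dataclass
class NoiseModel:
    """Correlated voltage noise eta = D^T xi from an M-dimensional Wiener source.

    The injected voltage noise has rank at most M and covariance proportional
    to D^T D.
    """

    d_matrix: np.ndarray
    amplitude: float
    seed: int | None = None

    def inject(self, xi: np.ndarray) -> np.ndarray:
        return _as_matrix(self.d_matrix).T @ xi


def build_fast_weights(d) -> np.ndarray:
    """Fast balancing connectivity -D^T D (symmetric, diagonal -||D_i||^2)."""
    mat = _as_matrix(d)
    if mat.size == 0:
        raise ValueError("empty decoding matrix")
    return -mat.T @ mat


def thresholds(d, nu: float = 0.0, mu: float = 0.0, lambda_leak: float = 1.0) -> np.ndarray:
    """Spike thresholds T_i = (nu*lam + mu*lam^2 + ||D_i||^2) / 2."""
    mat = _as_matrix(d)
    sq = np.sum(mat * mat, axis=0)
    return 0.5 * (nu * lambda_leak + mu * lambda_leak**2 + sq)


def spike_rule(state_or_v, t_vec: np.ndarray, step_index: int | None = None):
    """Greedy spike selection: the neuron with maximal threshold violation.

    Returns the spiking neuron index, or None when no voltage exceeds its
    threshold.  At most one neuron fires per call; ties break to the lowest
    index (numpy argmax convention).  If ``state_or_v`` is a NetworkState its
    spike indicator ``o`` is updated in place.
    """
    state = state_or_v if isinstance(state_or_v, NetworkState) else None
    v = state.v if state is not None else np.asarray(state_or_v, dtype=float)
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        where = f" at step {step_index}" if step_index is not None else ""
        raise SimulationInstabilityError(
            f"non-finite voltage in neuron {bad}{where}"
        )
    excess = v - t_vec
    k = int(np.argmax(excess))
    fired = excess[k] > 0.0
    if state is not None:
        state.o[:] = 0.0
        if fired:
            state.o[k] = 1.0
    return k if fired else None


def step(
    state: NetworkState,
    drift: np.ndarray,
    connectivity: Connectivity,
    params: SCNParams,
    t_vec: np.ndarray,
    noise: np.ndarray | None = None,
    step_index: int | None = None,
) -> NetworkState:
    """One Euler-Maruyama update of voltages, spikes, and filtered trains.

    ``drift`` is the neuron-space drive (length N).  A spike contributes its
    fast-weight column to v and a unit (or lam, in the "methods" convention)
    increment to r within the same step; the spike itself is treated as a
    delta of unit area, so its effect is not scaled by dt.
    """
    drift = np.asarray(drift, dtype=float)
    if drift.shape != state.v.shape:
        raise ValueError(f"drift has shape {drift.shape}, expected {state.v.shape}")
    lam, dt = params.lambda_leak, params.dt
    state.v += dt * (-lam * state.v + drift)
    if noise is not None:
        state.v += noise
    k = spike_rule(state, t_vec, step_index=step_index)
    state.r += dt * (-lam * state.r)
    if k is not None:
        state.v += connectivity.omega_fast[:, k]
        state.r[k] += lam if params.filter_convention == "methods" else 1.0
    state.t += dt
    return state


def readout(state: NetworkState, d, params: SCNParams | None = None) -> np.ndarray:
    """Linear readout zhat = D r (divided by lam in the "methods" convention)."""
    mat = _as_matrix(d)
    z = mat @ state.r
    if params is not None and params.filter_convention == "methods":
        z = z / params.lambda_leak
    return z


def ring_readout(n: int, radius_param: float = 1.0, m: int = 2) -> ReadoutMatrix:
    """Decoding columns at evenly spaced ring angles with a common norm.

    The norm is chosen as ``radius_param * sqrt(2 / n)`` so thresholds are
    O(radius_param^2 / n); for m == 1 the columns alternate sign instead.
    """
    if n < 2:
        raise ValueError("ring readout needs at least 2 neurons")
    scale = radius_param * np.sqrt(2.0 / n)
    if m == 1:
        cols = scale * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
        return ReadoutMatrix(cols[None, :])
    if m != 2:
        raise ValueError("ring readout supports m in {1, 2}")
    angles = 2 * np.pi * np.arange(n) / n
    return ReadoutMatrix(scale * np.stack([np.cos(angles), np.sin(angles)]))


@dataclass
class SimResult:
    """Recorded trajectory of a network run."""

    t: np.ndarray
    z: np.ndarray          # (steps, M) readout
    spikes: np.ndarray     # (steps,) spiking neuron index, -1 when silent
    r: np.ndarray | None = None
    v: np.ndarray | None = None
    seed: int | None = None
    dt: float = 0.0
    n_neurons: int = 0

    def spike_trains(self) -> np.ndarray:
        """Dense (steps, N) 0/1 spike indicator matrix."""
        out = np.zeros((self.spikes.shape[0], self.n_neurons), dtype=np.uint8)
        fired = self.spikes >= 0
        out[np.flatnonzero(fired), self.spikes[fired]] = 1
        return out

    def to_frame(self):
        """Columnar table: t, v_1.., r_1.., o_1.., z_1.. (recorded columns only)."""
        import pandas as pd

        data = {"t": self.t}
        if self.v is not None:
            data.update({f"v_{i + 1}": self.v[:, i] for i in range(self.n_neurons)})
        if self.r is not None:
            data.update({f"r_{i + 1}": self.r[:, i] for i in range(self.n_neurons)})
        trains = self.spike_trains()
        data.update({f"o_{i + 1}": trains[:, i] for i in range(self.n_neurons)})
        data.update({f"z_{j + 1}": self.z[:, j] for j in range(self.z.shape[1])})
        return pd.DataFrame(data)

    def save(self, csv_path, config: dict | None = None) -> None:
        """Write the run table as CSV with a JSON sidecar (config + seed)."""
        import json
        from pathlib import Path

        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.8g")
        sidecar = {"seed": self.seed, "dt": self.dt, "n_neurons": self.n_neurons}
        sidecar.update(config or {})
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


class Network:
    """An SCN whose readout follows a user-supplied readout-space drift.

    Parameters
    ----------
    d:
        Decoding matrix (ReadoutMatrix or array, shape M x N).
    params:
        SCNParams.
    drift:
        Callable ``f(z, t) -> array(M)`` giving the target readout-space
        velocity (e.g. a Langevin drift ``-(1/tau_s) grad U(z)``).  When
        ``leak_compensation`` is on, the engine adds ``lam * z`` before
        lifting by D^T, so the readout, not the voltage, follows f.
    noise_amp:
        Standard deviation scale of the M-dimensional Wiener drive per unit
        sqrt-time; samplers use sqrt(2 / tau_s).
    """

    def __init__(
        self,
        d,
        params: SCNParams,
        drift=None,
        noise_amp: float = 0.0,
        leak_compensation: bool = True,
    ):
        self.d = d if isinstance(d, ReadoutMatrix) else ReadoutMatrix(d)
        self.params = params
        self.drift = drift
        self.noise_amp = float(noise_amp)
        self.leak_compensation = leak_compensation
        self.omega_fast = build_fast_weights(self.d)
        self.t_vec = thresholds(self.d, params.nu, params.mu, params.lambda_leak)

    def initial_state(self, z0: np.ndarray | None = None) -> NetworkState:
        n = self.d.n
        r0 = np.zeros(n)
        if z0 is not None:
            from scipy.optimize import nnls

            z0 = np.asarray(z0, dtype=float)
            scale = self.params.lambda_leak if self.params.filter_convention == "methods" else 1.0
            r0, _ = nnls(self.d.entries, scale * z0)
        return NetworkState(v=np.zeros(n), r=r0, o=np.zeros(n), t=0.0)

    def run(
        self,
        duration: float,
        rng: np.random.Generator | int | None = None,
        z0: np.ndarray | None = None,
        record_r: bool = False,
        record_v: bool = False,
        state: NetworkState | None = None,
        divergence_bound: float | None = None,
    ) -> SimResult:
        params = self.params
        dt, lam = params.dt, params.lambda_leak
        seed = rng if isinstance(rng, (int, np.integer)) else None
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        n_steps = max(1, int(round(duration / dt)))
        dmat = self.d.entries
        dmat_t = np.ascontiguousarray(dmat.T)
        m, n = dmat.shape
        scale = 1.0 / lam if params.filter_convention == "methods" else 1.0

        if state is None:
            state = self.initial_state(z0)
        v, r = state.v, state.r
        z_rec = np.empty((n_steps, m))
        spk = np.full(n_steps, -1, dtype=np.int32)
        r_rec = np.empty((n_steps, n)) if record_r else None
        v_rec = np.empty((n_steps, n)) if record_v else None
        wf = self.omega_fast
        t_vec = self.t_vec
        noise_scale = self.noise_amp * np.sqrt(dt)
        drift = self.drift
        r_inc = lam if params.filter_convention == "methods" else 1.0

        t = state.t
        for i in range(n_steps):
            z = dmat @ r * scale
            if drift is not None:
                f = drift(z, t)
                if self.leak_compensation:
                    f = f + lam * z
                dv = dt * (dmat_t @ f - lam * v)
            else:
                dv = dt * (-lam * v)
            if noise_scale:
                dv += dmat_t @ (noise_scale * rng.standard_normal(m))
            v += dv
            excess = v - t_vec
            k = int(np.argmax(excess))
            r *= 1.0 - lam * dt
            if excess[k] > 0.0:
                if not np.isfinite(excess[k]):
                    raise SimulationInstabilityError(
                        f"non-finite voltage in neuron {k} at step {i}"
                    )
                v += wf[:, k]
                r[k] += r_inc
                spk[i] = k
            z_rec[i] = dmat @ r * scale
            if record_r:
                r_rec[i] = r
            if record_v:
                v_rec[i] = v
            t += dt
            if divergence_bound is not None and i % 256 == 0:
                if not np.all(np.abs(z_rec[i]) < divergence_bound):
                    raise SimulationInstabilityError(
                        f"readout exceeded divergence bound {divergence_bound} "
                        f"at step {i} (seed={seed})"
                    )
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationInstabilityError(
                f"non-finite voltage in neuron {bad} at end of run"
            )
        state.t = t
        times = state.t - dt * np.arange(n_steps - 1, -1, -1)
        return SimResult(
            t=times, z=z_rec, spikes=spk, r=r_rec, v=v_rec,
            seed=seed, dt=dt, n_neurons=n,
        )
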