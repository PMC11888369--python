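"""Synthetic driving signals: angular-velocity / heading trajectories and
end-to-end fixtures (trajectory -> sensory spikes -> files), so every stage of
the pipeline is testable without external data.

Default timescales: behavioral step 1e-3 s against a network step of 1e-4 s,
a tenfold separation (configurable up to the thousandfold ratio used for
moment-recovery experiments)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hd import wrap_angle
from .sensory import SensoryPopulation, SpikeRecord, emit_spikes, firing_rate

__all__ = ["Trajectory", "make_trajectory", "make_fixture", "DEFAULT_BEHAVIOR_DT", "DEFAULT_NETWORK_DT"]

DEFAULT_BEHAVIOR_DT = 1e-3
DEFAULT_NETWORK_DT = 1e-4


@dataclass
class Trajectory:
    """Time series of true head direction theta(t) and angular velocity omega(t).

    theta is wrapped to [-pi, pi); the wrapped finite difference of theta
    equals omega * dt at every step by construction.
    """

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    dt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "theta": self.theta, "omega": self.omega})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def load(cls, path) -> "Trajectory":
        frame = pd.read_csv(path)
        t = frame["t"].to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(t=t, theta=frame["theta"].to_numpy(), omega=frame["omega"].to_numpy(), dt=dt)


def make_trajectory(
    kind: str,
    params: dict | None = None,
    duration: float = 1.0,
    dt: float = DEFAULT_BEHAVIOR_DT,
    seed: int | np.random.Generator | None = None,
    theta0: float = 0.0,
) -> Trajectory:
    """Generate omega(t) of the requested kind and integrate theta with wrap.

    Kinds
    -----
    constant  : params {"omega": rad/s}
    piecewise : params {"times": [...], "values": [...]} — omega jumps to
                values[i] at times[i]
    ou        : params {"mean", "sd", "tau"} — Ornstein-Uhlenbeck velocity
                with stationary standard deviation sd
    sinusoid  : params {"amplitude", "frequency", "phase"}
    """
    if duration < dt:
        raise ValueError("duration must cover at least one step")
    params = dict(params or {})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if kind == "constant":
        omega = np.full(n, float(params.get("omega", 0.0)))
    elif kind == "piecewise":
        times = np.asarray(params["times"], dtype=float)
        values = np.asarray(params["values"], dtype=float)
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(values) - 1)
        omega = values[idx]
    elif kind == "ou":
        mean = float(params.get("mean", 0.0))
        sd = float(params.get("sd", 1.0))
        tau = float(params.get("tau", 0.5))
        omega = np.empty(n)
        x = mean + sd * rng.standard_normal()
        kick = sd * np.sqrt(2.0 * dt / tau)
        for i in range(n):
            x += (mean - x) * dt / tau + kick * rng.standard_normal()
            omega[i] = x
    elif kind == "sinusoid":
        amp = float(params.get("amplitude", 1.0))
        freq = float(params.get("frequency", 0.5))
        phase = float(params.get("phase", 0.0))
        omega = amp * np.sin(2 * np.pi * freq * t + phase)
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    theta = np.empty(n)
    acc = theta0
    for i in range(n):
        acc = wrap_angle(acc + omega[i] * dt)
        theta[i] = acc
    return Trajectory(t=t, theta=theta, omega=omega, dt=dt)


def make_fixture(
    trajectory: Trajectory,
    pop: SensoryPopulation,
    seed: int,
    out_dir,
) -> dict:
    """Write a complete fixture: trajectory CSV, spike CSV + header, manifest.

    Returns the manifest dict.  Re-running with the same seed produces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = emit_spikes(pop, trajectory.omega, trajectory.dt, seed=seed)
    traj_path = out_dir / "trajectory.csv"
    spike_path = out_dir / "spikes.csv"
    trajectory.save(traj_path)
    record.save(spike_path, meta={"seed": seed, "kernel": pop.kernel, "noise_family": pop.noise_family})
    manifest = {
        "seed": int(seed),
        "dt": trajectory.dt,
        "n_steps": int(trajectory.t.size),
        "population": {
            "kernel": pop.kernel,
            "noise_family": pop.noise_family,
            "beta": np.asarray(pop.beta).ravel().tolist(),
            "r0": pop.r0,
            "n_trials": pop.n_trials,
            "taylor_order": pop.taylor_order,
        },
        "files": {"trajectory": traj_path.name, "spikes": spike_path.name},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def empirical_rates(record: SpikeRecord) -> np.ndarray:
    """Mean observed event rate per neuron (events/s)."""
    return record.counts.mean(axis=0) / record.dt


def expected_rates(pop: SensoryPopulation, trajectory: Trajectory) -> np.ndarray:
    """Time-averaged kernel rate per neuron along a trajectory (events/s)."""
    rates = np.stack([firing_rate(pop, np.atleast_1d(w)) for w in trajectory.omega])
    return rates.mean(axis=0)
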