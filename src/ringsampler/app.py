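"""Experiment orchestration: config loading, seeded runners, artifact output.

Each named experiment reproduces one figure-level study end to end and
writes CSV artifacts plus a JSON manifest (full configuration, seeds,
package version, per-stage wall time and spike counts) so every output
directory is reconstructible from its manifest alone.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, experiments, hd, langevin, poly, scn, sensory

EXPERIMENTS = (
    "bimodal-sampling",
    "velocity-inference",
    "hd-darkness",
    "hd-reset",
    "predictions-suite",
)


class ConfigError(ValueError):
    """Invalid experiment configuration (bad schema or field value)."""


def load_config(source) -> dict:
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        cfg = yaml.safe_load(path.read_text())
        if not isinstance(cfg, dict):
            raise ConfigError("config root must be a mapping")
    if "experiment" not in cfg:
        raise ConfigError("missing required field 'experiment'")
    if cfg["experiment"] not in EXPERIMENTS:
        raise ConfigError(
            f"unknown experiment {cfg['experiment']!r}; choose from {EXPERIMENTS}"
        )
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    cfg.setdefault("out_dir", f"runs/{cfg['experiment']}")
    cfg.setdefault("params", {})
    if not isinstance(cfg["params"], dict):
        raise ConfigError("field 'params' must be a mapping")
    return cfg


def _write_json(path: Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))


def run_experiment(config_source) -> Path:
    """Execute one named experiment; returns the output directory.

    Raises ConfigError for schema problems and lets
    SimulationInstabilityError propagate (stage name and seed included).
    """
    cfg = load_config(config_source)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    params = cfg["params"]
    name = cfg["experiment"]
    log: list[dict] = []
    t0 = time.time()

    try:
        if name == "bimodal-sampling":
            diagnostics = _run_bimodal(seed, params, out_dir, log)
        elif name == "velocity-inference":
            diagnostics = _run_inference(seed, params, out_dir, log)
        elif name == "hd-darkness":
            diagnostics = _run_darkness(seed, params, out_dir, log)
        elif name == "hd-reset":
            diagnostics = _run_reset(seed, params, out_dir, log)
        else:
            diagnostics = _run_predictions(seed, params, out_dir, log)
    except scn.SimulationInstabilityError as exc:
        raise scn.SimulationInstabilityError(
            f"experiment {name!r} (seed={seed}) aborted: {exc}"
        ) from exc

    manifest = {
        "experiment": name,
        "seed": seed,
        "params": params,
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 3),
        "stages": log,
    }
    _write_json(out_dir / "manifest.json", manifest)
    _write_json(out_dir / "diagnostics.json", diagnostics)
    return out_dir


def _stage(log: list, name: str, started: float, **info) -> None:
    log.append({"stage": name, "wall_time_s": round(time.time() - started, 3), **info})


def _run_bimodal(seed, params, out_dir, log):
    t0 = time.time()
    duration = float(params.get("duration", 30.0))
    energy = params.get("energy", {"m": 1, "terms": [
        {"exponents": [4], "coeff": 1.0}, {"exponents": [2], "coeff": -2.0}]})
    u = poly.EnergyPolynomial.from_json(json.dumps(energy))
    dt, tau = 1e-4, 0.05
    net = langevin.build_sampler_network(
        u, scn.ring_readout(int(params.get("n_neurons", 20)), radius_param=1.0, m=1),
        scn.SCNParams(lambda_leak=10.0, dt=dt, tau_s=tau),
    )
    res = net.run(duration, rng=np.random.default_rng([seed, 0]), z0=np.array([1.0]))
    n_spikes = int((res.spikes >= 0).sum())
    pd.DataFrame({"t": res.t, "z": res.z[:, 0]}).to_csv(
        out_dir / "samples.csv", index=False, float_format="%.8g"
    )
    dens = langevin.density_quadrature(u, np.linspace(-2.5, 2.5, 1001))
    thinned = langevin.thin(res.z[int(2.0 / dt):, 0], dt, tau)
    diag = langevin.compare_samples(thinned, dens)
    diag["occupancy_positive"] = float((thinned > 0).mean())
    _stage(log, "sample", t0, n_spikes=n_spikes)
    return diag


def _run_inference(seed, params, out_dir, log):
    t0 = time.time()
    out = experiments.posterior_inference(
        seed, duration=float(params.get("duration", 30.0))
    )
    _stage(log, "infer", t0)
    return out


def _run_darkness(seed, params, out_dir, log):
    t0 = time.time()
    duration = float(params.get("duration", 10.0))
    omega = float(params.get("omega", 1.0))
    lam = float(params.get("lambda_leak", experiments.HD_LEAK))
    config = hd.HDConfig()
    d = experiments.hd_default_readout(config, int(params.get("n_neurons", 8)))
    rng = np.random.default_rng([seed, 1])
    n_bins = int(duration / config.dt)
    counts = hd.encode_velocity(np.full(n_bins, omega), config, rng)
    net = hd.build_hd_network(
        config, d, scn.SCNParams(lambda_leak=lam, dt=experiments.HD_NET_DT), counts
    )
    res = net.run(
        duration, rng=rng, z0=np.array([hd.stable_radius(config), 0.0]), record_r=True
    )
    theta_hat, radius = hd.decode_series(res.z)
    theta_true = hd.wrap_angle(omega * (np.arange(theta_hat.size) + 1) * experiments.HD_NET_DT)
    pd.DataFrame(
        {"t": res.t, "theta_true": theta_true, "theta_hat": theta_hat, "radius": radius}
    ).to_csv(out_dir / "decoded.csv", index=False, float_format="%.8g")
    sensory.SpikeRecord(counts=res.spike_trains(), dt=experiments.HD_NET_DT).save(
        out_dir / "network_spikes.csv", meta={"seed": seed}
    )
    burn = int(1.0 / experiments.HD_NET_DT)
    un = np.unwrap(theta_hat)
    gain = float((un[-1] - un[burn]) / ((un.size - burn) * experiments.HD_NET_DT) / omega)
    _stage(log, "hd-darkness", t0, n_spikes=int((res.spikes >= 0).sum()))
    return {
        "velocity_gain": gain,
        "mean_abs_err": float(np.mean(hd.angle_error(theta_hat[burn:], theta_true[burn:]))),
        "mean_radius": float(radius[burn:].mean()),
    }


def _run_reset(seed, params, out_dir, log):
    t0 = time.time()
    out = experiments.reset_experiment(
        seed,
        n_reps=int(params.get("n_reps", 10)),
        duration=float(params.get("duration", 4.0)),
    )
    _stage(log, "hd-reset", t0)
    return out


def _run_predictions(seed, params, out_dir, log):
    diag = {}
    for label, fn in (
        ("correlation_structure", experiments.correlation_structure),
        ("bump_velocity_skew", experiments.bump_velocity_skew),
        ("leak_comparison", experiments.leak_comparison),
    ):
        t0 = time.time()
        diag[label] = fn(seed)
        _stage(log, label, t0)
    return diag
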