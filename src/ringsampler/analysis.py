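"""Prediction statistics: subthreshold voltage cross-correlations, two-scale
spike correlations, tuning curves, bump-velocity distributions, and drift
curves — the experimentally testable signatures of a sampling head-direction
network."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d

from .hd import wrap_angle

__all__ = [
    "voltage_xcorr",
    "spike_corr_two_scales",
    "tuning_curves",
    "bump_velocity_stats",
    "drift_curve",
    "bump_localization",
    "tuning_heterogeneity",
]


def _standardize(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


@dataclass
class XCorrResult:
    lags: np.ndarray                # seconds
    corr: np.ndarray                # (N, N, n_lags)
    undefined_pairs: list           # pairs with a constant trace

    def lag_zero(self) -> np.ndarray:
        return self.corr[:, :, self.corr.shape[2] // 2]


def voltage_xcorr(voltages: np.ndarray, dt: float, max_lag: float) -> XCorrResult:
    """Pairwise lagged Pearson correlations of subthreshold voltage traces.

    ``voltages`` is (time, N); lags run over [-max_lag, max_lag].  Pairs
    containing a constant trace are flagged and left as nan.
    """
    v = np.asarray(voltages, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a (time, N) array with at least 2 neurons")
    if v.shape[0] < 100:
        raise ValueError("need at least 100 samples")
    n_t, n = v.shape
    k = int(round(max_lag / dt))
    k = min(k, n_t - 1)
    lags = np.arange(-k, k + 1)
    std = [_standardize(v[:, i]) for i in range(n)]
    corr = np.full((n, n, lags.size), np.nan)
    undefined = []
    for i in range(n):
        for j in range(i, n):
            if std[i] is None or std[j] is None:
                undefined.append((i, j))
                continue
            full = signal.correlate(std[i], std[j], mode="full", method="fft")
            mid = n_t - 1
            seg = full[mid - k: mid + k + 1]
            counts = n_t - np.abs(lags)
            c = seg / counts
            corr[i, j] = c
            corr[j, i] = c[::-1]
    return XCorrResult(lags=lags * dt, corr=corr, undefined_pairs=undefined)


def spike_corr_two_scales(
    trains: np.ndarray,
    dt: float,
    kernel_widths: tuple = (1e-3, 100e-3),
) -> dict:
    """Pairwise Pearson correlations of Gaussian-smoothed spike trains.

    Convolving with a narrow (1 ms) kernel exposes the fast, balance-driven
    coordination structure; a wide (100 ms) kernel exposes the slow,
    computation-driven rate comodulation.  Empty trains yield nan rows.
    """
    trains = np.asarray(trains, dtype=float)
    if trains.ndim != 2:
        raise ValueError("trains must be (time, N)")
    out = {}
    empty = np.flatnonzero(trains.sum(axis=0) == 0)
    for width in kernel_widths:
        sigma = width / dt
        smooth = gaussian_filter1d(trains, sigma=sigma, axis=0, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(smooth.T)
        c[empty, :] = np.nan
        c[:, empty] = np.nan
        out[width] = c
    return out


def tuning_curves(
    r: np.ndarray,
    theta: np.ndarray,
    n_bins: int = 36,
):
    """Per-neuron mean filtered activity in angle bins (default 10-degree bins).

    Returns (bin_centers, curves) with curves of shape (n_bins, N); bins that
    were never visited are nan, not interpolated.
    """
    r = np.asarray(r, dtype=float)
    theta = wrap_angle(np.asarray(theta, dtype=float))
    if r.shape[0] != theta.shape[0]:
        raise ValueError("activity and angle series must share a clock")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    curves = np.full((n_bins, r.shape[1]), np.nan)
    for b in range(n_bins):
        mask = idx == b
        if np.any(mask):
            curves[b] = r[mask].mean(axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, curves


@dataclass
class BumpVelocityStats:
    velocities: np.ndarray
    by_condition: pd.DataFrame      # mean / var / skew per omega condition
    scatter: pd.DataFrame           # (true omega, bump velocity) pairs


def bump_velocity_stats(
    theta_hat: np.ndarray,
    omega: np.ndarray,
    dt: float,
    stride: int = 1,
) -> BumpVelocityStats:
    """Wrapped finite-difference bump velocities, grouped by velocity condition.

    A wrap crossing (pi - eps -> -pi + eps) counts as a small positive step,
    never as a ~2*pi jump.  Conditions are the distinct values of the true
    omega series (rounded to 6 decimals); per condition the mean, variance,
    and skewness of the bump velocity are reported.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    omega = np.asarray(omega, dtype=float)
    th = theta_hat[::stride]
    om = omega[::stride][1:]
    vel = wrap_angle(np.diff(th)) / (dt * stride)
    cond = np.round(om, 6)
    frame = pd.DataFrame({"omega": cond, "velocity": vel})
    rows = []
    for value, group in frame.groupby("omega"):
        v = group["velocity"].to_numpy()
        rows.append(
            {
                "omega": value,
                "n": v.size,
                "mean": v.mean(),
                "var": v.var(),
                "skew": stats.skew(v) if v.size > 2 and v.var() > 0 else 0.0,
            }
        )
    return BumpVelocityStats(
        velocities=vel,
        by_condition=pd.DataFrame(rows),
        scatter=frame,
    )


def drift_curve(runs: np.ndarray):
    """Mean and standard-deviation band over time of per-repetition errors.

    ``runs`` is (repetitions, time) of shortest-arc angle errors; ragged
    inputs are rejected.
    """
    arr = np.asarray(runs, dtype=float)
    if arr.ndim != 2:
        raise ValueError("runs must be a rectangular (repetitions, time) array")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 repetitions")
    return arr.mean(axis=0), arr.std(axis=0)


def bump_localization(r: np.ndarray, d) -> float:
    """Mean resultant length of the population-activity profile.

    Activity r_i is treated as mass at each neuron's preferred angle; a value
    near 1 means a tight bump, near 0 a delocalized profile.
    """
    d_entries = d.entries if hasattr(d, "entries") else np.atleast_2d(np.asarray(d, float))
    angles = np.arctan2(d_entries[1], d_entries[0])
    r = np.asarray(r, dtype=float)
    weights = r.sum(axis=1)
    ok = weights > 0
    vec = r[ok] @ np.exp(1j * angles)
    return float(np.mean(np.abs(vec) / weights[ok]))


def tuning_heterogeneity(curves: np.ndarray) -> float:
    """Across-neuron dispersion of peak-aligned, normalized tuning curves.

    Curves are circularly rotated so each neuron's peak bin sits at zero and
    scaled to unit mean; the statistic is one minus the mean pairwise Pearson
    correlation of the aligned curves (0 for a homogeneous ring, larger when
    neurons develop idiosyncratic tuning).
    """
    curves = np.asarray(curves, dtype=float)
    n_bins, n = curves.shape
    aligned = np.empty_like(curves)
    for i in range(n):
        col = curves[:, i]
        if np.any(np.isnan(col)):
            col = np.where(np.isnan(col), np.nanmean(col), col)
        peak = int(np.argmax(col))
        shifted = np.roll(col, -peak)
        mean = shifted.mean()
        aligned[:, i] = shifted / mean if mean > 0 else shifted
    c = np.corrcoef(aligned.T)
    off = c[~np.eye(n, dtype=bool)]
    return float(1.0 - np.nanmean(off))
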