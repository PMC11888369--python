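"""Polynomial-dynamics machinery for multiplicative spike-coding networks.

A polynomial drift ``F(z) = sum_d A_d z^{(d)}`` (with ``z^{(d)}`` the d-fold
Kronecker power of the readout ``z``) can be embedded in neuron space because
the Kronecker mixed-product identity gives ``A_d (D r)^{(d)} = A_d D^{(d)}
r^{(d)}``.  This module provides the Kronecker helpers, a sparse
representation of multivariate polynomial energies ``U(z)``, their gradients
as per-degree coefficient matrices, and the materialized slow connectivity of
a multiplicative spike-coding network.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyPolynomial",
    "PolynomialDrift",
    "kron_power",
    "kron_power_vec",
    "g_vector",
    "grad_energy",
    "eval_drift",
    "build_slow_weights",
    "check_normalizable",
]


def kron_power(matrix: np.ndarray, d: int) -> np.ndarray:
    """d-fold Kronecker product of ``matrix`` with itself (row-major blocks)."""
    if d < 1:
        raise ValueError(f"Kronecker power requires d >= 1, got {d}")
    matrix = np.asarray(matrix, dtype=float)
    out = matrix
    for _ in range(d - 1):
        out = np.kron(out, matrix)
    return out


def kron_power_vec(v: np.ndarray, d: int) -> np.ndarray:
    """d-fold Kronecker power of a vector; length ``len(v)**d``."""
    if d < 1:
        raise ValueError(f"Kronecker power requires d >= 1, got {d}")
    v = np.asarray(v, dtype=float).ravel()
    out = v
    for _ in range(d - 1):
        out = np.kron(out, v)
    return out


def g_vector(r: np.ndarray, g: int) -> np.ndarray:
    """Stack all Kronecker powers r, r^{(2)}, ..., r^{(g)} into one vector."""
    if g < 1:
        raise ValueError(f"g_vector requires g >= 1, got {g}")
    r = np.asarray(r, dtype=float).ravel()
    return np.concatenate([kron_power_vec(r, d) for d in range(1, g + 1)])


def _flat_index(indices: tuple[int, ...], m: int) -> int:
    """Row-major flat position of a multi-index into the Kronecker basis."""
    idx = 0
    for i in indices:
        idx = idx * m + i
    return idx


@dataclass
class EnergyPolynomial:
    """A multivariate polynomial energy U(z) defining P(z) ~ exp(-U(z)).

    Parameters
    ----------
    m:
        Dimension of the variable z.
    terms:
        Mapping from exponent multi-indices (length-m integer tuples) to real
        coefficients.  ``{(4,): 1.0, (2,): -2.0}`` is the bimodal
        ``U(z) = z**4 - 2 z**2``.
    """

    m: int
    terms: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[int, ...], float] = {}
        for expo, coeff in self.terms.items():
            expo = tuple(int(e) for e in expo)
            if len(expo) != self.m:
                raise ValueError(
                    f"exponent tuple {expo} does not match dimension m={self.m}"
                )
            if any(e < 0 for e in expo):
                raise ValueError(f"negative exponent in {expo}")
            if coeff != 0.0:
                clean[expo] = clean.get(expo, 0.0) + float(coeff)
        self.terms = clean

    @property
    def degree(self) -> int:
        return max((sum(e) for e in self.terms), default=0)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.ndim == 0:
            z = z.reshape(1)
        batch = z.reshape(-1, self.m)
        out = np.zeros(batch.shape[0])
        for expo, coeff in self.terms.items():
            term = np.full(batch.shape[0], coeff)
            for axis, e in enumerate(expo):
                if e:
                    term *= batch[:, axis] ** e
            out += term
        return out[0] if batch.shape[0] == 1 else out

    def gradient_terms(self) -> list[dict[tuple[int, ...], float]]:
        """Term tables of dU/dz_k for each component k."""
        grads: list[dict[tuple[int, ...], float]] = [{} for _ in range(self.m)]
        for expo, coeff in self.terms.items():
            for k, e in enumerate(expo):
                if e == 0:
                    continue
                new = list(expo)
                new[k] = e - 1
                key = tuple(new)
                grads[k][key] = grads[k].get(key, 0.0) + coeff * e
        return grads

    def shifted(self, constant: float) -> "EnergyPolynomial":
        """U + constant (same distribution after normalization)."""
        terms = dict(self.terms)
        zero = (0,) * self.m
        terms[zero] = terms.get(zero, 0.0) + constant
        return EnergyPolynomial(self.m, terms)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        records = [
            {"exponents": list(expo), "coeff": coeff}
            for expo, coeff in sorted(self.terms.items())
        ]
        return json.dumps({"m": self.m, "terms": records}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EnergyPolynomial":
        data = json.loads(text)
        terms = {
            tuple(rec["exponents"]): float(rec["coeff"]) for rec in data["terms"]
        }
        return cls(int(data["m"]), terms)


@dataclass
class PolynomialDrift:
    """A polynomial map F(z) = sum_{d=0..g} A_d z^{(d)}.

    ``coeffs[d]`` is the (m, m**d) matrix A_d; ``coeffs[0]`` is the constant
    column A_0 of shape (m, 1).
    """

    m: int
    coeffs: list[np.ndarray]

    def __post_init__(self) -> None:
        fixed = []
        for d, a in enumerate(self.coeffs):
            a = np.atleast_2d(np.asarray(a, dtype=float))
            expected = (self.m, self.m**d)
            if a.shape != expected:
                raise ValueError(
                    f"A_{d} has shape {a.shape}, expected {expected}"
                )
            fixed.append(a)
        self.coeffs = fixed
        # scalar fast path: plain 1-D polynomial coefficients, low degree first
        if self.m == 1:
            self._coeffs_1d = np.array([a[0, 0] for a in self.coeffs])
        else:
            self._coeffs_1d = None

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float).ravel()
        if z.shape[0] != self.m:
            raise ValueError(f"z has length {z.shape[0]}, expected {self.m}")
        if self._coeffs_1d is not None:
            # Horner evaluation for the common 1-D case
            acc = 0.0
            for c in self._coeffs_1d[::-1]:
                acc = acc * z[0] + c
            return np.array([acc])
        out = self.coeffs[0][:, 0].copy()
        for d in range(1, len(self.coeffs)):
            out += self.coeffs[d] @ kron_power_vec(z, d)
        return out


def grad_energy(u: EnergyPolynomial) -> PolynomialDrift:
    """Coefficient matrices of the gradient of a polynomial energy.

    Each monomial of dU/dz_k of total degree d is assigned to its canonical
    (sorted, row-major) slot in the Kronecker basis, so evaluating the result
    with :func:`eval_drift` reproduces the analytic gradient exactly.
    """
    if u.degree < 1:
        raise ValueError("constant energy has a degenerate (zero) gradient")
    g = u.degree - 1
    coeffs = [np.zeros((u.m, u.m**d)) for d in range(g + 1)]
    for k, table in enumerate(u.gradient_terms()):
        for expo, coeff in table.items():
            d = sum(expo)
            indices = tuple(
                itertools.chain.from_iterable([axis] * e for axis, e in enumerate(expo))
            )
            coeffs[d][k, _flat_index(indices, u.m)] += coeff
    return PolynomialDrift(u.m, coeffs)


def eval_drift(drift: PolynomialDrift, z: np.ndarray) -> np.ndarray:
    """Evaluate ``sum_d A_d z^{(d)}`` at a point."""
    return drift(z)


@dataclass
class SlowWeights:
    """Materialized per-degree slow connectivity of a multiplicative SCN.

    ``matrices[d]`` acts on the d-fold Kronecker power of the filtered spike
    train r; ``matrices[0]`` is a constant current.  The drift they implement
    is ``D^T(-(1/tau_s) * F(D r) + lambda * D r)`` with F the energy gradient.
    """

    matrices: list[np.ndarray]

    def apply(self, r: np.ndarray) -> np.ndarray:
        out = self.matrices[0][:, 0].copy()
        for d in range(1, len(self.matrices)):
            out += self.matrices[d] @ kron_power_vec(r, d)
        return out


def build_slow_weights(
    d_matrix: np.ndarray,
    drift: PolynomialDrift,
    lambda_leak: float,
    tau_s: float,
) -> SlowWeights:
    """Per-degree slow weights for sampling drift in neuron space.

    The degree-d block is ``-(1/tau_s) D^T A_d D^{(d)}``; the linear block
    additionally folds in the ``+lambda D^T D`` leak compensation required so
    that the readout, not the voltage, follows the Langevin drift.
    """
    d_matrix = np.atleast_2d(np.asarray(d_matrix, dtype=float))
    m, n = d_matrix.shape
    if drift.m != m:
        raise ValueError(
            f"drift dimension {drift.m} does not match readout dimension {m}"
        )
    mats: list[np.ndarray] = []
    for deg, a_d in enumerate(drift.coeffs):
        if deg == 0:
            mats.append(-(1.0 / tau_s) * d_matrix.T @ a_d)
        elif deg == 1:
            core = -(1.0 / tau_s) * a_d + lambda_leak * np.eye(m)
            mats.append(d_matrix.T @ core @ d_matrix)
        else:
            mats.append(
                -(1.0 / tau_s) * d_matrix.T @ a_d @ kron_power(d_matrix, deg)
            )
    if len(mats) == 1:  # degree-0 drift still needs the leak-compensation term
        mats.append(lambda_leak * d_matrix.T @ d_matrix)
    return SlowWeights(mats)


def check_normalizable(u: EnergyPolynomial, grid_half_widths=(4.0, 8.0, 16.0)) -> bool:
    """Whether exp(-U) has a finite integral.

    In one dimension this is decided analytically: the top degree must be even
    with a positive coefficient.  In higher dimensions the integral of
    exp(-U) is evaluated on expanding grids and must stay finite and stop
    growing.
    """
    if not u.terms or u.degree < 1:
        return False
    if u.m == 1:
        top = u.degree
        lead = sum(c for e, c in u.terms.items() if sum(e) == top)
        return top % 2 == 0 and lead > 0
    if u.m > 3:
        raise ValueError("numerical normalizability check supports m <= 3")
    pts = 81 if u.m == 2 else 41
    prev = None
    for half in grid_half_widths:
        axes = [np.linspace(-half, half, pts)] * u.m
        mesh = np.meshgrid(*axes, indexing="ij")
        zs = np.stack([a.ravel() for a in mesh], axis=-1)
        vals = np.exp(-np.clip(u(zs), -700, 700))
        if not np.all(np.isfinite(vals)):
            return False
        step = (2 * half / (pts - 1)) ** u.m
        total = float(vals.sum() * step)
        if not np.isfinite(total):
            return False
        if prev is not None and total > prev * 1.5 + 1e-12:
            return False
        prev = total
    return True
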