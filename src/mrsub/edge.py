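"""Closed-form single-branch estimators and their discrete-chain oracle.

For a branch of length ``t`` with start state ``b`` (time 0) and end state
``a`` (time ``t``), conditioning on both endpoints:

* ``tmrs_edge``            E[T], T the time from the branch end back to the
  most recent substitution (``T = t`` when the path has none),
* ``second_moment_edge``   E[T^2],
* ``sigma_edge``           sqrt(E[T^2] - E[T]^2),
* ``q_edge``               P(no substitution at all).

``discrete_chain_oracle`` evaluates the same quantities exactly in the
N-step discrete approximation ``Q = I + tR/N`` and converges to the closed
forms as N grows; it is kept deliberately independent of the kernel-based
code paths.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .rates import RateModel, base_index, kernel_K, kernel_K_prime, realify

__all__ = [
    "EdgeProblem",
    "tmrs_edge",
    "second_moment_edge",
    "sigma_edge",
    "q_edge",
    "discrete_chain_oracle",
]


class UnreachableEndpointError(ValueError):
    """The endpoint pair has zero probability (Z = 0)."""


@dataclasses.dataclass(frozen=True)
class EdgeProblem:
    a: int | str  # observed base at the branch end (time t)
    b: int | str  # base at the branch start (time 0)
    t: float
    model: RateModel

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("branch length must be non-negative")

    @property
    def ai(self) -> int:
        return base_index(self.a)

    @property
    def bi(self) -> int:
        return base_index(self.b)


#: below this the endpoint pair is treated as unreachable (Z = 0)
_Z_FLOOR = 1e-14


def _spectral_parts(p: EdgeProblem):
    m = p.model
    a, b = p.ai, p.bi
    lam = m.eigenvalues
    w = m.U[a] * m.U_inv[:, b]  # U_ai * Uinv_ib over eigenindex i
    Z = complex(np.sum(w * np.exp(p.t * lam)))
    return m, a, b, lam, w, Z


def likelihood_edge(p: EdgeProblem) -> float:
    """``Z = [expm(tR)]_{ab}``."""
    *_, Z = _spectral_parts(p)
    return realify(Z)


def tmrs_edge(p: EdgeProblem) -> float:
    m, a, b, lam, w, Z = _spectral_parts(p)
    Zr = realify(Z)
    if Zr <= _Z_FLOOR:
        raise UnreachableEndpointError("endpoint pair has zero probability")
    x = p.t * m.rdiag[a]
    acc = sum(wi * kernel_K(complex(x), p.t * li) for wi, li in zip(w, lam))
    return p.t * realify(acc, tol=1e-8) / Zr


def second_moment_edge(p: EdgeProblem) -> float:
    """``E[T^2] = (2 t^2 / Z) sum_i U_ai Uinv_ib K'(t R_Daa, t lambda_i)``.

    (The ``t^2`` factor follows from ``E[T^2] = 2 t^2 int_0^1 s
    [e^{s t R_D} e^{(1-s) t R}]_{ab} ds / Z``; it makes the small-``t``
    limits ``E[T^2] -> t^2`` (a = b) and ``t^2/3`` (a != b) come out right.)
    """
    m, a, b, lam, w, Z = _spectral_parts(p)
    Zr = realify(Z)
    if Zr <= _Z_FLOOR:
        raise UnreachableEndpointError("endpoint pair has zero probability")
    x = p.t * m.rdiag[a]
    acc = sum(wi * kernel_K_prime(complex(x), p.t * li) for wi, li in zip(w, lam))
    return 2.0 * p.t * p.t * realify(acc, tol=1e-8) / Zr


def sigma_edge(p: EdgeProblem) -> float:
    mean = tmrs_edge(p)
    m2 = second_moment_edge(p)
    var = m2 - mean * mean
    if var < -1e-12 * max(1.0, m2):
        raise FloatingPointError(f"negative variance {var}")
    return float(np.sqrt(max(var, 0.0)))


def q_edge(p: EdgeProblem) -> float:
    if p.ai != p.bi:
        return 0.0
    Zr = likelihood_edge(p)
    if Zr <= _Z_FLOOR:
        raise UnreachableEndpointError("endpoint pair has zero probability")
    return float(np.exp(p.t * realify(p.model.rdiag[p.ai])) / Zr)


def discrete_chain_oracle(p: EdgeProblem, N: int) -> tuple[float, float, float]:
    """Exact (E[T], E[T^2], q) of the N-step discrete chain ``Q = I + tR/N``.

    Uses ``[Q_D^l Q^{N-l}]_{ab} = (Q_aa)^l [Q^{N-l}]_{ab}`` and the spectral
    form of ``Q`` powers; requires ``Q`` to be a stochastic matrix.
    """
    if N < 10:
        raise ValueError("need at least 10 steps")
    m, a, b = p.model, p.ai, p.bi
    Q = np.eye(4) + p.t * m.R / N
    if np.any(Q < 0):
        raise ValueError("t * max|R_ii| / N >= 1; increase N")
    mu = 1.0 + p.t * m.eigenvalues / N  # eigenvalues of Q
    w = m.U[a] * m.U_inv[:, b]
    qaa = Q[a, a]

    ls = np.arange(1, N + 1)
    # [Q^{N-l}]_{ab} for l = 1..N
    powers = np.power(mu[None, :], (N - ls)[:, None])
    q_tail = realify(powers @ w, tol=1e-7)
    weights = qaa**ls * q_tail  # P(run >= l, endpoints) unnormalised
    Z = realify(np.sum(w * mu**N), tol=1e-7)
    if Z <= _Z_FLOOR:
        raise UnreachableEndpointError("endpoint pair has zero probability")
    dt = p.t / N
    e_t = dt * np.sum(weights) / Z
    e_t2 = dt * dt * np.sum((2 * ls - 1) * weights) / Z
    q = (qaa**N if a == b else 0.0) / Z
    return float(e_t), float(e_t2), float(q)
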