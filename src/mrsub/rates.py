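"""Substitution rate matrices and the exponential-integral kernels.

Generator convention used throughout the package: ``R[a, i]`` is the
instantaneous rate of the substitution ``i -> a``, i.e. *columns* are indexed
by the source state.  Every column of ``R`` then sums to zero and state
probabilities evolve as ``p(t) = expm(t R) @ p(0)``, so
``p(a | b, t) = [expm(t R)]_{ab}``.

Two parameterisations are provided:

* a six-parameter strand-symmetric model, invariant under complementing
  both endpoint states (``R[comp(a), comp(b)] == R[a, b]``);
* a general time-reversible (GTR) model given six exchangeabilities and a
  base-frequency vector.

The eigensystem of a strand-symmetric generator is generally complex; all
spectral computations are carried out in complex arithmetic and the final
probabilities/expectations are checked to have negligible imaginary part
before the real part is returned.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "NUCLEOTIDES",
    "COMPLEMENT",
    "RateModel",
    "base_index",
    "complement_index",
    "kernel_K",
    "kernel_K_prime",
    "build_strand_symmetric",
    "build_gtr",
    "build_jukes_cantor",
    "normalize_model",
    "titv_ratio",
    "default_model",
    "read_model",
    "write_model",
]

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
#: complement permutation on state indices (A<->T, C<->G)
COMPLEMENT = np.array([3, 2, 1, 0])

# |x - y| below which the kernels switch to their series/limit branch
_SERIES_SWITCH = 1e-4
# tolerated imaginary part when realifying spectral results
_IMAG_TOL = 1e-9


class DegenerateModelError(ValueError):
    """Raised when a rate matrix has no substitution activity at all."""


def base_index(a) -> int:
    """Return the 0..3 state index for a base given as a letter or an int."""
    if isinstance(a, (int, np.integer)):
        if not 0 <= int(a) <= 3:
            raise ValueError(f"base index out of range: {a}")
        return int(a)
    try:
        return NUC_INDEX[str(a).upper()]
    except KeyError:
        raise ValueError(f"not an unambiguous nucleotide: {a!r}") from None


def complement_index(i: int) -> int:
    return int(COMPLEMENT[base_index(i)])


def _as_complex(x):
    return complex(x)


def _maybe_real(out, *args):
    if all(not isinstance(a, complex) and not np.iscomplexobj(a) for a in args):
        return float(out.real)
    return out


def kernel_K(x, y):
    """``K(x, y) = \\int_0^1 exp(s*x) * exp((1-s)*y) ds``.

    Equals ``(e^x - e^y) / (x - y)`` for ``x != y`` and ``e^x`` at ``x == y``.
    A short series in ``x - y`` is used near the diagonal to avoid
    catastrophic cancellation.  Accepts real or complex scalars.
    """
    xr, yr = x, y
    x = _as_complex(x)
    y = _as_complex(y)
    d = x - y
    if abs(d) < _SERIES_SWITCH:
        # e^y * sum_{n>=0} d^n / (n+1)!
        acc = 0.0 + 0.0j
        fact = 1.0
        for n in range(9):
            fact *= n + 1  # (n+1)!
            acc += d**n / fact
        out = np.exp(y) * acc
    else:
        out = (np.exp(x) - np.exp(y)) / d
    return _maybe_real(out, xr, yr)


def kernel_K_prime(x, y):
    """Partial derivative of :func:`kernel_K` with respect to ``x``.

    ``K'(x, y) = \\int_0^1 s * exp(s*x) * exp((1-s)*y) ds``; the analytic
    limit at ``x == y`` is ``e^x / 2``.
    """
    xr, yr = x, y
    x = _as_complex(x)
    y = _as_complex(y)
    d = x - y
    if abs(d) < _SERIES_SWITCH:
        # e^y * sum_{n>=1} n * d^(n-1) / (n+1)!
        acc = 0.0 + 0.0j
        fact = 1.0
        for n in range(9):
            fact *= n + 1
            if n >= 1:
                acc += n * d ** (n - 1) / fact
        out = np.exp(y) * acc
    else:
        ex = np.exp(x)
        out = (ex * d - (ex - np.exp(y))) / (d * d)
    return _maybe_real(out, xr, yr)


def realify(value, tol: float = _IMAG_TOL):
    """Drop a numerically negligible imaginary part, else raise."""
    arr = np.asarray(value)
    if np.iscomplexobj(arr):
        imax = float(np.max(np.abs(arr.imag))) if arr.size else 0.0
        scale = max(1.0, float(np.max(np.abs(arr.real)))) if arr.size else 1.0
        if imax > tol * scale:
            raise FloatingPointError(
                f"imaginary part {imax:.3e} exceeds tolerance {tol:.1e}"
            )
        arr = arr.real
    if arr.ndim == 0:
        return float(arr)
    return np.ascontiguousarray(arr, dtype=float)


@dataclasses.dataclass(frozen=True)
class RateModel:
    """A 4-state substitution generator with its spectral decomposition.

    Attributes
    ----------
    R : (4, 4) ndarray
        Generator; ``R[a, i]`` is the rate of ``i -> a``, columns sum to 0.
    U, eigenvalues, U_inv : complex ndarrays
        Eigendecomposition ``R = U diag(eigenvalues) U_inv``.
    pi : (4,) ndarray
        Equilibrium distribution (``R @ pi = 0``, ``sum(pi) = 1``).
    kind : str
        ``"symmetric"``, ``"gtr"`` or ``"custom"``.
    params : tuple or None
        The native parameters the model was built from, if any.
    """

    R: np.ndarray
    U: np.ndarray
    eigenvalues: np.ndarray
    U_inv: np.ndarray
    pi: np.ndarray
    kind: str = "custom"
    params: tuple | None = None

    # -- derived views ----------------------------------------------------
    @property
    def rdiag(self) -> np.ndarray:
        """Diagonal of the generator (entries of ``R_D``)."""
        return np.diag(self.R)

    @property
    def expected_rate(self) -> float:
        """Expected number of substitutions per unit time at equilibrium."""
        return float(-np.sum(self.pi * self.rdiag))

    # -- core operations --------------------------------------------------
    def transition_matrix(self, t: float) -> np.ndarray:
        """``expm(t R)`` computed through the eigendecomposition.

        Columns sum to one; tiny negative round-off entries are clipped to
        zero and the columns renormalised (larger deviations raise).
        """
        if t < 0:
            raise ValueError("time must be non-negative")
        P = realify(self.U @ np.diag(np.exp(t * self.eigenvalues)) @ self.U_inv)
        low = float(P.min())
        if low < -1e-9:
            raise FloatingPointError(f"transition matrix entry {low} < -1e-9")
        if low < 0:
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=0, keepdims=True)
        return P

    def no_substitution_prob(self, a, t: float) -> float:
        """Probability of dwelling in state ``a`` for time ``t`` (no jumps)."""
        if t < 0:
            raise ValueError("time must be non-negative")
        return float(np.exp(t * realify(self.rdiag[base_index(a)])))

    def is_strand_symmetric(self, tol: float = 1e-10) -> bool:
        Rc = self.R[np.ix_(COMPLEMENT, COMPLEMENT)]
        return bool(np.allclose(Rc, self.R, atol=tol))

    def normalized(self) -> "RateModel":
        return normalize_model(self)

    def scaled(self, c: float) -> "RateModel":
        """Return the model with all rates multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale must be positive")
        params = None
        if self.params is not None and self.kind == "symmetric":
            params = tuple(c * p for p in self.params)
        elif self.params is not None and self.kind == "gtr":
            rates, pi = self.params
            params = (tuple(c * r for r in rates), pi)
        return RateModel(
            R=c * self.R,
            U=self.U,
            eigenvalues=c * self.eigenvalues,
            U_inv=self.U_inv,
            pi=self.pi,
            kind=self.kind,
            params=params,
        )


def _finish(R: np.ndarray, kind: str, params) -> RateModel:
    R = np.asarray(R, dtype=float)
    if R.shape != (4, 4):
        raise ValueError("rate matrix must be 4x4")
    off = R[~np.eye(4, dtype=bool)]
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    col = R.sum(axis=0)
    if not np.allclose(col, 0.0, atol=1e-10):
        raise ValueError("columns of the generator must sum to zero")
    if np.allclose(R, 0.0):
        raise DegenerateModelError("all substitution rates are zero")

    lam, U = np.linalg.eig(R.astype(complex))
    U_inv = np.linalg.inv(U)
    recon = U @ np.diag(lam) @ U_inv
    err = float(np.max(np.abs(recon - R)))
    if err > 1e-8 * max(1.0, float(np.max(np.abs(R)))):
        raise FloatingPointError(f"eigendecomposition reconstruction error {err}")

    ns = null_space(R)
    if ns.shape[1] != 1:
        raise DegenerateModelError("generator has a multi-dimensional null space")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-12):
        raise ValueError("equilibrium distribution has negative entries")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return RateModel(R=R, U=U, eigenvalues=lam, U_inv=U_inv, pi=pi, kind=kind, params=params)


def build_strand_symmetric(alpha, beta, gamma, delta, epsilon, eta) -> RateModel:
    """Build the six-parameter strand-symmetric model.

    Off-diagonal layout (rows/columns ordered A, C, G, T; entry ``(a, b)`` is
    the rate of ``b -> a``)::

        .      alpha  beta   gamma
        eta    .      delta  epsilon
        epsilon delta .      eta
        gamma  beta   alpha  .

    so e.g. ``alpha`` is the rate of ``C -> A`` (and of ``G -> T``).
    """
    params = (alpha, beta, gamma, delta, epsilon, eta)
    if any(p < 0 for p in params):
        raise ValueError("rates must be non-negative")
    if all(p == 0 for p in params):
        raise DegenerateModelError("at least one rate must be positive")
    a, b, g, d, e, h = (float(p) for p in params)
    R = np.array(
        [
            [0.0, a, b, g],
            [h, 0.0, d, e],
            [e, d, 0.0, h],
            [g, b, a, 0.0],
        ]
    )
    R[np.diag_indices(4)] = -R.sum(axis=0)
    return _finish(R, "symmetric", tuple(float(p) for p in params))


def build_gtr(rates, pi) -> RateModel:
    """Build a GTR model from six exchangeabilities and base frequencies.

    ``rates = (alpha, beta, gamma, delta, epsilon, eta)`` scale the pairs
    (A,C), (A,G), (A,T), (C,G), (C,T), (G,T); the rate of ``b -> a`` is
    ``pi_a * rate_{ab}`` so that detailed balance holds and ``pi`` is the
    stationary distribution.
    """
    rates = tuple(float(r) for r in rates)
    pi = np.asarray(pi, dtype=float)
    if len(rates) != 6 or any(r < 0 for r in rates):
        raise ValueError("need six non-negative exchangeabilities")
    if pi.shape != (4,) or np.any(pi <= 0):
        raise ValueError("pi must be four positive frequencies")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must sum to 1")
    if all(r == 0 for r in rates):
        raise DegenerateModelError("at least one rate must be positive")
    a, b, g, d, e, h = rates
    pA, pC, pG, pT = pi
    R = np.array(
        [
            [0.0, pA * a, pA * b, pA * g],
            [pC * a, 0.0, pC * d, pC * e],
            [pG * b, pG * d, 0.0, pG * h],
            [pT * g, pT * e, pT * h, 0.0],
        ]
    )
    R[np.diag_indices(4)] = -R.sum(axis=0)
    return _finish(R, "gtr", (rates, tuple(pi)))


def build_jukes_cantor(mu: float = 1.0 / 3.0) -> RateModel:
    """All substitutions at rate ``mu`` (expected rate ``3 mu``)."""
    return build_strand_symmetric(mu, mu, mu, mu, mu, mu)


def titv_ratio(model: RateModel) -> float:
    """Mean of the two transition rates over the mean of the four
    transversion rates of a strand-symmetric model (unweighted averages)."""
    if model.kind != "symmetric" or model.params is None:
        raise ValueError("titv_ratio is defined for strand-symmetric models")
    a, b, g, d, e, h = model.params
    transitions = (b + e) / 2.0  # A<->G, C<->T
    transversions = (a + g + d + h) / 4.0
    return transitions / transversions


def normalize_model(model: RateModel) -> RateModel:
    """Rescale so the equilibrium substitution rate is one per unit time."""
    return model.scaled(1.0 / model.expected_rate)


# -- plain-text serialisation ---------------------------------------------

_PARAM_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "eta")


def write_model(model: RateModel, path) -> None:
    if model.kind not in ("symmetric", "gtr") or model.params is None:
        raise ValueError("only parameterised models can be serialised")
    lines = [f"kind={model.kind}"]
    if model.kind == "symmetric":
        for name, value in zip(_PARAM_NAMES, model.params):
            lines.append(f"{name}={float(value)!r}")
    else:
        rates, pi = model.params
        for name, value in zip(_PARAM_NAMES, rates):
            lines.append(f"{name}={float(value)!r}")
        for name, value in zip("ACGT", pi):
            lines.append(f"pi_{name}={float(value)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_kv(text: str) -> dict:
    out = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed model line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_model(path) -> RateModel:
    kv = _parse_kv(Path(path).read_text())
    kind = kv.get("kind", "symmetric")
    rates = tuple(float(kv[name]) for name in _PARAM_NAMES)
    if kind == "symmetric":
        model = build_strand_symmetric(*rates)
    elif kind == "gtr":
        pi = tuple(float(kv[f"pi_{b}"]) for b in "ACGT")
        model = build_gtr(rates, pi)
    else:
        raise ValueError(f"unknown model kind: {kind}")
    if kv.get("normalize", "false").lower() in ("1", "true", "yes"):
        model = normalize_model(model)
    return model


def default_model() -> RateModel:
    """The packaged default strand-symmetric parameters."""
    text = resources.files("mrsub.data").joinpath("default_rates.txt").read_text()
    kv = _parse_kv(text)
    rates = tuple(float(kv[name]) for name in _PARAM_NAMES)
    return build_strand_symmetric(*rates)
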