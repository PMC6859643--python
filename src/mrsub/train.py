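"""Maximum-likelihood training of rate parameters and branch lengths.

The topology is fixed; the free parameters are the six strand-symmetric
rates and the length of every non-root branch.  The log-likelihood of a
multiset of alignment columns is the sum over columns of ``log Z``, with
duplicate columns collapsed to counts.  Gradients are exact:

* branch lengths -- ``dZ/dt_n = sum_ij alpha(n, j) [R expm(t_n R)]_{ji}
  beta(n, i)``,
* rate parameters -- via the Frechet derivative of each edge's matrix
  exponential plus the derivative of the root equilibrium ``pi``.

The likelihood is invariant under ``(R, t) -> (cR, t/c)``; the fitted model
is therefore rescaled afterwards so that the equilibrium substitution rate
is one, branch lengths absorbing the scale.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm, expm_frechet, lstsq
from scipy.optimize import minimize

from .engine import symbol_to_vector
from .rates import NUC_INDEX, RateModel, build_strand_symmetric
from .tree import PhyloTree

__all__ = ["TrainingProblem", "FitResult", "relative_difference", "fit"]

_LOG_BOUNDS = (np.log(1e-6), np.log(1e3))

# basis matrices dR/dtheta_m for the six strand-symmetric parameters
def _sym_basis() -> np.ndarray:
    basis = np.zeros((6, 4, 4))
    layout = [  # (param, row, col) of off-diagonal placements
        (0, 0, 1), (0, 3, 2),  # alpha: C->A, G->T
        (1, 0, 2), (1, 3, 1),  # beta:  G->A, C->T
        (2, 0, 3), (2, 3, 0),  # gamma: T->A, A->T
        (3, 1, 2), (3, 2, 1),  # delta: G->C, C->G
        (4, 1, 3), (4, 2, 0),  # epsilon: T->C, A->G
        (5, 1, 0), (5, 2, 3),  # eta:   A->C, T->G
    ]
    for m, i, j in layout:
        basis[m, i, j] = 1.0
    for m in range(6):
        np.fill_diagonal(basis[m], 0.0)
        basis[m][np.diag_indices(4)] = -basis[m].sum(axis=0)
    return basis


_BASIS = _sym_basis()


def dedupe_columns(columns: Sequence[Mapping[str, str]], leaf_names: list[str]):
    """Collapse identical columns; returns (colmat, counts).

    ``colmat`` has shape (n_unique, n_leaves, 4) of leaf inside vectors.
    """
    seen: dict[tuple, int] = {}
    counts: list[int] = []
    vecs: list[np.ndarray] = []
    for col in columns:
        key = tuple(
            col.get(name, "-").upper() if col.get(name, "-").upper() in NUC_INDEX else "-"
            for name in leaf_names
        )
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(vecs)
            counts.append(1)
            vecs.append(np.stack([symbol_to_vector(s) for s in key]))
    return np.stack(vecs), np.asarray(counts, dtype=float)


@dataclasses.dataclass
class TrainingProblem:
    """Fixed topology + observed columns; parameter vector is
    ``theta = (alpha..eta, t_n for every non-root node in index order)``."""

    tree: PhyloTree
    columns: Sequence[Mapping[str, str]]

    def __post_init__(self):
        self.leaf_names = self.tree.leaf_names
        self.leaf_nodes = self.tree.leaf_indices()
        self.edges = [n for n in range(self.tree.n_nodes) if int(self.tree.parent[n]) >= 0]
        self.colmat, self.counts = dedupe_columns(self.columns, self.leaf_names)
        self.n_columns = int(self.counts.sum())

    @property
    def n_params(self) -> int:
        return 6 + len(self.edges)

    def initial_theta(self) -> np.ndarray:
        return np.concatenate([np.full(6, 0.25), self.tree.lengths[self.edges]])

    def theta_from(self, model: RateModel, tree: PhyloTree | None = None) -> np.ndarray:
        tree = tree or self.tree
        return np.concatenate([np.asarray(model.params), tree.lengths[self.edges]])

    def unpack(self, theta: np.ndarray) -> tuple[RateModel, np.ndarray]:
        model = build_strand_symmetric(*theta[:6])
        lengths = np.zeros(self.tree.n_nodes)
        lengths[self.edges] = theta[6:]
        return model, lengths

    # -- likelihood and gradient ------------------------------------------
    def _tables(self, model: RateModel, lengths: np.ndarray):
        tree = self.tree
        ncols = self.colmat.shape[0]
        P = {n: expm(lengths[n] * model.R) for n in self.edges}
        alpha = np.empty((tree.n_nodes, ncols, 4))
        leaf_pos = {n: i for i, n in enumerate(self.leaf_nodes)}
        for n in tree.postorder():
            if tree.is_leaf(n):
                alpha[n] = self.colmat[:, leaf_pos[n], :]
            else:
                a, b = tree.children[n]
                alpha[n] = (alpha[a] @ P[a]) * (alpha[b] @ P[b])
        Z = alpha[tree.root] @ model.pi
        return P, alpha, Z

    def _outside(self, model, P, alpha):
        tree = self.tree
        beta = np.empty_like(alpha)
        root = tree.root
        for n in tree.preorder():
            if tree.is_leaf(n):
                continue
            a, b = tree.children[n]
            gamma_a = alpha[a] @ P[a]
            gamma_b = alpha[b] @ P[b]
            up = model.pi[None, :] if n == root else beta[n] @ P[n].T
            beta[a] = gamma_b * up
            beta[b] = gamma_a * up
        return beta

    def log_likelihood(self, theta: np.ndarray) -> float:
        model, lengths = self.unpack(theta)
        _, _, Z = self._tables(model, lengths)
        if np.any(Z <= 0) or not np.all(np.isfinite(Z)):
            bad = int(np.argmin(Z))
            raise FloatingPointError(f"non-finite likelihood at column {bad}")
        return float(self.counts @ np.log(Z))

    def gradient(self, theta: np.ndarray) -> np.ndarray:
        """Exact ``d log L / d theta``."""
        model, lengths = self.unpack(theta)
        P, alpha, Z = self._tables(model, lengths)
        beta = self._outside(model, P, alpha)
        wz = self.counts / Z  # per-column weight of dZ contributions

        grad = np.zeros(self.n_params)
        dpis = _dpi(model)  # (6, 4)
        grad[:6] += wz @ (alpha[self.tree.root] @ dpis.T)
        for e, n in enumerate(self.edges):
            a_n, b_n = alpha[n], beta[n]
            # branch length derivative
            dP_t = model.R @ P[n]
            grad[6 + e] = wz @ np.einsum(
                "cj,ji,ci->c", a_n, dP_t, b_n, optimize=True
            )
            # rate parameter derivatives via the Frechet derivative
            for m in range(6):
                dP = expm_frechet(
                    lengths[n] * model.R, lengths[n] * _BASIS[m], compute_expm=False
                )
                grad[m] += wz @ np.einsum("cj,ji,ci->c", a_n, dP, b_n, optimize=True)
        return grad


def _dpi(model: RateModel) -> np.ndarray:
    """d pi / d theta_m for the six rate parameters.

    Differentiates ``R pi = 0, 1'pi = 1``: solve ``[R; 1'] dpi = [-B pi; 0]``.
    """
    A = np.vstack([model.R, np.ones((1, 4))])
    out = np.empty((6, 4))
    for m in range(6):
        rhs = np.concatenate([-_BASIS[m] @ model.pi, [0.0]])
        sol, *_ = lstsq(A, rhs)
        out[m] = sol
    return out


@dataclasses.dataclass(frozen=True)
class FitResult:
    model: RateModel      # normalised to unit equilibrium rate
    tree: PhyloTree       # branch lengths in substitutions/site
    theta: np.ndarray     # normalised parameter vector
    log_likelihood: float
    converged: bool
    n_iterations: int
    message: str


def fit(
    problem: TrainingProblem,
    init_theta: np.ndarray | None = None,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """L-BFGS-B over log-transformed parameters.

    ``seed`` only randomises the initial point (when ``init_theta`` is not
    given); the optimisation itself is deterministic.
    """
    if init_theta is None:
        init_theta = problem.initial_theta()
        if seed is not None:
            rng = np.random.default_rng(seed)
            init_theta = init_theta * np.exp(rng.uniform(-1.0, 1.0, init_theta.shape))
    x0 = np.log(np.clip(init_theta, np.exp(_LOG_BOUNDS[0]), np.exp(_LOG_BOUNDS[1])))

    def objective(x):
        theta = np.exp(x)
        try:
            ll = problem.log_likelihood(theta)
            g = problem.gradient(theta)
        except FloatingPointError:
            return np.inf, np.zeros_like(x)
        return -ll, -(g * theta)

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[_LOG_BOUNDS] * len(x0),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
    )
    theta = np.exp(res.x)
    model, lengths = problem.unpack(theta)
    # fix the scale: unit equilibrium substitution rate
    c = model.expected_rate
    model = model.scaled(1.0 / c)
    lengths = lengths * c
    theta_norm = np.concatenate([np.asarray(model.params), lengths[problem.edges]])
    fitted_tree = dataclasses.replace(problem.tree, lengths=lengths)
    return FitResult(
        model=model,
        tree=fitted_tree,
        theta=theta_norm,
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        message=str(res.message),
    )


def relative_difference(theta1, theta2) -> float:
    """``|theta1 - theta2| / max(|theta1|, |theta2|)`` (Euclidean norms)."""
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("parameter vectors must have equal length")
    denom = max(np.linalg.norm(t1), np.linalg.norm(t2))
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(t1 - t2) / denom)
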