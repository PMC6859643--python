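"""Exact per-column estimates on a phylogenetic tree.

For an alignment column ``Y`` and a target leaf, :class:`TreeEngine`
computes, by dynamic programming over the tree:

* ``Z``        -- the column likelihood,
* ``t_mrs``    -- the posterior expected time back to the most recent
  substitution on the target leaf-to-root lineage,
* ``sigma``    -- its posterior standard deviation,
* ``q``        -- the posterior probability of no substitution anywhere on
  the lineage (in which case the time is defined as the full path length).

The expectation decomposes over lineage edges.  For edge ``k`` (from
concestor ``c_{k-1}`` to ``c_k``, length ``t_k``) the mixed
"no-substitution below, free above" propagator integral

``kappa_k[i, j] = int_0^{t_k} [e^{u R_D}]_{ii} [e^{(t_k - u) R}]_{ij} du``

is evaluated in closed form with the kernel ``K`` (and its derivative
``K'`` for the second moment, via the survival-function identity
``E[T^m] = m int_0^{tbar} u^{m-1} P(T >= u | Y) du``).  The edge terms are
weighted by the no-substitution prefix ``D_{k-1}`` (dwell factors and
sibling emissions below the edge) and the outside variable at ``c_{k-1}``
(everything above, including the sibling at ``c_k``).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .rates import (
    NUCLEOTIDES,
    NUC_INDEX,
    RateModel,
    kernel_K,
    kernel_K_prime,
    realify,
)
from .tree import PhyloTree, TargetLineage, extract_lineage

__all__ = ["SiteEstimates", "TreeEngine", "column_to_vectors"]

#: symbols treated as fully missing data in non-target rows
MISSING_SYMBOLS = set("-.*NX?")


class ImpossibleColumnError(ValueError):
    """The column has zero likelihood under the model."""


@dataclasses.dataclass(frozen=True)
class SiteEstimates:
    """Per-column outputs for one target species."""

    t_mrs: float
    sigma: float
    q: float
    log_z: float
    skipped: bool = False
    target_base: str | None = None

    @classmethod
    def skipped_site(cls, base) -> "SiteEstimates":
        return cls(
            t_mrs=np.nan, sigma=np.nan, q=np.nan, log_z=np.nan,
            skipped=True, target_base=None if base is None else str(base),
        )


def symbol_to_vector(symbol: str | None) -> np.ndarray:
    """Inside vector for one observed symbol (all-ones when missing)."""
    if symbol is not None:
        s = symbol.upper()
        if s in NUC_INDEX:
            v = np.zeros(4)
            v[NUC_INDEX[s]] = 1.0
            return v
    # gaps, IUPAC ambiguity codes and absent species are all treated as
    # missing: the likelihood then marginalises the leaf state away
    return np.ones(4)


def column_to_vectors(column: Mapping[str, str], leaf_names: list[str]) -> np.ndarray:
    """(n_leaves, 4) inside vectors in ``leaf_names`` order."""
    return np.stack([symbol_to_vector(column.get(name)) for name in leaf_names])


class TreeEngine:
    """Caches per-edge transition matrices and lineage kernels for a fixed
    (tree, model, target) triple so that many columns can be scored cheaply."""

    def __init__(self, tree: PhyloTree, model: RateModel, target: str):
        self.tree = tree
        self.model = model
        self.target = target
        self.lineage: TargetLineage = extract_lineage(tree, target)
        if self.lineage.tbar <= 0:
            raise ValueError("target lineage has zero total length")
        self.pi = model.pi
        self._post = tree.postorder()
        self._leaves = tree.leaf_indices()
        self._leaf_pos = {n: i for i, n in enumerate(self._leaves)}
        self.leaf_names = [tree.names[n] for n in self._leaves]
        # transition matrix over each non-root edge, indexed by child node
        self.P = {}
        for n in range(tree.n_nodes):
            if int(tree.parent[n]) >= 0:
                self.P[n] = model.transition_matrix(float(tree.lengths[n]))
        self._kappa, self._kappa2 = self._lineage_kernels()
        # dwell factors exp(t_k * R_D[a, a]) per lineage edge and base
        rdiag = realify(model.rdiag)
        self._dwell = np.exp(np.outer(self.lineage.edge_lengths, rdiag))

    # -- lineage kernels ---------------------------------------------------
    def _lineage_kernels(self):
        """Closed-form kappa (K) and kappa2 (K') matrices per lineage edge."""
        U, lam, Uinv = self.model.U, self.model.eigenvalues, self.model.U_inv
        rdiag = self.model.rdiag.astype(complex)
        kappas, kappa2s = [], []
        for t_k in self.lineage.edge_lengths:
            kap = np.zeros((4, 4), dtype=complex)
            kap2 = np.zeros((4, 4), dtype=complex)
            if t_k > 0:
                for i in range(4):
                    x = t_k * rdiag[i]
                    kv = np.array([kernel_K(x, t_k * l) for l in lam])
                    kv2 = np.array([kernel_K_prime(x, t_k * l) for l in lam])
                    kap[i] = t_k * (U[i] * kv) @ Uinv
                    kap2[i] = t_k * t_k * (U[i] * kv2) @ Uinv
            kappas.append(realify(kap, tol=1e-8))
            kappa2s.append(realify(kap2, tol=1e-8))
        return kappas, kappa2s

    def kappa_edge(self, k: int, i=None, j=None):
        """Mixed propagator integral for lineage edge ``k`` (1-based)."""
        kap = self._kappa[k - 1]
        if i is None:
            return kap
        ii = NUC_INDEX[i] if isinstance(i, str) else int(i)
        jj = NUC_INDEX[j] if isinstance(j, str) else int(j)
        return float(kap[ii, jj])

    # -- inside / outside --------------------------------------------------
    def inside(self, column: Mapping[str, str]) -> np.ndarray:
        """Post-order inside table ``alpha[n, i] = P(Y below n | X_n = i)``."""
        tree = self.tree
        alpha = np.empty((tree.n_nodes, 4))
        for n in self._post:
            if tree.is_leaf(n):
                alpha[n] = symbol_to_vector(column.get(tree.names[n]))
            else:
                a, b = tree.children[n]
                alpha[n] = (alpha[a] @ self.P[a]) * (alpha[b] @ self.P[b])
        return alpha

    def outside(self, alpha: np.ndarray) -> np.ndarray:
        """Pre-order outside table.

        ``beta[n, i] = P(Y outside the subtree of n, X_parent(n) = i)``;
        the root row is left as the prior ``pi`` for convenience.
        """
        tree = self.tree
        beta = np.empty_like(alpha)
        root = tree.root
        beta[root] = self.pi
        for n in tree.preorder():
            if tree.is_leaf(n):
                continue
            a, b = tree.children[n]
            gamma_a = alpha[a] @ self.P[a]
            gamma_b = alpha[b] @ self.P[b]
            if n == root:
                up = self.pi
            else:
                up = self.P[n] @ beta[n]
            beta[a] = gamma_b * up
            beta[b] = gamma_a * up
        return beta

    def likelihood(self, column: Mapping[str, str]) -> float:
        return float(self.inside(column)[self.tree.root] @ self.pi)

    def gamma_sibling(self, alpha: np.ndarray, k: int) -> np.ndarray:
        """``gamma(b_k, i) = sum_j alpha(b_k, j) p(j | i, t_{b_k})``."""
        b_k = self.lineage.siblings[k - 1]
        return alpha[b_k] @ self.P[b_k]

    def inside_no_sub(self, column: Mapping[str, str], alpha: np.ndarray | None = None) -> np.ndarray:
        """Prefix probabilities ``D_k(a)`` of no substitution up to ``c_k``.

        ``D[k] = prod_{j<=k} exp(t_j R_D[a,a]) * gamma(b_j, a)`` with ``a``
        the observed target base; ``D[0] = 1``.
        """
        if alpha is None:
            alpha = self.inside(column)
        a = NUC_INDEX[column[self.target].upper()]
        M = self.lineage.M
        D = np.empty(M + 1)
        D[0] = 1.0
        for k in range(1, M + 1):
            D[k] = D[k - 1] * self._dwell[k - 1, a] * self.gamma_sibling(alpha, k)[a]
        return D

    # -- estimates ---------------------------------------------------------
    def estimate(self, column: Mapping[str, str]) -> SiteEstimates:
        """Exact (t_mrs, sigma, q, Z) for one column."""
        raw = column.get(self.target)
        if raw is None or raw.upper() not in NUC_INDEX:
            return SiteEstimates.skipped_site(raw)
        a = NUC_INDEX[raw.upper()]

        alpha = self.inside(column)
        Z = float(alpha[self.tree.root] @ self.pi)
        if Z <= 0:
            raise ImpossibleColumnError("column has zero likelihood")
        beta = self.outside(alpha)

        lineage = self.lineage
        D = self.inside_no_sub(column, alpha)
        t_acc = 0.0
        m2_acc = 0.0
        for k in range(1, lineage.M + 1):
            node = lineage.nodes[k - 1]
            beta_k = beta[node]  # indexed by the state at c_k
            kb = self._kappa[k - 1][a] @ beta_k
            k2b = self._kappa2[k - 1][a] @ beta_k
            tau_prev = lineage.taus[k - 1]
            t_acc += D[k - 1] * kb
            m2_acc += 2.0 * D[k - 1] * (tau_prev * kb + k2b)
        t_mrs = t_acc / Z
        m2 = m2_acc / Z
        q = D[lineage.M] * self.pi[a] / Z

        var = m2 - t_mrs * t_mrs
        if var < -1e-12 * max(1.0, m2):
            raise FloatingPointError(f"negative variance {var}")
        sigma = float(np.sqrt(max(var, 0.0)))
        return SiteEstimates(
            t_mrs=float(t_mrs),
            sigma=sigma,
            q=float(min(max(q, 0.0), 1.0)),
            log_z=float(np.log(Z)),
            target_base=NUCLEOTIDES[a],
        )

    def node_posterior(self, column: Mapping[str, str]) -> np.ndarray:
        """``P(X_n = i | Y)`` for every node."""
        alpha = self.inside(column)
        Z = float(alpha[self.tree.root] @ self.pi)
        if Z <= 0:
            raise ImpossibleColumnError("column has zero likelihood")
        beta = self.outside(alpha)
        post = np.empty_like(alpha)
        for n in range(self.tree.n_nodes):
            if n == self.tree.root:
                post[n] = alpha[n] * self.pi
            else:
                post[n] = alpha[n] * (self.P[n] @ beta[n])
        post /= post.sum(axis=1, keepdims=True)
        return post

    def reconstruct_ancestors(self, column: Mapping[str, str]) -> list[int]:
        """Max-posterior base index at each concestor ``c_0 .. c_M``.

        Ties are broken towards the smaller index (A < C < G < T).
        """
        post = self.node_posterior(column)
        return [int(np.argmax(post[n])) for n in self.lineage.nodes]
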