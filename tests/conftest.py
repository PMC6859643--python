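"""Shared fixtures and independent oracles.

The oracles here (Gillespie path simulation, numeric quadrature, brute-force
enumeration over internal states) deliberately avoid the closed-form kernel
code paths they are used to check.
"""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from mrsub import rates
from mrsub.tree import PhyloTree


@pytest.fixture(scope="session")
def jc():
    return rates.build_jukes_cantor()  # mu = 1/3, expected rate 1


@pytest.fixture(scope="session")
def sym_model():
    return rates.default_model()


@pytest.fixture(scope="session")
def five_taxon_tree():
    return PhyloTree.from_newick(
        "(((hg:0.1,pt:0.12):0.15,mm:0.4):0.2,(gg:0.5,xt:0.7):0.3);"
    )


@pytest.fixture(scope="session")
def two_leaf_tree():
    return PhyloTree.from_newick("(hg:0.4,mm:0.6);")


def gillespie_edge(model, b, t, n_paths, rng):
    """Unconditional path simulation on one branch.

    Returns (end_states, T, no_sub) arrays; T is the time from the branch
    end back to the last jump (t when the path has none).
    """
    rdiag = np.real(model.rdiag)
    R = model.R
    n = n_paths
    cur = np.full(n, rates.base_index(b))
    clock = np.zeros(n)
    last_jump = np.full(n, -np.inf)
    active = np.arange(n)
    while active.size:
        waits = rng.exponential(1.0 / (-rdiag[cur[active]]))
        clock[active] += waits
        jumped = active[clock[active] < t]
        for idx in jumped:
            p = R[:, cur[idx]].copy()
            p[cur[idx]] = 0.0
            p /= p.sum()
            cur[idx] = rng.choice(4, p=p)
            last_jump[idx] = clock[idx]
        active = jumped
    no_sub = ~np.isfinite(last_jump)
    T = np.where(no_sub, t, t - last_jump)
    return cur, T, no_sub


def gillespie_edge_conditional(model, a, b, t, n_paths, rng):
    """Moments of T conditioned on the endpoint pair, by rejection."""
    end, T, no_sub = gillespie_edge(model, b, t, n_paths, rng)
    sel = end == rates.base_index(a)
    if sel.sum() < 50:
        raise RuntimeError("too few accepted paths for a stable oracle")
    Tsel = T[sel]
    return {
        "n": int(sel.sum()),
        "mean": float(Tsel.mean()),
        "mean_se": float(Tsel.std(ddof=1) / np.sqrt(sel.sum())),
        "m2": float((Tsel**2).mean()),
        "m2_se": float((Tsel**2).std(ddof=1) / np.sqrt(sel.sum())),
        "q": float(no_sub[sel].mean()),
        "q_se": float(no_sub[sel].std(ddof=1) / np.sqrt(sel.sum())),
    }


def kappa_quadrature(model, i, j, t_k):
    """Numeric quadrature of the mixed no-sub/full propagator integral."""
    rdiag = float(np.real(model.rdiag[i]))

    def integrand(u):
        P = model.transition_matrix(t_k - u)
        return np.exp(u * rdiag) * P[i, j]

    val, _ = quad(integrand, 0.0, t_k, limit=200)
    return val


def brute_force_likelihood(tree, model, column):
    """Likelihood by enumerating all internal-node states."""
    P = {
        n: model.transition_matrix(float(tree.lengths[n]))
        for n in range(tree.n_nodes)
        if int(tree.parent[n]) >= 0
    }
    leaves = {tree.names[n]: n for n in tree.leaf_indices()}
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
    observed = {
        leaves[sp]: rates.NUC_INDEX[sym.upper()]
        for sp, sym in column.items()
        if sp in leaves and sym.upper() in rates.NUC_INDEX
    }
    free_leaves = [n for n in tree.leaf_indices() if n not in observed]
    total = 0.0
    for states in itertools.product(range(4), repeat=len(internal) + len(free_leaves)):
        s = dict(zip(internal + free_leaves, states))
        s.update(observed)
        pr = model.pi[s[tree.root]]
        for n in range(tree.n_nodes):
            if int(tree.parent[n]) >= 0:
                pr *= P[n][s[n], s[int(tree.parent[n])]]
        total += pr
    return total
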