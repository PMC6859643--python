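import itertools

import numpy as np
import pytest

from mrsub import edge, rates
from mrsub.engine import SiteEstimates, TreeEngine, symbol_to_vector
from mrsub.simulate import posterior_sample_histories, sampled_estimates
from mrsub.tree import PhyloTree, extract_lineage, restrict_to_leaves
from conftest import brute_force_likelihood, kappa_quadrature

FIVE_LEAVES = ["hg", "pt", "mm", "gg", "xt"]


@pytest.fixture(scope="module")
def eng(five_taxon_tree, sym_model):
    return TreeEngine(five_taxon_tree, sym_model, "hg")


class TestLineage:
    def test_two_leaf(self, two_leaf_tree):
        lin = extract_lineage(two_leaf_tree, "hg")
        assert lin.M == 1
        assert lin.tbar == pytest.approx(0.4)
        assert lin.fractions.tolist() == [0.0, 1.0]

    def test_balanced_four_leaf(self):
        tree = PhyloTree.from_newick("((a:0.1,b:0.2):0.3,(c:0.4,d:0.5):0.6);")
        lin = extract_lineage(tree, "a")
        assert lin.M == 2
        # sibling of the leaf is its cherry-mate; then the other cherry's root
        assert tree.names[lin.siblings[0]] == "b"
        assert set(tree.names[c] for c in tree.children[lin.siblings[1]]) == {"c", "d"}

    def test_fraction_prefix_sums(self, five_taxon_tree):
        lin = extract_lineage(five_taxon_tree, "mm")
        assert np.allclose(lin.fractions * lin.tbar, lin.taus)
        assert np.all(np.diff(lin.fractions) > 0)

    def test_unknown_species(self, five_taxon_tree):
        with pytest.raises(KeyError):
            extract_lineage(five_taxon_tree, "nope")


class TestInside:
    def test_single_leaf_vector(self):
        assert symbol_to_vector("G").tolist() == [0, 0, 1, 0]
        assert symbol_to_vector("-").tolist() == [1, 1, 1, 1]
        assert symbol_to_vector("N").tolist() == [1, 1, 1, 1]

    def test_only_target_observed_collapses_to_prior(self, eng, sym_model):
        assert eng.likelihood({"hg": "A"}) == pytest.approx(sym_model.pi[0], abs=1e-14)

    def test_against_enumeration(self, five_taxon_tree, sym_model, eng):
        col = {"hg": "A", "pt": "G", "mm": "A", "gg": "C", "xt": "T"}
        assert eng.likelihood(col) == pytest.approx(
            brute_force_likelihood(five_taxon_tree, sym_model, col), rel=1e-10
        )

    def test_likelihoods_sum_to_one(self, eng):
        total = sum(
            eng.likelihood(dict(zip(FIVE_LEAVES, bases)))
            for bases in itertools.product("ACGT", repeat=5)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestOutside:
    def test_node_marginal_consistency(self, eng, five_taxon_tree):
        col = {"hg": "A", "pt": "G", "mm": "-", "gg": "C", "xt": "T"}
        alpha = eng.inside(col)
        beta = eng.outside(alpha)
        Z = alpha[five_taxon_tree.root] @ eng.pi
        for n in range(five_taxon_tree.n_nodes):
            if int(five_taxon_tree.parent[n]) >= 0:
                v = (alpha[n] @ eng.P[n]) @ beta[n]
                assert v == pytest.approx(Z, rel=1e-12)

    def test_posterior_rows_sum_to_one(self, eng):
        post = eng.node_posterior({"hg": "A", "pt": "C", "mm": "G", "gg": "T", "xt": "A"})
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestInsideNoSub:
    def test_prefix_starts_at_one(self, eng):
        D = eng.inside_no_sub({"hg": "A", "pt": "A", "mm": "A", "gg": "A", "xt": "A"})
        assert D[0] == 1.0
        assert np.all(np.diff(D) <= 0)  # factors are probabilities

    def test_path_restricted_enumeration(self, sym_model):
        # pin every lineage state to the target base and enumerate the rest
        tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.4,(c:0.5,d:0.6):0.7);")
        eng = TreeEngine(tree, sym_model, "a")
        col = {"a": "C", "b": "G", "c": "C", "d": "T"}
        D = eng.inside_no_sub(col)
        lin = eng.lineage
        a = 1  # C
        # manual: D[1] = exp(t_a R_CC) * gamma(b, C); D[2] adds root edge + other cherry
        P_b = sym_model.transition_matrix(0.3)
        g1 = P_b[2, a]  # b observed G
        d1 = np.exp(0.2 * np.real(sym_model.rdiag[a])) * g1
        assert D[1] == pytest.approx(d1, rel=1e-12)
        P_c = sym_model.transition_matrix(0.5)
        P_d = sym_model.transition_matrix(0.6)
        P_cd = sym_model.transition_matrix(0.7)
        g2 = sum(
            P_cd[j, a] * P_c[1, j] * P_d[3, j] for j in range(4)
        )  # sibling subtree emits c=C, d=T
        d2 = d1 * np.exp(0.4 * np.real(sym_model.rdiag[a])) * g2
        assert D[2] == pytest.approx(d2, rel=1e-12)


class TestKappa:
    def test_zero_length_edge_is_zero(self, sym_model):
        tree = PhyloTree.from_newick("((a:0.0,b:0.3):0.4,c:0.7);")
        eng = TreeEngine(tree, sym_model, "a")
        assert np.allclose(eng.kappa_edge(1), 0.0)

    def test_quadrature_oracle(self, eng, sym_model, five_taxon_tree):
        lin = eng.lineage
        for k in (1, 2, 3):
            t_k = float(lin.edge_lengths[k - 1])
            for i, j in ((0, 0), (1, 3), (2, 1)):
                expected = kappa_quadrature(sym_model, i, j, t_k)
                assert eng.kappa_edge(k, i, j) == pytest.approx(expected, abs=1e-8)

    def test_single_edge_reduction(self, two_leaf_tree, sym_model):
        # with the sibling missing, the lineage is one edge; the engine must
        # reproduce the closed-form single-edge estimator mixed over the prior
        eng = TreeEngine(two_leaf_tree, sym_model, "hg")
        est = eng.estimate({"hg": "A"})
        t = 0.4
        probs = [
            sym_model.pi[b] * edge.likelihood_edge(edge.EdgeProblem(0, b, t, sym_model))
            for b in range(4)
        ]
        Z = sum(probs)
        tm = (
            sum(
                p * edge.tmrs_edge(edge.EdgeProblem(0, b, t, sym_model))
                for b, p in enumerate(probs)
            )
            / Z
        )
        m2 = (
            sum(
                p * edge.second_moment_edge(edge.EdgeProblem(0, b, t, sym_model))
                for b, p in enumerate(probs)
            )
            / Z
        )
        q = sym_model.pi[0] * np.exp(t * np.real(sym_model.rdiag[0])) / Z
        assert est.t_mrs == pytest.approx(tm, rel=1e-10)
        assert est.sigma == pytest.approx(np.sqrt(m2 - tm * tm), rel=1e-10)
        assert est.q == pytest.approx(q, rel=1e-10)


class TestEstimate:
    def test_skipped_for_gap_or_ambiguous_target(self, eng):
        for sym in ("-", "N", "R", None):
            col = {"hg": sym, "pt": "A"} if sym is not None else {"pt": "A"}
            est = eng.estimate(col)
            assert est.skipped

    def test_support_bounds(self, eng):
        lin = eng.lineage
        for bases in itertools.product("ACGT", repeat=2):
            col = {"hg": bases[0], "pt": bases[1], "mm": "A", "gg": "C", "xt": "G"}
            est = eng.estimate(col)
            assert 0.0 <= est.t_mrs <= lin.tbar + 1e-12
            assert 0.0 <= est.q <= 1.0
            assert est.sigma >= 0.0

    def test_missing_data_pruning_invariance(self, five_taxon_tree, sym_model):
        eng_full = TreeEngine(five_taxon_tree, sym_model, "hg")
        est_full = eng_full.estimate({"hg": "A", "pt": "G", "mm": "-", "gg": "C", "xt": "N"})
        pruned = restrict_to_leaves(five_taxon_tree, ["hg", "pt", "gg"])
        eng_red = TreeEngine(pruned, sym_model, "hg")
        est_red = eng_red.estimate({"hg": "A", "pt": "G", "gg": "C"})
        assert est_full.t_mrs == pytest.approx(est_red.t_mrs, abs=1e-12)
        assert est_full.sigma == pytest.approx(est_red.sigma, abs=1e-12)
        assert est_full.q == pytest.approx(est_red.q, abs=1e-12)
        assert est_full.log_z == pytest.approx(est_red.log_z, abs=1e-12)

    def test_complement_invariance(self, eng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        col = {"hg": "A", "pt": "G", "mm": "A", "gg": "C", "xt": "T"}
        ccol = {k: comp[v] for k, v in col.items()}
        e1, e2 = eng.estimate(col), eng.estimate(ccol)
        assert e1.t_mrs == pytest.approx(e2.t_mrs, abs=1e-12)
        assert e1.sigma == pytest.approx(e2.sigma, abs=1e-12)
        assert e1.q == pytest.approx(e2.q, abs=1e-12)

    def test_recent_evidence_lowers_tmrs(self, eng):
        # increasingly recent substitution evidence must shrink t_mrs
        ladder = [
            {"hg": "A", "pt": "A", "mm": "A", "gg": "A", "xt": "C"},
            {"hg": "A", "pt": "A", "mm": "C", "gg": "C", "xt": "C"},
            {"hg": "A", "pt": "C", "mm": "C", "gg": "C", "xt": "C"},
        ]
        vals = [eng.estimate(c).t_mrs for c in ladder]
        assert vals[0] > vals[1] > vals[2]

    def test_q_matches_sampled_no_sub_mass(self, five_taxon_tree, sym_model, eng):
        col = {"hg": "A", "pt": "A", "mm": "A", "gg": "A", "xt": "A"}
        est = eng.estimate(col)
        times, nosub = posterior_sample_histories(
            five_taxon_tree, col, sym_model, "hg", 40000, 300, seed=21, engine=eng
        )
        tm, sg, q = sampled_estimates(times, nosub)
        se = np.sqrt(est.q * (1 - est.q) / 40000)
        assert abs(q - est.q) < 3 * se + 2e-3  # MC + discretisation slack


class TestReconstruction:
    def test_uniform_column(self, eng):
        col = dict.fromkeys(FIVE_LEAVES, "G")
        assert eng.reconstruct_ancestors(col) == [2] * (eng.lineage.M + 1)

    def test_brute_force_posterior_argmax(self, sym_model):
        tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.4,(c:0.5,d:0.6):0.7);")
        eng = TreeEngine(tree, sym_model, "a")
        col = {"a": "A", "b": "G", "c": "G", "d": "G"}
        # enumerate joint internal states for the exact node posterior
        P = {
            n: sym_model.transition_matrix(float(tree.lengths[n]))
            for n in range(tree.n_nodes)
            if int(tree.parent[n]) >= 0
        }
        leaves = {tree.names[n]: n for n in tree.leaf_indices()}
        internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
        post = {n: np.zeros(4) for n in internal}
        for states in itertools.product(range(4), repeat=len(internal)):
            s = dict(zip(internal, states))
            for sp, b in col.items():
                s[leaves[sp]] = "ACGT".index(b)
            pr = sym_model.pi[s[tree.root]]
            for n in range(tree.n_nodes):
                if int(tree.parent[n]) >= 0:
                    pr *= P[n][s[n], s[int(tree.parent[n])]]
            for n in internal:
                post[n][s[n]] += pr
        recon = eng.reconstruct_ancestors(col)
        for k, node in enumerate(eng.lineage.nodes):
            if node in post:
                assert recon[k] == int(np.argmax(post[node]))


class TestSamplingOracleAgreement:
    def test_estimates_match_sampling(self, five_taxon_tree, sym_model, eng):
        col = {"hg": "A", "pt": "G", "mm": "A", "gg": "C", "xt": "A"}
        est = eng.estimate(col)
        times, nosub = posterior_sample_histories(
            five_taxon_tree, col, sym_model, "hg", 60000, 400, seed=9, engine=eng
        )
        tm, sg, q = sampled_estimates(times, nosub)
        assert tm == pytest.approx(est.t_mrs, rel=0.02)
        assert sg == pytest.approx(est.sigma, rel=0.05)
        assert q == pytest.approx(est.q, rel=0.02)
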