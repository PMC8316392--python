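"""Binary-state CTMC likelihood, marginals, and the Metropolis sampler."""

import math
import warnings

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from molmorph.ancestral import (
    CTMCParams,
    MCMCSettings,
    bbm_mcmc,
    mc_standard_error,
    node_marginals,
    prune_loglik,
    summarize_over_trees,
    transition_matrix,
)
from molmorph.io import read_newick
from molmorph.synthetic import gen_tree, sim_trait

from oracles import enum_likelihood, random_small_tree


def star_tree(n, branch=500.0):
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    for i in range(n):
        ch = tree.seed_node.new_child(edge_length=branch)
        ch.taxon = taxa.new_taxon(label=f"T{i}")
    tree.is_rooted = True
    return tree


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(CTMCParams(pi1=0.3, mu=0.7), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_long_time_reaches_stationarity(self):
        params = CTMCParams(pi1=0.3, mu=1.0)
        P = transition_matrix(params, 50.0 / params.rate)
        assert np.allclose(P, [[0.7, 0.3], [0.7, 0.3]], atol=1e-15)

    def test_matches_matrix_exponential(self):
        params = CTMCParams(pi1=0.3, mu=0.7)
        r = params.rate
        Q = np.array([[-r * 0.3, r * 0.3], [r * 0.7, -r * 0.7]])
        assert np.allclose(
            transition_matrix(params, 1.3), expm(Q * 1.3), atol=1e-10
        )

    def test_rows_sum_to_one_and_unit_flux(self):
        params = CTMCParams(pi1=0.42, mu=1.0)
        P = transition_matrix(params, 0.37)
        assert np.allclose(P.sum(axis=1), 1.0)
        # mu = expected changes per unit length at stationarity
        r = params.rate
        flux = params.pi0 * r * params.pi1 + params.pi1 * r * params.pi0
        assert flux == pytest.approx(params.mu)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(CTMCParams(pi1=0.5), -0.1)


class TestPruneLoglik:
    def test_single_tip_is_root_prior(self):
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node.taxon = taxa.new_taxon(label="A")
        tree.is_rooted = True
        params = CTMCParams(pi1=0.3)
        assert prune_loglik(tree, {"A": 1}, params) == pytest.approx(math.log(0.3))

    def test_zero_length_star_all_present(self):
        tree = star_tree(5, branch=0.0)
        params = CTMCParams(pi1=0.25, mu=1.0)
        traits = {f"T{i}": 1 for i in range(5)}
        assert prune_loglik(tree, traits, params) == pytest.approx(math.log(0.25))

    def test_matches_enumeration_on_random_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            tree = random_small_tree(rng, n)
            traits = {f"T{i}": int(rng.integers(2)) for i in range(n)}
            params = CTMCParams(
                pi1=float(rng.uniform(0.05, 0.95)), mu=float(rng.uniform(0.05, 3))
            )
            ll_enum, _ = enum_likelihood(tree, traits, params)
            assert prune_loglik(tree, traits, params) == pytest.approx(
                ll_enum, abs=1e-10
            )

    def test_unknown_tips_marginalized(self, rng):
        tree = random_small_tree(rng, 4)
        params = CTMCParams(pi1=0.4, mu=0.8)
        traits = {"T0": 1, "T1": "?", "T2": 0, "T3": "?"}
        ll_enum, _ = enum_likelihood(tree, traits, params)
        assert prune_loglik(tree, traits, params) == pytest.approx(ll_enum, abs=1e-10)

    def test_missing_tip_raises(self, rng):
        tree = random_small_tree(rng, 3)
        with pytest.raises(KeyError):
            prune_loglik(tree, {"T0": 1, "T1": 0}, CTMCParams(pi1=0.5))

    def test_child_order_invariance(self, rng):
        tree = random_small_tree(rng, 5)
        traits = {f"T{i}": i % 2 for i in range(5)}
        params = CTMCParams(pi1=0.35, mu=0.9)
        ll0 = prune_loglik(tree, traits, params)
        for nd in tree.preorder_node_iter():
            ch = nd.child_nodes()
            if len(ch) > 1:
                nd.set_child_nodes(list(reversed(ch)))
        assert prune_loglik(tree, traits, params) == pytest.approx(ll0, abs=1e-12)


class TestNodeMarginals:
    def test_frozen_character_when_rate_vanishes(self, rng):
        tree = random_small_tree(rng, 5)
        traits = {f"T{i}": 1 for i in range(5)}
        for p in node_marginals(tree, traits, CTMCParams(pi1=0.5, mu=1e-12)):
            assert p.p_present == pytest.approx(1.0, abs=1e-9)

    def test_saturated_branches_return_prior(self):
        tree = star_tree(6, branch=1e4)
        traits = {f"T{i}": i % 2 for i in range(6)}
        for p in node_marginals(tree, traits, CTMCParams(pi1=0.3, mu=1.0)):
            assert p.p_present == pytest.approx(0.3, abs=1e-9)

    def test_matches_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 7))
            tree = random_small_tree(rng, n)
            traits = {f"T{i}": int(rng.integers(2)) for i in range(n)}
            params = CTMCParams(
                pi1=float(rng.uniform(0.1, 0.9)), mu=float(rng.uniform(0.1, 2))
            )
            _, marg = enum_likelihood(tree, traits, params)
            for p in node_marginals(tree, traits, params):
                assert p.p_present == pytest.approx(
                    marg[p.bipartition][1], abs=1e-10
                )

    def test_root_marginal_equals_weighted_partials(self, rng):
        # the up-down root marginal must equal the renormalized root
        # partial likelihoods weighted by the stationary frequencies
        from molmorph.ancestral import _IndexedTree, _down_pass

        tree = random_small_tree(rng, 6)
        traits = {f"T{i}": int(rng.integers(2)) for i in range(6)}
        params = CTMCParams(pi1=0.6, mu=0.5)
        it = _IndexedTree(tree)
        d0, d1, _, _, _ = _down_pass(
            it, it.tip_partials(traits), params.pi0, params.pi1, params.rate
        )
        w1 = params.pi1 * d1[it.root]
        w0 = params.pi0 * d0[it.root]
        root_post = max(node_marginals(tree, traits, params), key=lambda p: len(p.bipartition))
        assert root_post.p_present == pytest.approx(w1 / (w0 + w1), abs=1e-12)

    def test_probabilities_normalized(self, rng):
        tree = gen_tree(20, seed=3)
        traits = sim_trait(tree, CTMCParams(pi1=0.5, mu=1.0), seed=4).tip_states
        for p in node_marginals(tree, traits, CTMCParams(pi1=0.5, mu=1.0)):
            assert 0 <= p.p_present <= 1
            assert p.p_present + p.p_absent == pytest.approx(1.0)


class TestBbmMcmc:
    def test_conjugate_posterior_on_saturated_star(self):
        n, k = 40, 28
        tree = star_tree(n, branch=500.0)
        traits = {f"T{i}": 1 if i < k else 0 for i in range(n)}
        res = bbm_mcmc(
            tree, traits,
            MCMCSettings(generations=20_000, chains=2, sample_every=10, seed=5),
            compute_marginals=False,
        )
        exact = (k + 0.5) / (n + 1)  # Beta(k+0.5, n-k+0.5) mean
        se = mc_standard_error(res["pi1"])
        assert abs(res["pi1"].mean() - exact) < 3 * se

    def test_identical_seed_identical_traces(self, rng):
        tree = gen_tree(12, seed=9)
        traits = sim_trait(tree, CTMCParams(pi1=0.6, mu=0.8), seed=1).tip_states
        settings = MCMCSettings(generations=500, chains=2, sample_every=5, seed=123)
        r1 = bbm_mcmc(tree, traits, settings, compute_marginals=False)
        r2 = bbm_mcmc(tree, traits, settings, compute_marginals=False)
        assert np.array_equal(r1["pi1"], r2["pi1"])
        assert np.array_equal(r1["mu"], r2["mu"])

    def test_fixed_mu_mode(self, rng):
        tree = gen_tree(12, seed=9)
        traits = sim_trait(tree, CTMCParams(pi1=0.6, mu=0.8), seed=1).tip_states
        res = bbm_mcmc(
            tree, traits,
            MCMCSettings(generations=500, chains=1, sample_every=5, seed=3,
                         fix_mu=1.0),
            compute_marginals=False,
        )
        assert np.all(res["mu"] == 1.0)

    def test_node_posteriors_normalized(self):
        tree = gen_tree(15, seed=2)
        traits = sim_trait(tree, CTMCParams(pi1=0.5, mu=0.5), seed=3).tip_states
        res = bbm_mcmc(
            tree, traits,
            MCMCSettings(generations=1000, chains=1, sample_every=10, seed=8),
        )
        assert res["node_posteriors"]
        for p in res["node_posteriors"]:
            assert 0 <= p.p_present <= 1


class TestSummarizeOverTrees:
    def _settings(self):
        return MCMCSettings(generations=1000, chains=1, sample_every=10, seed=17)

    def test_identical_trees_equal_single_tree(self):
        tree_text = "((A:1,B:1):1,(C:1,D:1):1);"
        trees = [read_newick(tree_text, is_path=False) for _ in range(3)]
        traits = {"A": 1, "B": 1, "C": 0, "D": 0}
        agg = summarize_over_trees(trees, traits, self._settings())
        single = bbm_mcmc(
            read_newick(tree_text, is_path=False), traits, self._settings()
        )
        ref = {p.bipartition: p.p_present for p in single["node_posteriors"]}
        for bip, v in agg["bipartitions"].items():
            assert v["support"] == 1.0
            assert v["p_present"] == pytest.approx(ref[bip], abs=1e-12)

    def test_nni_conflict_reports_half_support(self):
        t1 = read_newick("(((A:1,B:1):1,C:1):1,D:1);", is_path=False)
        t2 = read_newick("(((A:1,C:1):1,B:1):1,D:1);", is_path=False)
        traits = {"A": 1, "B": 1, "C": 0, "D": 0}
        agg = summarize_over_trees([t1, t2], traits, self._settings())
        ab = frozenset({"A", "B"})
        assert agg["bipartitions"][ab]["support"] == 0.5
        abc = frozenset({"A", "B", "C"})
        assert agg["bipartitions"][abc]["support"] == 1.0

    def test_disjoint_tip_sets_rejected(self):
        t1 = read_newick("(A:1,B:1);", is_path=False)
        t2 = read_newick("(A:1,C:1);", is_path=False)
        with pytest.raises(ValueError):
            summarize_over_trees([t1, t2], {"A": 1, "B": 0, "C": 0},
                                 self._settings())
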