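"""GMYC, PTP/mPTP, enumeration oracle and MCMC support sampling."""

import math

import numpy as np
import pytest

from barcodedelim.errors import TreeError
from barcodedelim.partition import groups_of
from barcodedelim.simulate import (
    SamplesPerSpecies,
    simulate_clustered_gene_tree,
    simulate_species_tree,
)
from barcodedelim.tree_delim import (
    TreeIndex,
    delim_support_mcmc,
    delimitation_count,
    enumerate_delimitations,
    exact_delimitation_posterior,
    gmyc_fit,
    mptp_ml,
    mptp_loglik,
    ptp_loglik,
    ptp_ml,
)
from barcodedelim.trees import parse_newick


def random_tree(rng, n_tips):
    return simulate_species_tree(n_tips, 1.0, rng)


class TestEnumeration:
    def test_two_tip_cherry_has_two_delimitations(self):
        t = parse_newick("(A:1,B:1);")
        assert len(enumerate_delimitations(t)) == 2

    def test_balanced_four_tip_has_five(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert len(enumerate_delimitations(t)) == 5

    def test_caterpillar_four_tip_has_four(self):
        # N(leaf)=1; cherry=2; then 1+1*2=3; then 1+1*3=4
        t = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        assert len(enumerate_delimitations(t)) == 4

    def test_count_matches_recursion_on_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = random_tree(rng, int(rng.integers(3, 10)))
            assert len(enumerate_delimitations(t)) == delimitation_count(t)

    def test_every_delimitation_is_valid_antichain(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        for delim in enumerate_delimitations(t):
            tips = [x for s in delim for x in s]
            assert sorted(tips) == ["A", "B", "C", "D"]  # disjoint cover

    def test_refuses_large_trees(self):
        rng = np.random.default_rng(0)
        with pytest.raises(TreeError):
            enumerate_delimitations(random_tree(rng, 15), max_tips=12)


class TestPtpFamily:
    def test_two_separated_clades_found(self):
        t = parse_newick(
            "((A:0.012,B:0.008):1.0,((C:0.011,D:0.009):0.01,E:0.02):1.0);"
        )
        res = ptp_ml(t)
        assert res.n_species == 2
        assert {frozenset(s) for s in res.species} == {
            frozenset("AB"), frozenset("CDE"),
        }

    def test_heuristic_matches_enumeration_on_small_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = random_tree(rng, int(rng.integers(4, 9)))
            exact_p = ptp_ml(t, max_exact=12)
            heur_p = ptp_ml(t, max_exact=0, seed=1)
            assert heur_p.logL == pytest.approx(exact_p.logL, abs=1e-9)
            exact_m = mptp_ml(t, max_exact=12)
            heur_m = mptp_ml(t, max_exact=0, seed=1)
            assert heur_m.AIC == pytest.approx(exact_m.AIC, abs=1e-9)

    def test_aic_identity_and_param_count(self):
        rng = np.random.default_rng(5)
        t = random_tree(rng, 7)
        res = mptp_ml(t)
        assert res.AIC == pytest.approx(2 * res.n_params - 2 * res.logL)
        with_edges = sum(1 for lam in res.lambda_per_species.values() if lam)
        spec_param = 1 if res.lambda_speciation is not None else 0
        assert res.n_params == spec_param + with_edges

    def test_mptp_no_worse_than_ptp_delimitation(self):
        # per-species rates nest the pooled rate at any fixed delimitation
        rng = np.random.default_rng(9)
        for _ in range(10):
            t = random_tree(rng, 8)
            ti = TreeIndex(t)
            best_ptp = ptp_ml(t).species
            labels = {min(s) for s in best_ptp}
            anti = frozenset(
                k for k in range(ti.n_nodes)
                if ti.tips_below[k] in set(best_ptp)
            )
            ll_p, _ = ptp_loglik(ti, anti)
            ll_m, _ = mptp_loglik(ti, anti)
            assert ll_m >= ll_p - 1e-9

    def test_invariant_to_child_order(self):
        a = parse_newick("((A:0.01,B:0.01):1.0,(C:0.01,D:0.01):1.0);")
        b = parse_newick("((D:0.01,C:0.01):1.0,(B:0.01,A:0.01):1.0);")
        ra, rb = mptp_ml(a), mptp_ml(b)
        assert {frozenset(s) for s in ra.species} == {frozenset(s) for s in rb.species}
        assert ra.AIC == pytest.approx(rb.AIC)

    def test_zero_length_edges_excluded_from_likelihood(self):
        # duplicate haplotypes (zero-length cherries) must not be split off
        t = parse_newick(
            "((A:0.0,A2:0.0):0.01,((B:0.0,B2:0.0):0.012,C:0.01):1.0);"
        )
        res = mptp_ml(t)
        part = groups_of(res.partition)
        for members in part.values():
            assert not ({"A", "A2"} & members) or {"A", "A2"} <= members
            assert not ({"B", "B2"} & members) or {"B", "B2"} <= members

    def test_fewer_than_three_tips_rejected(self):
        with pytest.raises(TreeError):
            ptp_ml(parse_newick("(A:1,B:1);"))


class TestGmyc:
    def test_two_cluster_tree_yields_two_entities(self):
        t = parse_newick("((A:0.01,B:0.01):0.99,(C:0.01,D:0.01):0.99);")
        res = gmyc_fit(t)
        assert res.n_entities == 2
        assert 0.01 < res.best_threshold_T < 1.0
        assert {frozenset(v) for v in groups_of(res.entities).values()} == {
            frozenset("AB"), frozenset("CD"),
        }

    def test_likelihood_ratio_non_negative_and_in_ci(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            res = gmyc_fit(random_tree(rng, 12))
            assert res.logL_alt >= res.logL_null
            assert res.LR == pytest.approx(2 * (res.logL_alt - res.logL_null))
            assert res.n_entities in res.ci_entity_counts

    def test_null_equals_root_threshold_fit(self):
        rng = np.random.default_rng(4)
        res = gmyc_fit(random_tree(rng, 10))
        # the above-root candidate IS the null by construction
        assert res.candidate_logL[-1] == pytest.approx(res.logL_null)

    def test_recovers_species_on_clustered_gene_trees(self):
        gt, truth = simulate_clustered_gene_tree(
            8, 4.0, 0.002, SamplesPerSpecies(fixed=4), seed=77
        )
        res = gmyc_fit(gt)
        assert res.n_entities == 8
        got = {frozenset(v) for v in groups_of(res.entities).values()}
        assert got == {frozenset(v) for v in groups_of(truth).values()}

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeError):
            gmyc_fit(parse_newick("((A:1,B:2):1,C:4);"))

    def test_tip_order_invariance(self):
        a = parse_newick("((A:0.01,B:0.01):0.99,(C:0.02,D:0.02):0.98);")
        b = parse_newick("((D:0.02,C:0.02):0.98,(B:0.01,A:0.01):0.99);")
        ra, rb = gmyc_fit(a), gmyc_fit(b)
        assert ra.logL_alt == pytest.approx(rb.logL_alt)
        assert ra.n_entities == rb.n_entities


class TestMcmcSupport:
    def test_same_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(8)
        t = random_tree(rng, 6)
        r1 = delim_support_mcmc(t, "PTP", n_chains=2, n_steps=5000, thinning=5, seed=3)
        r2 = delim_support_mcmc(t, "PTP", n_chains=2, n_steps=5000, thinning=5, seed=3)
        assert r1.sample_counts == r2.sample_counts
        assert r1.per_clade_support == r2.per_clade_support

    def test_separated_clusters_get_high_support(self):
        t = parse_newick("((A:0.01,B:0.012):0.99,(C:0.011,D:0.009):0.99);")
        res = delim_support_mcmc(t, "PTP", n_chains=2, n_steps=50_000, seed=5)
        assert res.per_clade_support[frozenset("AB")] >= 0.95
        assert res.per_clade_support[frozenset("CD")] >= 0.95
        assert res.asddsv is not None and res.asddsv < 0.05

    def test_sampled_frequencies_match_exact_posterior(self):
        rng = np.random.default_rng(7)
        t = random_tree(rng, 7)
        exact = exact_delimitation_posterior(t, "PTP")
        res = delim_support_mcmc(t, "PTP", n_chains=2, n_steps=100_000, thinning=5, seed=11)
        tot = sum(res.sample_counts.values())
        tv = 0.5 * sum(
            abs(exact.get(k, 0.0) - res.sample_counts.get(k, 0) / tot)
            for k in set(exact) | set(res.sample_counts)
        )
        assert tv < 0.05

    def test_burn_in_must_leave_samples(self):
        rng = np.random.default_rng(2)
        t = random_tree(rng, 5)
        with pytest.raises(TreeError):
            delim_support_mcmc(t, "PTP", n_steps=100, burn_in_fraction=1.5)
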