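"""Ancestral state reconstruction: ER likelihoods, marginals, threshold MCMC."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from snakedent import (
    ancthresh_mcmc,
    er_log_likelihood,
    fit_er_rate,
    ml_asr_marginal,
    parse_newick,
    sim_er_discrete,
    sim_threshold_trait,
    sim_yule_tree,
)


def er_rate_matrix(k: float, q: float) -> np.ndarray:
    Q = np.full((k, k), q)
    np.fill_diagonal(Q, -(k - 1) * q)
    return Q


def expm_likelihood(tree, tip_states, q, states):
    """Independent oracle: pruning with explicit matrix exponentials."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    Q = er_rate_matrix(k, q)

    def partial(node):
        if node.is_leaf:
            v = np.zeros(k)
            v[sidx[tip_states[node.label]]] = 1.0
            return v
        out = np.ones(k)
        for child in node.children:
            out = out * (expm(Q * child.length) @ partial(child))
        return out

    return float(np.log(np.mean(partial(tree.root))))


def enumeration_marginals(tree, tip_states, q, states):
    """Independent oracle: sum over every assignment of internal states."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    Q = er_rate_matrix(k, q)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    P = {n: expm(Q * n.length) for n in tree.postorder() if n.parent is not None}
    marg = {n: np.zeros(k) for n in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        state_of = dict(zip(internals, assign))
        like = 1.0 / k  # uniform root prior
        for node in tree.postorder():
            if node.parent is None:
                continue
            s_par = state_of[node.parent]
            s_node = (
                sidx[tip_states[node.label]] if node.is_leaf else state_of[node]
            )
            like *= P[node][s_par, s_node]
        for node in internals:
            marg[node][state_of[node]] += like
    return {n: v / v.sum() for n, v in marg.items()}


class TestERLikelihood:
    def test_worked_two_tip_case(self):
        """k=2, q=0.5, t=1: L = 0.5 * (P_same^2 + P_diff^2) = 0.2838338."""
        tree = parse_newick("(A:1,B:1);")
        tips = {"A": "s0", "B": "s0"}
        logL = er_log_likelihood(tree, tips, 0.5, states=["s0", "s1"])
        e = np.exp(-1.0)
        closed = 0.5 * ((0.5 + 0.5 * e) ** 2 + (0.5 - 0.5 * e) ** 2)
        assert logL == pytest.approx(np.log(closed), abs=1e-12)
        assert logL == pytest.approx(
            expm_likelihood(tree, tips, 0.5, ["s0", "s1"]), abs=1e-10
        )

    def test_q_zero_same_state_gives_root_prior_mass(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": "x", "B": "x", "C": "x"}
        logL = er_log_likelihood(tree, tips, 0.0, states=["x", "y", "z"])
        assert logL == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_large_q_stationarity_limit(self):
        tree = parse_newick("((A:5,B:5):5,C:10);")
        tips = {"A": "x", "B": "y", "C": "x"}
        logL = er_log_likelihood(tree, tips, 50.0, states=["x", "y"])
        assert logL == pytest.approx(3 * np.log(0.5), abs=1e-6)

    def test_matches_expm_oracle_on_random_trees(self):
        rng = np.random.default_rng(17)
        states = ["a", "b", "c"]
        for i in range(10):
            n = int(rng.integers(3, 6))
            tree = sim_yule_tree(n, seed=700 + i)
            tips = {t: states[rng.integers(3)] for t in tree.tip_labels}
            q = float(rng.uniform(0.05, 1.5))
            assert er_log_likelihood(tree, tips, q, states=states) == pytest.approx(
                expm_likelihood(tree, tips, q, states), abs=1e-10
            )

    def test_unknown_state_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            er_log_likelihood(tree, {"A": "w", "B": "x"}, 0.1, states=["x", "y"])


class TestFitER:
    def test_single_state_boundary(self):
        tree = sim_yule_tree(10, seed=1)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_er_rate(tree, {t: "a" for t in tree.tip_labels}, states=["a", "b"])
        assert fit.q == 0.0 and fit.at_boundary

    def test_optimum_beats_grid(self):
        tree = sim_yule_tree(30, seed=2)
        tips, _ = sim_er_discrete(tree, 0.4, k=3, seed=3)
        fit = fit_er_rate(tree, tips, k=3)
        grid = np.linspace(0.01, 5.0, 100)
        grid_best = max(
            er_log_likelihood(tree, tips, g, k=3) for g in grid
        )
        assert fit.log_likelihood >= grid_best - 1e-6

    def test_rate_recovery(self):
        """Median q-hat over replicates near the generating rate."""
        q_true = 0.3
        fits = []
        for i in range(12):
            tree = sim_yule_tree(300, seed=100 + i).scale_to_height(1.0)
            tips, _ = sim_er_discrete(tree, q_true, k=3, seed=200 + i)
            fits.append(fit_er_rate(tree, tips, k=3).q)
        assert 0.15 <= float(np.median(fits)) <= 0.45


class TestMLMarginals:
    def test_uniform_data_concentrates(self):
        tree = sim_yule_tree(15, seed=4)
        tips = {t: "a" for t in tree.tip_labels}
        res = ml_asr_marginal(tree, tips, states=["a", "b"])
        assert (res.node_probabilities["a"] >= 0.99).all()

    def test_rows_sum_to_one(self):
        tree = sim_yule_tree(25, seed=5)
        tips, _ = sim_er_discrete(tree, 0.5, k=3, seed=6)
        res = ml_asr_marginal(tree, tips, k=3)
        np.testing.assert_allclose(
            res.node_probabilities.sum(axis=1), 1.0, atol=1e-9
        )

    def test_matches_enumeration_oracle(self):
        states = ["a", "b", "c"]
        rng = np.random.default_rng(77)
        from snakedent.tree import node_ids

        for i in range(5):
            tree = sim_yule_tree(5, seed=800 + i)
            tips = {t: states[rng.integers(3)] for t in tree.tip_labels}
            res = ml_asr_marginal(tree, tips, states=states)
            oracle = enumeration_marginals(tree, tips, res.q, states)
            ids = node_ids(tree)
            for node, probs in oracle.items():
                np.testing.assert_allclose(
                    res.node_probabilities.loc[ids[node]].to_numpy(),
                    probs,
                    atol=1e-10,
                )

    def test_annotated_newick_contains_probabilities(self):
        tree = sim_yule_tree(6, seed=9)
        tips, _ = sim_er_discrete(tree, 0.5, k=2, seed=10)
        res = ml_asr_marginal(tree, tips, k=2)
        text = res.annotated_newick(tree)
        assert "[&" in text and "N" in text


class TestThresholdMCMC:
    def test_posteriors_sum_to_one(self):
        tree = sim_yule_tree(30, seed=11)
        tips, _, _ = sim_threshold_trait(tree, (0.0, 1.0), seed=12,
                                         states=["u", "g", "h"])
        res = ancthresh_mcmc(tree, tips, ["u", "g", "h"], ngen=2000, burnin=500,
                             seed=13)
        np.testing.assert_allclose(res.node_probabilities.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_single_state_data_concentrates_at_root(self):
        tree = sim_yule_tree(25, seed=14)
        tips = {t: "grooved" for t in tree.tip_labels}
        res = ancthresh_mcmc(tree, tips, ["unmodified", "grooved", "hollow"],
                             ngen=6000, burnin=1500, seed=15)
        root_id = res.node_probabilities.index[-1]
        assert res.node_probabilities.loc[root_id, "grooved"] >= 0.95

    def test_concentration_grows_with_chain_length(self):
        tree = sim_yule_tree(20, seed=16)
        tips = {t: "g" for t in tree.tip_labels}
        min_probs = []
        for ngen in (600, 3000, 12000):
            res = ancthresh_mcmc(tree, tips, ["u", "g", "h"], ngen=ngen,
                                 burnin=ngen // 5, seed=17)
            min_probs.append(res.node_probabilities["g"].min())
        assert min_probs[2] >= min_probs[0] - 0.05
        assert min_probs[2] > 0.8

    def test_three_and_four_state_agree_on_grooved_direction(self):
        """Where hollow/tubular states are absent, both codings should point
        the same way on P(grooved) at every node."""
        tree = sim_yule_tree(40, seed=18)
        tips, _, _ = sim_threshold_trait(
            tree, (0.0,), seed=19, states=["unmodified", "grooved"]
        )
        r3 = ancthresh_mcmc(tree, tips, ["unmodified", "grooved", "hollow"],
                            ngen=4000, burnin=1000, seed=20)
        r4 = ancthresh_mcmc(tree, tips,
                            ["unmodified", "grooved", "hollow", "tubular"],
                            ngen=4000, burnin=1000, seed=21)
        p3 = r3.node_probabilities["grooved"]
        p4 = r4.node_probabilities["grooved"]
        agree = ((p3 > 0.5) == (p4 > 0.5)) | (abs(p3 - p4) < 0.25)
        assert agree.mean() > 0.9

    def test_state_order_and_ngen_validation(self):
        tree = sim_yule_tree(10, seed=22)
        tips = {t: "x" for t in tree.tip_labels}
        with pytest.raises(ValueError):
            ancthresh_mcmc(tree, tips, ["a", "b"], ngen=100, burnin=50)
        with pytest.raises(ValueError):
            ancthresh_mcmc(tree, {t: "a" for t in tree.tip_labels}, ["a", "b"],
                           ngen=100, burnin=200)
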