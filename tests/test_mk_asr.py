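import itertools
import math

import numpy as np
import pytest

from paleotherm.mk_asr import (
    MkParams,
    brute_force_asr,
    fit_rate_ml,
    marginal_asr,
    transition_probability,
    tree_log_likelihood,
)
from paleotherm.synthetic_data import SimulationScenario, simulate_states, simulate_tree
from paleotherm.tree_time import TimeScaledTree

from .conftest import make_ts, random_states, random_ts


def enum_log_likelihood(ts, states, params):
    """Independent likelihood oracle: sum over all internal assignments."""
    internal = [n for n in ts.tree.preorder_node_iter() if not n.is_leaf()]
    prior = params.prior()
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = {n.id: s for n, s in zip(internal, combo)}
        w = prior[assign[ts.tree.seed_node.id]]
        for node in ts.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = ts.ages[node.parent_node.id] - ts.ages[node.id]
            P = transition_probability(t, params)
            cs = assign[node.id] if not node.is_leaf() else states[node.taxon.label]
            w *= P[assign[node.parent_node.id], cs]
        total += w
    return math.log(total)


class TestTransitionProbability:
    def test_identity_at_zero(self):
        P = transition_probability(0.0, MkParams.er(0.3))
        np.testing.assert_allclose(P, np.eye(2))

    def test_uniform_limit(self):
        P = transition_probability(1e6, MkParams.er(0.1))
        np.testing.assert_allclose(P, np.full((2, 2), 0.5), atol=1e-12)

    def test_er_closed_form(self):
        P = transition_probability(1.0, MkParams.er(0.5))
        stay = (1 + math.exp(-1.0)) / 2
        assert P[0, 0] == pytest.approx(0.683940, abs=1e-6)
        assert P[1, 1] == pytest.approx(stay)

    def test_rows_sum_to_one(self):
        P = transition_probability(3.7, MkParams(0.2, 0.05, model_form="ARD"))
        np.testing.assert_allclose(P.sum(axis=1), [1.0, 1.0], atol=1e-14)
        assert (P >= 0).all()

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            transition_probability(-1.0, MkParams.er(0.1))

    def test_zero_rates_identity(self):
        np.testing.assert_allclose(
            transition_probability(5.0, MkParams.er(0.0)), np.eye(2))


class TestMkParams:
    def test_er_requires_equal_rates(self):
        with pytest.raises(ValueError):
            MkParams(0.1, 0.2, model_form="ER")

    def test_stationary_prior(self):
        p = MkParams(0.3, 0.1, model_form="ARD", root_prior="stationary")
        np.testing.assert_allclose(p.prior(), [0.25, 0.75])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MkParams.er(-0.1)


CHERRY = ("(A,B)R;", {"A": 0.0, "B": 0.0, "R": 4.0})


class TestTreeLogLikelihood:
    def test_cherry_closed_form(self):
        t = 4.0
        params = MkParams.er(0.13)
        ts = make_ts(*CHERRY)
        P = transition_probability(t, params)
        expected = math.log((P[0, 0] ** 2 + P[1, 0] ** 2) / 2)
        got = tree_log_likelihood(ts, {"A": 0, "B": 0}, params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_change_limit(self):
        ts = make_ts("((A,B)X,C)R;",
                     {"A": 0.0, "B": 0.0, "C": 0.0, "X": 5.0, "R": 9.0})
        ll = tree_log_likelihood(ts, {"A": 1, "B": 1, "C": 1},
                                 MkParams.er(1e-12))
        assert ll == pytest.approx(math.log(0.5), abs=1e-9)

    def test_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            ts = random_ts(rng, int(rng.integers(3, 6)))
            states = random_states(rng, ts)
            params = MkParams.er(float(rng.uniform(0.005, 0.3)))
            got = tree_log_likelihood(ts, states, params)
            want = enum_log_likelihood(ts, states, params)
            assert got == pytest.approx(want, abs=1e-10)

    def test_child_order_invariance(self):
        ts1 = make_ts("((A,B)X,C)R;",
                      {"A": 0.0, "B": 1.0, "C": 0.0, "X": 5.0, "R": 9.0})
        ts2 = make_ts("(C,(B,A)X)R;",
                      {"A": 0.0, "B": 1.0, "C": 0.0, "X": 5.0, "R": 9.0})
        states = {"A": 0, "B": 1, "C": 1}
        params = MkParams.er(0.07)
        assert tree_log_likelihood(ts1, states, params) == pytest.approx(
            tree_log_likelihood(ts2, states, params), abs=1e-12)

    def test_missing_state_errors(self):
        ts = make_ts(*CHERRY)
        with pytest.raises(ValueError, match="B"):
            tree_log_likelihood(ts, {"A": 0}, MkParams.er(0.1))


class TestFitRateMl:
    def test_no_signal_pins_lower_bound(self):
        ts = make_ts("((A,B)X,C)R;",
                     {"A": 0.0, "B": 0.0, "C": 0.0, "X": 5.0, "R": 9.0})
        with pytest.warns(UserWarning, match="one state"):
            params = fit_rate_ml(ts, {"A": 0, "B": 0, "C": 0})
        assert params.q01 == pytest.approx(1e-8)

    def test_local_optimality(self):
        rng = np.random.default_rng(3)
        ts = random_ts(rng, 12)
        states = random_states(rng, ts, ensure_both=True)
        params = fit_rate_ml(ts, states)
        ll_hat = tree_log_likelihood(ts, states, params)
        for factor in (0.9, 1.1):
            other = MkParams.er(params.q01 * factor)
            assert ll_hat >= tree_log_likelihood(ts, states, other) - 1e-9

    def test_parameter_recovery(self):
        # states simulated under ER q=0.05 on 64-tip trees; the median
        # estimate across replicates must land in [0.025, 0.1]
        q_true = 0.05
        estimates = []
        for rep in range(50):
            scenario = SimulationScenario(n_extant=64, n_fossil=0,
                                          birth_rate=0.08, death_rate=0.0,
                                          seed=1000 + rep)
            tree, ages = simulate_tree(scenario)
            ts = TimeScaledTree(tree=tree, ages=ages, method="sim")
            states = simulate_states(tree, ages, MkParams.er(q_true),
                                     seed=2000 + rep)
            tips = {lf.taxon.label: states[lf.id]
                    for lf in tree.leaf_node_iter()}
            if len(set(tips.values())) < 2:
                continue
            estimates.append(fit_rate_ml(ts, tips).q01)
        assert len(estimates) >= 40
        assert 0.025 <= np.median(estimates) <= 0.1

    def test_ard_fit_runs(self):
        rng = np.random.default_rng(11)
        ts = random_ts(rng, 10)
        states = random_states(rng, ts, ensure_both=True)
        params = fit_rate_ml(ts, states, model_form="ARD")
        assert params.model_form == "ARD"
        assert params.log_likelihood is not None


class TestMarginalAsr:
    def test_tip_certainty(self):
        ts = make_ts(*CHERRY)
        probs = marginal_asr(ts, {"A": 0, "B": 1}, MkParams.er(0.2))
        np.testing.assert_allclose(probs["A"], [1.0, 0.0])
        np.testing.assert_allclose(probs["B"], [0.0, 1.0])

    def test_symmetric_cherry_root(self):
        ts = make_ts(*CHERRY)
        probs = marginal_asr(ts, {"A": 0, "B": 1}, MkParams.er(0.2))
        np.testing.assert_allclose(probs["R"], [0.5, 0.5], atol=1e-12)

    def test_five_tip_oracle(self):
        rng = np.random.default_rng(21)
        ts = random_ts(rng, 5)
        states = random_states(rng, ts)
        params = MkParams.er(0.1)
        got = marginal_asr(ts, states, params)
        want = brute_force_asr(ts, states, params)
        for nid in want:
            np.testing.assert_allclose(got[nid], want[nid], atol=1e-10)

    def test_normalized_everywhere(self):
        rng = np.random.default_rng(8)
        ts = random_ts(rng, 9)
        states = random_states(rng, ts)
        probs = marginal_asr(ts, states, MkParams.er(0.03))
        for vec in probs.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)

    def test_root_placement_invariance(self):
        # same unrooted duration tree rooted at two points on the X-Y path;
        # ER + flat prior marginals at shared nodes must agree
        states = {"A": 0, "B": 1, "C": 1, "D": 0}
        params = MkParams.er(0.12)
        t1 = make_ts("((A,B)X,(C,D)Y)R;",
                     {"A": 0.0, "B": 0.0, "X": 1.0, "R": 3.0,
                      "C": -1.0, "D": -1.0, "Y": 0.0})
        t2 = make_ts("((A,B)X,(C,D)Y)R;",
                     {"A": 0.0, "B": 0.0, "X": 1.0, "R": 2.0,
                      "C": -3.0, "D": -3.0, "Y": -2.0})
        p1 = marginal_asr(t1, states, params)
        p2 = marginal_asr(t2, states, params)
        for nid in ("A", "B", "C", "D", "X", "Y"):
            np.testing.assert_allclose(p1[nid], p2[nid], atol=1e-10)

    def test_soft_tips_match_oracle(self):
        rng = np.random.default_rng(31)
        ts = random_ts(rng, 6)
        tips = [lf.taxon.label for lf in ts.tree.leaf_node_iter()]
        states = {t: (float(p := rng.uniform()), float(1 - p)) for t in tips}
        params = MkParams.er(0.08)
        got = marginal_asr(ts, states, params)
        want = brute_force_asr(ts, states, params)
        for nid in want:
            np.testing.assert_allclose(got[nid], want[nid], atol=1e-10)


class TestBruteForceAsr:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        ts = random_ts(rng, 6)
        states = random_states(rng, ts)
        out = brute_force_asr(ts, states, MkParams.er(0.2))
        for vec in out.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)

    def test_low_rate_limit_consistent_states(self):
        ts = make_ts("((A,B)X,C)R;",
                     {"A": 0.0, "B": 0.0, "C": 0.0, "X": 5.0, "R": 9.0})
        out = brute_force_asr(ts, {"A": 1, "B": 1, "C": 1}, MkParams.er(1e-9))
        assert out["R"][1] == pytest.approx(1.0, abs=1e-6)

    def test_too_many_nodes_rejected(self):
        rng = np.random.default_rng(2)
        ts = random_ts(rng, 15)  # 14 internal nodes
        with pytest.raises(ValueError, match="12"):
            brute_force_asr(ts, random_states(rng, ts), MkParams.er(0.1))
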