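import numpy as np
import pytest

import mranet as m
from mranet.network import Condition, PerturbationDesign
from mranet.simulator import (
    SingularNetworkError,
    simulate_condition,
    simulate_design,
)


class TestLocalToGlobal:
    def test_feedforward_two_node(self):
        r = np.array([[-1.0, 0.0], [2.0, -1.0]])
        assert np.allclose(m.local_to_global(r, np.array([1.0, 0.0])), [1.0, 2.0])

    def test_with_feedback(self):
        r = np.array([[-1.0, -0.5], [2.0, -1.0]])
        assert np.allclose(m.local_to_global(r, np.array([1.0, 0.0])), [0.5, 1.0])

    def test_no_perturbation_gives_zero(self):
        r = np.array([[-1.0, 0.3], [0.7, -1.0]])
        assert np.allclose(m.local_to_global(r, np.zeros(2)), 0.0)

    def test_singular_matrix_rejected(self):
        r = np.array([[-1.0, 1.0], [1.0, -1.0]])  # loop product exactly 1
        with pytest.raises(SingularNetworkError):
            m.local_to_global(r, np.array([1.0, 0.0]))


class TestInhibitorAction:
    """The twofold inhibitor action on transmitted signal: basal offset l
    and stimulated dampening exp(l)."""

    def test_basal_action_alone(self, two_node):
        net, r = two_node
        x = simulate_condition(net, r, {"A": -1.0}, Condition("i", frozenset(), {"A"}))
        assert np.allclose(x, [0.0, -2.0])

    def test_combined_with_stimulation(self, two_node):
        net, r = two_node
        x = simulate_condition(
            net, r, {"A": -1.0}, Condition("si", {"A"}, {"A"})
        )
        assert np.isclose(x[0], 1.0)
        assert np.isclose(x[1], 2.0 * (np.exp(-1.0) - 1.0))  # ~ -1.2642

    def test_stimulus_alone(self, two_node):
        net, r = two_node
        x = simulate_condition(net, r, {}, Condition("s", {"A"}, frozenset()))
        assert np.allclose(x, [1.0, 2.0])

    def test_inhibited_nodes_own_response_unaltered(self, two_node):
        net, r = two_node
        x = simulate_condition(
            net, r, {"B": -2.0}, Condition("s+bi", {"A"}, {"B"})
        )
        # B has no outgoing edges: its own response must equal the
        # uninhibited one, and l_B must have no effect anywhere
        assert np.allclose(x, [1.0, 2.0])


class TestSimulateDesign:
    def test_three_condition_matrix(self, two_node):
        net, r = two_node
        design = PerturbationDesign(
            (
                Condition("s", {"A"}, frozenset()),
                Condition("i", frozenset(), {"A"}),
                Condition("si", {"A"}, {"A"}),
            ),
            (("A", "A"), ("B", "B")),
        )
        sim = simulate_design(net, r, {"A": -1.0}, design)
        expected = np.array(
            [[1.0, 2.0], [0.0, -2.0], [1.0, 2.0 * (np.exp(-1) - 1)]]
        )
        assert np.allclose(sim, expected, atol=1e-10)

    def test_all_control_design_is_zero(self, two_node):
        net, r = two_node
        design = PerturbationDesign(
            (Condition("ctrl"),), (("A", "A"), ("B", "B"))
        )
        sim = simulate_design(net, r, {}, design)
        assert np.allclose(sim, 0.0)

    def test_masked_cells_missing(self, two_node):
        net, r = two_node
        design = PerturbationDesign(
            (Condition("i", frozenset(), {"A"}), Condition("s", {"A"})),
            (("A", "A"), ("B", "B")),
            masked={("A", "A")},
        )
        sim = simulate_design(net, r, {"A": -1.0}, design)
        assert np.isnan(sim[0, 0])  # masked where A inhibited
        assert np.isfinite(sim[1, 0])  # not masked elsewhere

    def test_linearity_in_stimuli(self):
        net = m.SignalingNetwork(
            ("S1", "S2", "X", "Y"),
            (("S1", "X"), ("S2", "X"), ("X", "Y"), ("Y", "X")),
            {"S1", "S2"},
        )
        rng = np.random.default_rng(3)
        r = -np.eye(4)
        idx = {n: i for i, n in enumerate(net.nodes)}
        for s, t in net.edges:
            r[idx[t], idx[s]] = rng.normal(0, 0.8)
        lv = {"X": -1.2}
        inh = frozenset({"X"})
        both = simulate_condition(net, r, lv, Condition("b", {"S1", "S2"}, inh))
        s1 = simulate_condition(net, r, lv, Condition("1", {"S1"}, inh))
        s2 = simulate_condition(net, r, lv, Condition("2", {"S2"}, inh))
        none = simulate_condition(net, r, lv, Condition("0", frozenset(), inh))
        assert np.allclose(both, s1 + s2 - none, atol=1e-10)


class TestFixedPointOracle:
    """simulate_condition must agree with damped fixed-point iteration of
    x_j = sum_k r_jk xt_k + p_j on random stable networks."""

    @staticmethod
    def fixed_point(net, r, l_values, condition, iters=20000):
        n = len(net.nodes)
        idx = {node: i for i, node in enumerate(net.nodes)}
        p = np.zeros(n)
        for s in condition.stimulated:
            p[idx[s]] += 1.0
        x = np.zeros(n)
        damp = 0.5
        for _ in range(iters):
            xt = x.copy()
            for k in condition.inhibited:
                kk = idx[k]
                xt[kk] = np.exp(l_values[k]) * x[kk] + l_values[k]
            total = p.copy()
            for (s, t) in net.edges:
                total[idx[t]] += r[idx[t], idx[s]] * xt[idx[s]]
            x_new = (1 - damp) * x + damp * total
            if np.max(np.abs(x_new - x)) < 1e-14:
                return x_new
            x = x_new
        return x

    @pytest.mark.parametrize("seed", range(15))
    def test_agreement_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(3, 7))
        net = m.random_network(
            n_nodes, n_extra_edges=2, seed=seed, acyclic=bool(seed % 2)
        )
        idx = {node: i for i, node in enumerate(net.nodes)}
        r = -np.eye(n_nodes)
        for s, t in net.edges:
            r[idx[t], idx[s]] = rng.uniform(-0.6, 0.6)
        targets = [n for n in net.nodes if n not in net.stimuli]
        k = targets[int(rng.integers(0, len(targets)))]
        lv = {k: float(rng.uniform(-2, -0.2))}
        cond = Condition("c", frozenset({"S"}), frozenset({k}))
        direct = simulate_condition(net, r, lv, cond)
        iterated = self.fixed_point(net, r, lv, cond)
        assert np.allclose(direct, iterated, atol=1e-10)
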