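import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mranet as m
from mranet.uncertainty import BIN_LABELS, bin_coefficient, compose_path

from conftest import quick_config


@pytest.fixture(scope="module")
def fitted_chain():
    net = m.SignalingNetwork(("S", "A", "B"), (("S", "A"), ("A", "B")), {"S"})
    design = m.systematic_design(net)
    truth = m.generate_ground_truth(net, design, seed=1)
    data = m.generate_dataset(truth, noise_sd=0.1, seed=2, error_mode="exact")
    fit = m.fit_model(net, design, data, quick_config())
    return net, design, truth, data, fit


class TestBinning:
    @pytest.mark.parametrize(
        "value, label",
        [
            (1.5, "amplification"),
            (1.0, "dampening to neutral relay"),
            (0.3, "dampening to neutral relay"),
            (0.0, "no link"),
            (-0.5, "attenuating to neutral inhibition"),
            (-1.0, "attenuating to neutral inhibition"),
            (-1.2, "enforced inhibition"),
        ],
    )
    def test_five_states(self, value, label):
        assert bin_coefficient(value) == label

    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_real_line(self, value):
        assert bin_coefficient(value) in BIN_LABELS


class TestComposePath:
    @pytest.mark.parametrize(
        "values, expected",
        [([2.0, 0.5], 1.0), ([-0.5, -2.0], 1.0), ([3.0], 3.0), ([-1.0, 2.0, 0.5], -1.0)],
    )
    def test_products_and_sign_rule(self, values, expected):
        assert compose_path(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compose_path([])


class TestConsensus:
    @staticmethod
    def toy_model(edges, values, seed=0):
        nodes = []
        for s, t in edges:
            for n in (s, t):
                if n not in nodes:
                    nodes.append(n)
        net = m.SignalingNetwork(tuple(nodes), tuple(edges), frozenset({"S"}))
        design = m.systematic_design(net)
        model = m.generate_ground_truth(net, design, seed=seed)
        for (s, t), v in values.items():
            from mranet.identifiability import Symbol

            model.raw[model.param.symbols.index(Symbol.edge(s, t))] = v
        return model

    def test_three_of_four_kept_two_dropped(self):
        shared = [("S", "A"), ("A", "B")]
        extra = ("A", "C")
        rare = ("B", "C")
        models = [
            self.toy_model(shared + [extra, rare], {e: 2.0 for e in shared}),
            self.toy_model(shared + [extra], {e: 1.5 for e in shared}),
            self.toy_model(shared + [extra], {e: 1.5 for e in shared}),
            self.toy_model(shared + [rare], {e: 0.5 for e in shared}),
        ]
        net = m.consensus_network(models, k=3)
        edges = net.edge_set()
        assert set(shared) <= edges
        assert extra in edges  # present in 3 of 4
        assert rare not in edges  # present in 2 of 4

    def test_identical_quartet_reproduces_member(self):
        edges = [("S", "A"), ("A", "B")]
        models = [self.toy_model(edges, {("S", "A"): 2.0, ("A", "B"): -0.5})] * 4
        net = m.consensus_network(models, k=4)
        assert net.edge_set() == set(edges)
        by_edge = {(e.source, e.target): e for e in net.edges}
        assert by_edge[("S", "A")].consensus_state == "amplification"
        assert (
            by_edge[("A", "B")].consensus_state
            == "attenuating to neutral inhibition"
        )

    def test_k_one_is_union_k_n_is_intersection(self):
        a = self.toy_model([("S", "A"), ("A", "B")], {})
        b = self.toy_model([("S", "A"), ("A", "C")], {})
        union = m.consensus_network([a, b], k=1).edge_set()
        inter = m.consensus_network([a, b], k=2).edge_set()
        assert union == {("S", "A"), ("A", "B"), ("A", "C")}
        assert inter == {("S", "A")}

    def test_k_above_model_count_rejected(self):
        a = self.toy_model([("S", "A")], {})
        with pytest.raises(ValueError, match="exceeds"):
            m.consensus_network([a], k=2)


class TestProfileLikelihood:
    def test_ci_contains_truth_on_calibrated_data(self, fitted_chain):
        _net, _design, truth, data, fit = fitted_chain
        for name, tv in truth.path_values().items():
            pr = m.profile_likelihood(fit, data, name)
            assert pr.contains(tv), f"{name}: truth {tv} outside CI"
            assert pr.lower <= pr.estimate <= pr.upper

    def test_ci_collapses_as_noise_vanishes(self):
        net = m.SignalingNetwork(("S", "A", "B"), (("S", "A"), ("A", "B")), {"S"})
        design = m.systematic_design(net)
        truth = m.generate_ground_truth(net, design, seed=5)
        sharp = m.FitConfig(
            n_starts=8, seed=0, sign_flip_rounds=2, error_floor=1e-9
        )
        widths = []
        for sd in (0.2, 0.02):
            data = m.generate_dataset(
                truth, noise_sd=sd, seed=6, error_mode="exact"
            )
            fit = m.fit_model(net, design, data, sharp)
            pr = m.profile_likelihood(fit, data, "r_B_A", config=sharp)
            widths.append(pr.upper - pr.lower)
        assert widths[1] < widths[0] / 3
        assert abs(pr.estimate - truth.path_values()["r_B_A"]) < 0.05

    def test_structural_redundancy_flagged_ni(self):
        """Parallel routes through a measured but never separately
        perturbed relay (A->B direct vs A->Z->B): only the sum of the two
        routes is constrained, so either branch coefficient is
        non-identifiable in both directions."""
        net = m.SignalingNetwork(
            ("S", "A", "Z", "B"),
            (("S", "A"), ("A", "Z"), ("A", "B"), ("Z", "B")),
            {"S"},
        )
        design = m.PerturbationDesign(
            (
                m.Condition("s", frozenset({"S"}), frozenset()),
                m.Condition("ai", frozenset(), frozenset({"A"})),
                m.Condition("ai+s", frozenset({"S"}), frozenset({"A"})),
            ),
            (("A", "A"), ("Z", "Z"), ("B", "B")),
        )
        truth = m.generate_ground_truth(net, design, seed=9)
        data = m.generate_dataset(truth, noise_sd=0.05, seed=10, error_mode="exact")
        fit = m.fit_model(net, design, data, quick_config())
        assert fit.n_parameters < len(fit.model.param.paths) + len(
            [s for s in fit.model.param.symbols if s.kind == "i"]
        )
        pr = m.profile_likelihood(fit, data, "r_B_A", bound=50.0)
        assert pr.ni_lower and pr.ni_upper

    def test_fixed_path_cannot_be_profiled(self, fitted_chain):
        net, design, _truth, data, fit = fitted_chain
        refit = m.refit_with_fixed_inhibitors(
            fit, {"i_A": -1.0}, data, quick_config()
        )
        with pytest.raises(ValueError, match="fixed"):
            m.profile_likelihood(refit, data, "i_A")


class TestCompareAndTransfer:
    def test_identical_models_not_flagged(self, fitted_chain):
        _net, _design, _truth, data, fit = fitted_chain
        cmp_result = m.compare_models([fit, fit], [data, data])
        assert cmp_result.significantly_different() == []

    def test_tenfold_difference_flagged(self):
        net = m.SignalingNetwork(("S", "A", "B"), (("S", "A"), ("A", "B")), {"S"})
        design = m.systematic_design(net)
        truth_a = m.generate_ground_truth(net, design, seed=20)
        truth_b = m.generate_ground_truth(net, design, seed=20)
        from mranet.identifiability import Symbol

        j = truth_b.param.symbols.index(Symbol.edge("A", "B"))
        truth_b.raw[j] *= 10.0
        flagged = 0
        runs = 5
        for k in range(runs):
            data_a = m.generate_dataset(truth_a, noise_sd=0.1, seed=40 + k, error_mode="exact")
            data_b = m.generate_dataset(truth_b, noise_sd=0.1, seed=60 + k, error_mode="exact")
            fit_a = m.fit_model(net, design, data_a, quick_config(seed=k))
            fit_b = m.fit_model(net, design, data_b, quick_config(seed=k))
            cmp_result = m.compare_models([fit_a, fit_b], [data_a, data_b])
            flagged += "r_B_A" in cmp_result.significantly_different()
        assert flagged >= runs - 1

    def test_individual_links_reported_not_flagged(self, fitted_chain):
        net, design, truth, data, fit = fitted_chain
        wider = net.with_edge("S", "B")
        truth2 = m.generate_ground_truth(wider, design, seed=21)
        data2 = m.generate_dataset(truth2, noise_sd=0.1, seed=22, error_mode="exact")
        fit2 = m.fit_model(wider, design, data2, quick_config())
        cmp_result = m.compare_models([fit, fit2], [data, data2])
        assert "r_B_S" in cmp_result.individual[1]
        assert "r_B_S" not in cmp_result.significant

    def test_transfer_to_own_data_matches_native_fit(self, fitted_chain):
        net, design, _truth, data, fit = fitted_chain
        tr = m.transfer_structure(net, design, data, quick_config())
        assert tr.wssr_fit == pytest.approx(fit.wssr_fit, rel=1e-6)
        assert tr.n_parameters == fit.n_parameters

    def test_transfer_of_wrong_structure_fits_worse(self):
        net = m.SignalingNetwork(
            ("S", "A", "B"), (("S", "A"), ("A", "B")), {"S"}
        )
        design = m.systematic_design(net)
        truth = m.generate_ground_truth(net, design, seed=33)
        data = m.generate_dataset(truth, noise_sd=0.05, seed=34, error_mode="exact")
        native = m.fit_model(net, design, data, quick_config())
        # wrong topology: B fed directly by S, no A->B route
        wrong = m.SignalingNetwork(("S", "A", "B"), (("S", "A"), ("S", "B")), {"S"})
        transferred = m.transfer_structure(wrong, design, data, quick_config())
        assert transferred.wssr_fit > native.wssr_fit + 10
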