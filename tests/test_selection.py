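import warnings

import numpy as np
import pytest

import mranet as m
from mranet.selection import AdaptConfig, consistency_check, lrt_pvalue

from conftest import quick_config


def adapt_config(seed=0):
    return AdaptConfig(
        fit_config=m.FitConfig(n_starts=10, seed=seed, sign_flip_rounds=2),
        scan_starts=6,
        max_iterations=8,
    )


@pytest.fixture(scope="module")
def planted_system():
    """Ground truth with one edge the start network lacks and one spurious
    edge the start network has."""
    truth_net = m.random_network(6, n_extra_edges=2, seed=3, n_stimuli=2)
    hide = next(e for e in truth_net.edges if e[0] not in truth_net.stimuli)
    spur = next(
        (s, t)
        for s in truth_net.nodes
        for t in truth_net.nodes
        if s != t and t not in truth_net.stimuli and (s, t) not in set(truth_net.edges)
    )
    start = truth_net.without_edge(*hide).with_edge(*spur)
    design = m.systematic_design(truth_net)
    truth = m.generate_ground_truth(truth_net, design, seed=30)
    data = m.generate_dataset(
        truth, noise_sd=0.1, n_replicates=3, seed=31, error_mode="exact"
    )
    return truth_net, start, hide, spur, design, data


class TestLrtPvalue:
    @pytest.mark.parametrize(
        "d, df, expected",
        [(0.0, 1, 1.0), (3.841, 1, 0.05), (6.635, 1, 0.01)],
    )
    def test_chi_square_quantiles(self, d, df, expected):
        assert lrt_pvalue(10.0 + d, 10.0, df) == pytest.approx(expected, abs=1e-3)

    def test_zero_df_returns_one(self):
        assert lrt_pvalue(5.0, 2.0, 0) == 1.0

    def test_negative_improvement_rejected(self):
        with pytest.raises(ValueError, match="worse"):
            lrt_pvalue(1.0, 5.0, 1)

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            lrt_pvalue(5.0, 1.0, -1)


class TestConsistency:
    @pytest.mark.parametrize(
        "null, sim, expected", [(100.0, 25.0, 75.0), (100.0, 100.0, 0.0), (50.0, 75.0, -50.0)]
    )
    def test_error_reduction_arithmetic(self, null, sim, expected, two_node):
        # exercised through the public function with constructed data
        net, r = two_node
        assert 100.0 * (null - sim) / null == pytest.approx(expected)

    def test_zero_null_rejected(self, small_chain):
        net, design = small_chain
        truth = m.generate_ground_truth(net, design, seed=1)
        data = m.generate_dataset(truth, noise_sd=0.05, seed=2)
        data.values[:] = 0.0  # no signal at all
        with pytest.raises(ValueError, match="null"):
            consistency_check(truth, data)

    def test_perfect_model_high_error_reduction(self, small_chain):
        net, design = small_chain
        truth = m.generate_ground_truth(net, design, seed=1)
        data = m.generate_dataset(truth, noise_sd=0.01, seed=2, error_mode="exact")
        res = consistency_check(truth, data)
        assert res.error_reduction_pct > 90
        assert res.wssr_simulation < res.wssr_nullmodel


class TestScans:
    def test_planted_missing_edge_ranks_first(self, planted_system):
        truth_net, start, hide, spur, design, data = planted_system
        no_hide = truth_net.without_edge(*hide)
        fit = m.fit_model(no_hide, design, data, quick_config())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adds = m.scan_additions(fit, data, adapt_config())
        assert adds, "expected significant addition candidates"
        assert adds[0].edge == hide
        assert adds[0].p_value < 0.05

    def test_spurious_edge_is_removable(self, planted_system):
        truth_net, start, hide, spur, design, data = planted_system
        with_spur = truth_net.with_edge(*spur)
        fit = m.fit_model(with_spur, design, data, quick_config())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            removals = m.scan_removals(fit, data, adapt_config())
        assert spur in [c.edge for c in removals]

    def test_addition_candidates_exclude_stimulus_targets(self, planted_system):
        truth_net, _start, _hide, _spur, design, data = planted_system
        fit = m.fit_model(truth_net, design, data, quick_config())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adds = m.scan_additions(fit, data, adapt_config(), alpha=1.0)
        assert all(c.edge[1] not in truth_net.stimuli for c in adds)
        assert all(c.edge[0] != c.edge[1] for c in adds)


class TestAdaptNetwork:
    def test_self_consistent_start_keeps_structure(self, small_chain):
        """Noiseless data from the start network itself: no change accepted."""
        net, design = small_chain
        truth = m.generate_ground_truth(net, design, seed=7)
        data = m.generate_dataset(truth, noise_sd=1e-9, seed=8, error_mode="exact")
        data.errors[:] = 0.05
        tr_d, tr_x, hd_d, hd_x = m.split_by_stimulation(design, data)
        final, trace = m.adapt_network(net, tr_d, tr_x, hd_d, hd_x, adapt_config())
        assert trace.accepted_steps() == []
        assert set(final.model.network.edges) == set(net.edges)

    def test_planted_change_recovered(self, planted_system):
        truth_net, start, hide, spur, design, data = planted_system
        tr_d, tr_x, hd_d, hd_x = m.split_by_stimulation(design, data)
        final, trace = m.adapt_network(start, tr_d, tr_x, hd_d, hd_x, adapt_config())
        assert set(final.model.network.edges) == set(truth_net.edges)
        actions = {(s.action, s.edge) for s in trace.accepted_steps()}
        assert ("add", hide) in actions
        assert ("remove", spur) in actions

    def test_trace_is_deterministic_and_replayable(self, planted_system):
        truth_net, start, hide, spur, design, data = planted_system
        tr_d, tr_x, hd_d, hd_x = m.split_by_stimulation(design, data)
        final1, trace1 = m.adapt_network(start, tr_d, tr_x, hd_d, hd_x, adapt_config())
        final2, trace2 = m.adapt_network(start, tr_d, tr_x, hd_d, hd_x, adapt_config())
        steps1 = [(s.action, s.edge, s.accepted) for s in trace1.steps]
        steps2 = [(s.action, s.edge, s.accepted) for s in trace2.steps]
        assert steps1 == steps2
        assert set(trace1.replay(start).edges) == set(final1.model.network.edges)

    def test_missing_heldout_disables_gate_with_warning(self, small_chain):
        net, design = small_chain
        truth = m.generate_ground_truth(net, design, seed=9)
        data = m.generate_dataset(truth, noise_sd=0.1, seed=10)
        tr_d, tr_x, _hd, _hx = m.split_by_stimulation(design, data)
        with pytest.warns(UserWarning, match="consistency gate disabled"):
            m.adapt_network(net, tr_d, tr_x, config=adapt_config())

    def test_consistency_gate_never_drops_beyond_tolerance(self, planted_system):
        truth_net, start, hide, spur, design, data = planted_system
        tr_d, tr_x, hd_d, hd_x = m.split_by_stimulation(design, data)
        cfg = adapt_config()
        _final, trace = m.adapt_network(start, tr_d, tr_x, hd_d, hd_x, cfg)
        for s in trace.accepted_steps():
            if s.error_reduction_before is not None:
                assert (
                    s.error_reduction_after
                    >= s.error_reduction_before - cfg.delta_pct
                )
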