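import numpy as np
import pytest

import mranet as m
from mranet.synth import GroundTruthConfig, bcr_design_fixture


class TestBcrFixture:
    def test_study_layout_counts(self):
        net, design = bcr_design_fixture("bl")
        assert design.n_readouts == 14
        inhibitors = design.inhibited_nodes()
        assert len(inhibitors) == 8
        assert design.n_conditions == 17  # aIgM + 8 x (inhib, inhib+aIgM)
        assert design.stimulated_nodes() == ("BCR",)

    def test_dlbcl_variant_has_no_stimulation(self):
        _net, design = bcr_design_fixture("dlbcl")
        assert all(not c.stimulated for c in design.conditions)
        assert design.n_conditions == 8

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            bcr_design_fixture("hela")

    def test_fixture_validates(self):
        net, design = bcr_design_fixture("bl")
        report = m.validate_design(net, design)
        # RAF and p38 are interior unmeasured nodes of the encoding
        assert "RAF" not in design.readout_nodes
        assert report.n_masked_cells == 4


class TestGenerateGroundTruth:
    def test_deterministic_under_seed(self, small_chain):
        net, design = small_chain
        a = m.generate_ground_truth(net, design, seed=42)
        b = m.generate_ground_truth(net, design, seed=42)
        assert np.array_equal(a.raw, b.raw)

    def test_degenerate_magnitude_range(self, small_chain):
        net, design = small_chain
        cfg = GroundTruthConfig(mag_range=(1.0, 1.0))
        model = m.generate_ground_truth(net, design, cfg, seed=1)
        for (s, t) in net.edges:
            assert model.edge_value(s, t) == pytest.approx(1.0)

    def test_inhibitor_strengths_negative(self, small_chain):
        net, design = small_chain
        for seed in range(5):
            model = m.generate_ground_truth(net, design, seed=seed)
            assert all(v < 0 for v in model.l_values().values())

    def test_random_signs_policy(self, small_chain):
        net, design = small_chain
        cfg = GroundTruthConfig(sign_policy="random")
        signs = set()
        for seed in range(10):
            model = m.generate_ground_truth(net, design, cfg, seed=seed)
            signs.update(np.sign(model.edge_value(s, t)) for s, t in net.edges)
        assert signs == {-1.0, 1.0}


class TestGenerateDataset:
    def test_noiseless_limit_reproduces_simulation(self, small_chain):
        net, design = small_chain
        model = m.generate_ground_truth(net, design, seed=3)
        data = m.generate_dataset(model, noise_sd=0.0, seed=4)
        assert np.allclose(data.values, model.simulate(), equal_nan=True)

    def test_sem_magnitude(self):
        net, design = bcr_design_fixture("bl")
        model = m.generate_ground_truth(net, design, seed=5)
        sd = 0.3
        data = m.generate_dataset(model, noise_sd=sd, n_replicates=3, seed=6)
        observed = data.errors[np.isfinite(data.errors)]
        # sample SEM: mean c4(3)*sd/sqrt(3) with c4 ~ 0.886
        assert np.mean(observed) == pytest.approx(sd / np.sqrt(3), rel=0.2)
        exact = m.generate_dataset(
            model, noise_sd=sd, n_replicates=3, seed=6, error_mode="exact"
        )
        assert np.allclose(
            exact.errors[np.isfinite(exact.errors)], sd / np.sqrt(3)
        )

    def test_deterministic_under_seed(self, small_chain):
        net, design = small_chain
        model = m.generate_ground_truth(net, design, seed=7)
        a = m.generate_dataset(model, noise_sd=0.2, seed=8)
        b = m.generate_dataset(model, noise_sd=0.2, seed=8)
        assert np.array_equal(a.values, b.values, equal_nan=True)
        assert np.array_equal(a.errors, b.errors, equal_nan=True)

    def test_masked_cells_missing(self):
        net, design = bcr_design_fixture("bl")
        model = m.generate_ground_truth(net, design, seed=9)
        data = m.generate_dataset(model, noise_sd=0.1, seed=10)
        assert np.isnan(data.values[design.mask_matrix()]).all()

    def test_too_few_replicates_rejected(self, small_chain):
        net, design = small_chain
        model = m.generate_ground_truth(net, design, seed=11)
        with pytest.raises(ValueError, match="replicates"):
            m.generate_dataset(model, n_replicates=1, seed=12)

    def test_per_readout_noise_vector(self, small_chain):
        net, design = small_chain
        model = m.generate_ground_truth(net, design, seed=13)
        sds = np.array([0.05, 0.5])
        data = m.generate_dataset(
            model, noise_sd=sds, n_replicates=3, seed=14, error_mode="exact"
        )
        assert np.allclose(data.errors[:, 0], 0.05 / np.sqrt(3))
        assert np.allclose(data.errors[:, 1], 0.5 / np.sqrt(3))


class TestStimulationContrast:
    def test_stimulated_responses_richer_than_basal(self):
        """With moderate basal throughput the unstimulated inhibitor
        conditions show visibly less response spread than the stimulated
        ones, as in the study's heat maps."""
        net, design = bcr_design_fixture("bl")
        model = m.generate_ground_truth(net, design, seed=15)
        data = m.generate_dataset(model, noise_sd=0.1, seed=16)
        stim_rows = [i for i, c in enumerate(design.conditions) if c.stimulated]
        basal_rows = [
            i
            for i, c in enumerate(design.conditions)
            if not c.stimulated and c.inhibited
        ]
        v_stim = np.nanvar(data.values[stim_rows])
        v_basal = np.nanvar(data.values[basal_rows])
        assert v_stim > v_basal


class TestEndToEndRecovery:
    def test_identifiable_paths_recovered_within_ten_percent(self):
        """Median relative error of identifiable path values < 10% at the
        study-like noise level (0.1 log2 units, n = 3)."""
        errors = []
        for seed in range(6):
            net = m.random_network(6, n_extra_edges=2, seed=seed, n_stimuli=2)
            design = m.systematic_design(net)
            truth = m.generate_ground_truth(net, design, seed=100 + seed)
            data = m.generate_dataset(
                truth, noise_sd=0.1, n_replicates=3, seed=200 + seed
            )
            fit = m.fit_model(
                net, design, data,
                m.FitConfig(n_starts=10, seed=seed, sign_flip_rounds=2),
            )
            tv = truth.path_values()
            for name, est in fit.model.path_values().items():
                if abs(tv[name]) > 1e-9:
                    errors.append(abs(est - tv[name]) / abs(tv[name]))
        assert np.median(errors) < 0.10
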