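"""Ground-truth generators: construction invariants and sampling statistics."""

import numpy as np
import pytest
from scipy.stats import chisquare

from msmbind.synthetic import (
    GroundTruthSpec,
    ToyBinderSpec,
    build_ground_truth_model,
    default_ground_truth_spec,
    sample_markov_chain,
    simulate_toy_binder,
)


class TestGroundTruthModel:
    def test_single_conformation_symmetric_two_state(self, two_state_spec):
        m = build_ground_truth_model(two_state_spec)
        T = m.transition_matrix
        a = T[0, 1]
        assert 0 < a < 1
        np.testing.assert_allclose(T, [[1 - a, a], [a, 1 - a]], atol=1e-14)
        np.testing.assert_allclose(m.stationary_distribution, [0.5, 0.5], atol=1e-14)

    @pytest.mark.parametrize("n_conf,hub", [(3, 0), (3, 1), (5, 2), (7, 0)])
    def test_detailed_balance_by_construction(self, n_conf, hub):
        spec = GroundTruthSpec(
            n_conformations=n_conf,
            substates_per_conformation=[["bound", "associated", "unbound"]] * n_conf,
            hub_index=hub,
        )
        m = build_ground_truth_model(spec)
        pi, T = m.stationary_distribution, m.transition_matrix
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-12

    def test_stationary_weights_reproduced_exactly(self, ten_state_model):
        w = np.concatenate(ten_state_model.spec.substate_stationary_weights)
        np.testing.assert_allclose(
            ten_state_model.stationary_distribution, w / w.sum(), atol=1e-14
        )

    def test_hub_topology_zero_blocks_between_non_hub_conformations(self):
        spec = GroundTruthSpec(
            n_conformations=3,
            substates_per_conformation=[["bound", "unbound"]] * 3,
            hub_index=1,
        )
        m = build_ground_truth_model(spec)
        T = m.transition_matrix
        conf = m.conformation_labels
        # conformations 0 and 2 may only couple through the hub (1)
        blk = T[np.ix_(conf == 0, conf == 2)]
        assert np.all(blk == 0)
        assert np.all(T[np.ix_(conf == 2, conf == 0)] == 0)
        # but each couples to the hub
        assert T[np.ix_(conf == 0, conf == 1)].sum() > 0

    def test_timescale_separation_at_weight_ratio_50(self):
        for n_conf in (3, 5, 7):
            spec = GroundTruthSpec(
                n_conformations=n_conf,
                substates_per_conformation=[["bound", "unbound"]] * n_conf,
                conformational_exchange_weight=1e-3,
                binding_exchange_weight=0.05,  # ratio 50
            )
            m = build_ground_truth_model(spec)
            ts = m.timescales(n_conf)
            assert ts[n_conf - 2] / ts[n_conf - 1] >= 5.0

    def test_rejects_fast_conformational_exchange(self):
        with pytest.raises(ValueError, match="binding_exchange_weight"):
            GroundTruthSpec(
                n_conformations=2,
                conformational_exchange_weight=0.2,
                binding_exchange_weight=0.1,
            )

    def test_rejects_conformation_without_bound_substate(self):
        with pytest.raises(ValueError, match="bound"):
            GroundTruthSpec(
                n_conformations=2,
                substates_per_conformation=[["unbound"], ["bound", "unbound"]],
            )

    def test_rejects_excessive_coupling_with_diagnostic(self):
        spec = GroundTruthSpec(
            n_conformations=2,
            substates_per_conformation=[["bound", "unbound"]] * 2,
            conformational_exchange_weight=0.5,
            binding_exchange_weight=0.9,
        )
        with pytest.raises(ValueError, match="microstate"):
            build_ground_truth_model(spec)

    def test_default_preset_structure(self, preset_model):
        m = preset_model
        assert m.spec.n_conformations == 7
        # exactly one bound-only conformation (ligand-induced state)
        only_bound = [
            c for c, subs in enumerate(m.spec.substates_per_conformation)
            if subs == ["bound"]
        ]
        assert len(only_bound) == 1
        assert m.is_reversible(1e-12)


class TestSampling:
    def test_identity_matrix_is_absorbing(self):
        from msmbind.msm import TransitionModel

        m = TransitionModel(np.eye(3), np.ones(3) / 3)
        d = sample_markov_chain(m, 10, start_state=0, seed=1)
        assert np.all(d.states == 0)
        assert len(d) == 11

    def test_occupancy_matches_stationary_distribution(self):
        from msmbind.msm import TransitionModel

        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = TransitionModel(T, np.array([2 / 3, 1 / 3]))
        n = 1_000_000
        d = sample_markov_chain(m, n, start_state=0, seed=42)
        occ0 = np.mean(d.states == 0)
        # binomial-scale error inflated by the chain's autocorrelation time
        sigma = np.sqrt((2 / 3) * (1 / 3) / n) * np.sqrt((1 + 0.7) / (1 - 0.7))
        assert abs(occ0 - 2 / 3) < 3 * sigma

    def test_determinism_same_seed(self, ten_state_model):
        a = sample_markov_chain(ten_state_model, 1000, seed=7)
        b = sample_markov_chain(ten_state_model, 1000, seed=7)
        np.testing.assert_array_equal(a.states, b.states)
        c = sample_markov_chain(ten_state_model, 1000, seed=8)
        assert not np.array_equal(a.states, c.states)

    def test_zero_steps_single_frame_flagged(self, ten_state_model):
        with pytest.warns(UserWarning, match="single-frame"):
            d = sample_markov_chain(ten_state_model, 0, start_state=3, seed=0)
        assert len(d) == 1

    def test_long_run_ergodicity_chi_square(self, preset_model):
        """Empirical occupancy of a 10^6-step chain is consistent with pi."""
        n = 1_000_000
        d = sample_markov_chain(preset_model, n, seed=11)
        counts = np.bincount(d.states, minlength=preset_model.n_states)
        pi = preset_model.stationary_distribution
        # thin to roughly independent samples before the goodness-of-fit test
        t_slow = preset_model.timescales(1)[0]
        stride = int(5 * t_slow)
        thin = d.states[::stride]
        counts = np.bincount(thin, minlength=preset_model.n_states)
        _, p = chisquare(counts, pi * counts.sum())
        assert p > 0.01
        assert np.all(np.bincount(d.states, minlength=preset_model.n_states) > 0)


class TestToyBinder:
    def test_zero_noise_at_minimum_stays_constant(self):
        spec = ToyBinderSpec(
            x_well_positions=(0.0,), x_spring=2.0, bound_depth=0.0,
            noise_amplitude=0.0, diffusion=1e-12, seed=0,
            mixing_matrix=np.eye(2),
        )
        # vanishing diffusion: no thermal kicks and no drift at the minimum
        ft = simulate_toy_binder(spec, 100, start=(0.0, spec.r_unbound))
        np.testing.assert_allclose(ft.values[:, 0], 0.0, atol=1e-5)
        np.testing.assert_allclose(ft.ligand_distances, spec.r_unbound, atol=1e-5)

    def test_harmonic_well_equipartition(self):
        k_spring = 3.0
        spec = ToyBinderSpec(
            x_well_positions=(0.0,), x_spring=k_spring, bound_depth=0.0,
            kT=1.0, timestep=2e-3, noise_amplitude=0.0,
            mixing_matrix=np.eye(2), seed=123,
        )
        ft = simulate_toy_binder(spec, 400_000, start=(0.0, spec.r_unbound))
        var = ft.values[20_000:, 0].var()
        assert abs(var - spec.kT / k_spring) / (spec.kT / k_spring) < 0.05

    def test_high_barrier_no_well_crossing(self):
        spec = ToyBinderSpec(
            x_well_positions=(-1.0, 1.0), x_barrier_height=20.0, kT=1.0,
            bound_depth=0.0, timestep=1e-3, seed=5, mixing_matrix=np.eye(2),
            noise_amplitude=0.0,
        )
        ft = simulate_toy_binder(spec, 50_000, start=(-1.0, spec.r_unbound))
        assert np.all(ft.values[:, 0] < 0)  # Kramers time >> run length

    def test_unstable_integration_reports_step(self):
        spec = ToyBinderSpec(
            x_well_positions=(-1.0, 1.0), x_barrier_height=5.0,
            timestep=5.0, seed=0, box_bound=10.0,
        )
        with pytest.raises(FloatingPointError, match="step"):
            simulate_toy_binder(spec, 10_000)

    def test_ligand_distance_column_is_raw_r(self):
        spec = ToyBinderSpec(seed=2)
        ft = simulate_toy_binder(spec, 500)
        assert ft.feature_names[ft.ligand_distance_column] == "site_ligand_distance"
        assert np.all(ft.ligand_distances >= 0)
        assert ft.n_features == spec.mixing_matrix.shape[0] + 1

    def test_bound_occupancy_monotone_in_well_depth(self):
        occ = []
        for depth in (1.0, 3.0, 5.0):
            spec = ToyBinderSpec(
                x_well_positions=(1.0,), x_spring=4.0, bound_depth=depth,
                gate_x_well=-1, r_spring=0.1, kT=1.0, timestep=2e-3, seed=77,
                mixing_matrix=np.eye(2), noise_amplitude=0.0,
            )
            ft = simulate_toy_binder(spec, 200_000, start=(1.0, spec.r_bound))
            occ.append(np.mean(ft.ligand_distances < 6.0))
        assert occ[0] < occ[1] < occ[2]

    def test_reproducible_given_seed(self):
        a = simulate_toy_binder(ToyBinderSpec(seed=9), 200)
        b = simulate_toy_binder(ToyBinderSpec(seed=9), 200)
        np.testing.assert_array_equal(a.values, b.values)
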