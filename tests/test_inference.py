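import numpy as np
import pytest

from pentrack import (EmissionTensor, MotionModel, PosteriorTensor, assign_identities,
                      backward_pass, forward_pass, forward_pass_expspace, log_sum_exp,
                      posterior_marginals, slot_distance, track_identities,
                      SimulationConfig, simulate, precision_recall)
from pentrack.inference import _log_transitions
from conftest import random_emissions, random_trackset, static_trackset
from oracles import brute_force_assignment, enumerate_posterior


class TestSlotDistance:
    def test_identical_poses_zero(self):
        pose = (np.array([3.0, 4.0]), np.array([5.0, 6.0]))
        assert slot_distance(pose, pose) == 0.0

    def test_pythagorean_combination(self):
        a = (np.array([0.0, 0]), np.array([0.0, 0]))
        b = (np.array([3.0, 0]), np.array([0.0, 4]))
        assert slot_distance(a, b) == pytest.approx(5.0)

    def test_symmetry(self, rng):
        a = (rng.uniform(0, 10, 2), rng.uniform(0, 10, 2))
        b = (rng.uniform(0, 10, 2), rng.uniform(0, 10, 2))
        assert slot_distance(a, b) == pytest.approx(slot_distance(b, a))


class TestLogSumExp:
    def test_single_element_identity(self):
        assert log_sum_exp([-3.7]) == pytest.approx(-3.7)

    def test_deep_underflow_region(self):
        assert log_sum_exp([-1000.0, -1000.0]) == pytest.approx(-1000.0 + np.log(2))

    def test_minus_infinity_absorbed(self):
        assert log_sum_exp([0.0, -np.inf]) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            log_sum_exp([])


class TestForwardBackward:
    def test_single_frame_alpha_is_emission(self, rng):
        tracks = random_trackset(rng, 1, 3)
        em = EmissionTensor(random_emissions(rng, 1, 3, 3))
        la = forward_pass(em, tracks, MotionModel.default(), 1)
        np.testing.assert_allclose(la[0], em.log_e[0, :, 1])

    def test_terminal_beta_is_zero(self, rng):
        tracks = random_trackset(rng, 4, 3)
        em = EmissionTensor(random_emissions(rng, 4, 3, 3))
        lb = backward_pass(em, tracks, MotionModel.default(), 0)
        np.testing.assert_allclose(lb[-1], 0.0)

    def test_two_frame_recursion_matches_exp_space(self, rng):
        """T=2 hand recursion in linear domain (extended precision)."""
        model = MotionModel.default()
        tracks = random_trackset(rng, 2, 2)
        em = EmissionTensor(random_emissions(rng, 2, 2, 2))
        lt = _log_transitions(tracks, model)
        for n in (0, 1):
            e = np.exp(np.longdouble(em.log_e[:, :, n]))
            trans = np.exp(np.longdouble(lt[0]))
            alpha1 = e[1] * (trans @ e[0])
            la = forward_pass(em, tracks, model, n)
            np.testing.assert_allclose(np.exp(la[1]), alpha1.astype(float), rtol=1e-12)
            beta0 = trans.T @ (e[1] * np.ones(2))
            lb = backward_pass(em, tracks, model, n)
            np.testing.assert_allclose(np.exp(lb[0]), beta0.astype(float), rtol=1e-12)

    def test_alpha_beta_product_constant_over_time(self, rng):
        tracks = random_trackset(rng, 6, 3)
        em = EmissionTensor(random_emissions(rng, 6, 3, 3))
        model = MotionModel.default()
        for n in range(3):
            la = forward_pass(em, tracks, model, n)
            lb = backward_pass(em, tracks, model, n)
            totals = [log_sum_exp(la[t] + lb[t]) for t in range(6)]
            np.testing.assert_allclose(totals, totals[0], rtol=1e-10)

    @pytest.mark.parametrize("n_frames,n_slots", [(2, 2), (3, 3), (5, 2), (4, 3)])
    def test_marginals_match_path_enumeration(self, rng, n_frames, n_slots):
        model = MotionModel.default()
        tracks = random_trackset(rng, n_frames, n_slots)
        em = EmissionTensor(random_emissions(rng, n_frames, n_slots, n_slots))
        post = posterior_marginals(em, tracks, model)
        lt = _log_transitions(tracks, model)
        for n in range(n_slots):
            expect = enumerate_posterior(em.log_e[:, :, n], lt)
            got = post.log_post[:, :, n]
            got = got - log_sum_exp_rows(got)
            np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_uniform_emissions_make_identities_indistinguishable(self, rng):
        tracks = random_trackset(rng, 5, 3)
        em = EmissionTensor(np.full((5, 3, 3), np.log(1 / 3)))
        post = posterior_marginals(em, tracks)
        for n in (1, 2):
            np.testing.assert_allclose(post.log_post[:, :, n], post.log_post[:, :, 0])

    def test_single_sighting_propagates_through_static_scene(self):
        positions = [[0, 0], [0, 100], [0, 200]]
        tracks = static_trackset(positions, 9)
        log_e = np.full((9, 3, 3), np.log(1 / 3))
        row = np.full(3, 1e-6)
        row[1] = 1 - 2e-6  # identity 1 sighted in slot 2 at t=4
        log_e[4, 2] = np.log(row / row.sum())
        log_e[4, [0, 1]] = np.log(np.array([(1 - row) / (1 - row).sum()] * 2))
        post = posterior_marginals(EmissionTensor(log_e), tracks)
        assert (np.argmax(post.log_post[:, :, 1], axis=1) == 2).all()

    def test_stay_put_dominance_follows_nearest_chain(self):
        positions = [[0, 0], [0, 50], [0, 100]]
        tracks = static_trackset(positions, 6)
        log_e = np.full((6, 3, 3), np.log(1 / 3))
        hot = np.full(3, 1e-6)
        hot[0] = 1 - 2e-6
        log_e[0, 1] = np.log(hot / hot.sum())  # identity 0 seeded in slot 1
        post = posterior_marginals(EmissionTensor(log_e), tracks)
        assert (np.argmax(post.log_post[:, :, 0], axis=1) == 1).all()


def log_sum_exp_rows(a):
    from scipy.special import logsumexp
    return logsumexp(a, axis=1, keepdims=True)


class TestUnderflowRobustness:
    def test_log_space_finite_where_linear_reference_underflows(self):
        n_frames = 2000
        tracks = static_trackset([[0, 0], [0, 80], [0, 160]], n_frames)
        # slow drift so per-step probabilities are genuinely < 1
        drift = 0.5 * np.arange(n_frames)[:, None, None] * np.array([1.0, 0.0])
        tracks.shoulders = tracks.shoulders + drift
        tracks.tails = tracks.tails + drift
        probs = np.full((n_frames, 3, 3), 1e-6)
        probs[:, 0, 0] = probs[:, 1, 1] = probs[:, 2, 2] = 1 - 2e-6
        probs /= probs.sum(axis=2, keepdims=True)
        em = EmissionTensor(np.log(probs))
        model = MotionModel.default()
        post = posterior_marginals(em, tracks, model)
        assert np.isfinite(post.log_alpha).all() and np.isfinite(post.log_beta).all()
        alpha_linear = forward_pass_expspace(em, tracks, model, 0)
        assert (alpha_linear[-1] == 0.0).all()  # textbook recursion dies


class TestAssignIdentities:
    def _post(self, cost):
        return PosteriorTensor(-np.asarray(cost, float)[None, :, :],
                               np.zeros((1, *np.shape(cost))), np.zeros((1, *np.shape(cost))))

    def test_obvious_minimum(self):
        ids = assign_identities(self._post([[1.0, 2.0], [2.0, 1.0]]))
        assert ids.slot_to_identity.tolist() == [[0, 1]]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_permutation_brute_force(self, rng, n):
        cost = rng.uniform(0, 10, size=(n, n))
        ids = assign_identities(self._post(cost))
        total = cost[np.arange(n), ids.slot_to_identity[0]].sum()
        _, best = brute_force_assignment(cost)
        assert total == pytest.approx(best, abs=1e-12)

    def test_symmetric_posterior_breaks_ties_to_identity_map(self):
        ids = assign_identities(self._post(np.ones((4, 4))))
        assert ids.slot_to_identity.tolist() == [[0, 1, 2, 3]]


class TestTrackIdentities:
    def test_location_scenario_returns_slot_indices(self):
        gt, det = simulate(SimulationConfig(n=3, t=20, seed=5))
        tracks, ids = track_identities(det, 3, scenario="location")
        assert (ids.slot_to_identity == np.arange(3)).all()

    def test_initialized_requires_annotations(self):
        _, det = simulate(SimulationConfig(n=3, t=5, seed=5))
        with pytest.raises(Exception, match="initialized"):
            track_identities(det, 3, scenario="initialized")

    def test_initialized_recovers_identities_without_tags(self):
        gt, det = simulate(SimulationConfig(
            n=4, t=60, seed=9, dropout_prob=0.0, fp_rate=0.0, assoc_noise_sd=0.0,
            reversal_prob=0.0, ear_visibility_prob=0.0))
        tracks, ids = track_identities(det, 4, scenario="initialized", init=gt[0])
        res = precision_recall(gt, (tracks, ids), "location_id")
        assert res.precision == 1.0

    def test_uninitialized_without_tags_is_temporally_consistent(self):
        gt, det = simulate(SimulationConfig(
            n=4, t=40, seed=9, dropout_prob=0.0, fp_rate=0.0, assoc_noise_sd=0.0,
            reversal_prob=0.0, ear_visibility_prob=0.0))
        tracks, ids = track_identities(det, 4, scenario="uninitialized")
        # labels are arbitrary but must not swap in a well-separated scene
        assert (ids.slot_to_identity == ids.slot_to_identity[0]).all()
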