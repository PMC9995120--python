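"""Featurization, tICA, clustering, VAMP-2 validation and MSM estimation."""

import numpy as np
import pytest

from pocketensemble.kinetics import (
    ClusterModel,
    DiscreteTrajectories,
    TICA,
    cluster_assign,
    count_matrix,
    dihedral_features,
    fit_msm,
    fit_tica,
    frame_weights,
    implied_timescales,
    validate_msm,
    vamp2_score,
)
from pocketensemble.structure_io import Trajectory


def simulate_chain(T, n_steps, seed, pi0=None):
    """Direct simulation of a discrete Markov chain (independent oracle helper)."""
    T = np.asarray(T, float)
    rng = np.random.default_rng(seed)
    k = T.shape[0]
    cdf = np.cumsum(T, axis=1)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(k, p=pi0) if pi0 is not None else rng.integers(k)
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t])
    return states


class TestDihedralFeatures:
    def test_feature_count_matches_hand_enumeration(self, tripeptide):
        # ALA-SER-GLY: phi x2 (res 2,3), psi x2 (res 1,2), chi1 x1 (SER) -> 5
        # dihedrals -> 10 sin/cos columns
        traj = Trajectory(tripeptide, tripeptide.coords[None], 20.0)
        fm = dihedral_features(traj, tripeptide.residue_ids())
        assert fm.n_features == 10
        angles = {lbl.split(":")[2] for lbl in fm.labels}
        assert angles == {"phi", "psi", "chi1"}

    def test_glycine_contributes_backbone_only(self, tripeptide):
        traj = Trajectory(tripeptide, tripeptide.coords[None], 20.0)
        fm = dihedral_features(traj, [("A", 3)])
        assert all(lbl.split(":")[2] in ("phi", "psi") for lbl in fm.labels)
        # terminal GLY: phi only (psi needs a following residue), no chi
        assert fm.n_features == 2

    def test_sincos_on_unit_circle(self, tripeptide, rng):
        frames = tripeptide.coords[None] + rng.normal(scale=0.05, size=(4, 15, 3))
        traj = Trajectory(tripeptide, frames, 20.0)
        fm = dihedral_features(traj, tripeptide.residue_ids())
        x = fm.trajectories[0]
        np.testing.assert_allclose(x[:, 0::2] ** 2 + x[:, 1::2] ** 2, 1.0,
                                   atol=1e-9)

    def test_unresolvable_residue_raises(self, tripeptide):
        traj = Trajectory(tripeptide, tripeptide.coords[None], 20.0)
        with pytest.raises(ValueError, match="resolvable"):
            dihedral_features(traj, [("A", 99)])


class TestTICA:
    def test_white_noise_has_no_autocorrelation(self, rng):
        x = rng.normal(size=(10_000, 6))
        model = fit_tica_features(x, lag=10)
        assert np.all(np.abs(model.eigenvalues_) < 0.1)

    def test_recovers_slow_coordinate(self, rng):
        states = simulate_chain([[0.99, 0.01], [0.01, 0.99]], 20_000, seed=5)
        slow = states * 2.0 - 1.0
        x = np.column_stack([slow + 0.1 * rng.normal(size=slow.size)]
                            + [rng.normal(size=slow.size) for _ in range(10)])
        model = fit_tica_features(x, lag=10)
        proj = model.transform(x)
        corr = np.corrcoef(proj[:, 0], slow)[0, 1]
        assert abs(corr) > 0.9

    def test_duplicated_column_is_regularized(self, rng):
        x = rng.normal(size=(2000, 3))
        x = np.column_stack([x, x[:, 0]])
        model = fit_tica_features(x, lag=5)
        assert np.all(np.isfinite(model.eigenvalues_))
        assert np.all(np.isfinite(model.transform(x)))

    def test_invariant_under_feature_rotation(self, rng):
        states = simulate_chain([[0.98, 0.02], [0.02, 0.98]], 5_000, seed=9)
        x = np.column_stack([states + 0.05 * rng.normal(size=states.size),
                             rng.normal(size=states.size),
                             rng.normal(size=states.size)])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = fit_tica_features(x, lag=5)
        b = fit_tica_features(x @ q.T, lag=5)
        pa = a.transform(x)[:, 0]
        pb = b.transform(x @ q.T)[:, 0]
        assert abs(np.corrcoef(pa, pb)[0, 1]) > 1 - 1e-6

    def test_lag_longer_than_data_raises(self, rng):
        with pytest.raises(ValueError, match="lag"):
            fit_tica_features(rng.normal(size=(10, 2)), lag=10)

    def test_sklearn_params_roundtrip(self):
        model = TICA(lag=7, var_cutoff=0.8)
        assert model.get_params()["lag"] == 7
        model.set_params(lag=3)
        assert model.lag == 3


def fit_tica_features(x, lag):
    return TICA(lag=lag).fit([x])


class TestClustering:
    def test_k1_single_state(self, rng):
        _, dtrajs = cluster_assign([rng.normal(size=(50, 2))], k=1, seed=0)
        assert np.all(dtrajs.dtrajs[0] == 0)

    def test_separated_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = np.array([[0.0, 0], [20, 0], [0, 20]])
        labels = rng.integers(3, size=600)
        x = centers[labels] + rng.normal(scale=0.5, size=(600, 2))
        model, dtrajs = cluster_assign([x], k=3, seed=0)
        assert adjusted_rand_score(labels, dtrajs.dtrajs[0]) == 1.0
        assert model.k == 3

    def test_heldout_assignment_and_tiebreak(self):
        model = ClusterModel(np.array([[0.0], [2.0]]))
        assert model.assign(np.array([[1.0]]))[0] == 0  # equidistant -> lowest index
        assert model.assign(np.array([[1.9]]))[0] == 1

    def test_fit_subset_assigns_heldout(self, rng):
        xs = [rng.normal(size=(100, 2)), rng.normal(size=(80, 2)) + 10]
        _, dtrajs = cluster_assign(xs, k=2, seed=0, fit_subset=[0])
        assert dtrajs.dtrajs[1].shape == (80,)

    def test_k_exceeds_frames(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_assign([rng.normal(size=(5, 2))], k=10, seed=0)


class TestVAMP2:
    def test_frozen_chain_scores_k(self):
        # identity transition matrix: k self-looping states, all singular values 1
        for k in (3, 12):
            dtrajs = DiscreteTrajectories(
                [np.full(50, s) for s in range(k)], n_states=k
            )
            assert vamp2_score(dtrajs, lag=1) == pytest.approx(min(10, k), abs=1e-9)

    def test_iid_jumps_score_one(self, rng):
        d = rng.integers(4, size=200_000)
        dtrajs = DiscreteTrajectories([d], n_states=4)
        assert vamp2_score(dtrajs, lag=1) == pytest.approx(1.0, abs=0.01)

    def test_too_few_states(self):
        with pytest.raises(ValueError):
            vamp2_score(DiscreteTrajectories([np.zeros(10, int)], 1), lag=1)


class TestMSM:
    T2 = np.array([[0.95, 0.05], [0.10, 0.90]])

    def test_constant_trajectory(self):
        dtrajs = DiscreteTrajectories([np.zeros(20, int)], n_states=1)
        msm = fit_msm(dtrajs, lag=1)
        np.testing.assert_allclose(msm.transition_matrix_, [[1.0]])
        np.testing.assert_allclose(msm.stationary_distribution_, [1.0])

    def test_two_state_chain_recovery(self):
        states = simulate_chain(self.T2, 100_000, seed=42)
        dtrajs = DiscreteTrajectories([states], n_states=2)
        msm = fit_msm(dtrajs, lag=1)
        np.testing.assert_allclose(msm.transition_matrix_, self.T2, atol=0.02)
        # closed-form stationary distribution of T2 is (2/3, 1/3)
        np.testing.assert_allclose(msm.stationary_distribution_, [2 / 3, 1 / 3],
                                   atol=0.02)

    def test_detailed_balance_and_row_sums(self):
        states = simulate_chain(self.T2, 20_000, seed=3)
        dtrajs = DiscreteTrajectories([states], n_states=2)
        msm = fit_msm(dtrajs, lag=2)
        t, pi = msm.transition_matrix_, msm.stationary_distribution_
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pi.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(pi @ t, pi, atol=1e-8)
        np.testing.assert_allclose(pi[:, None] * t, (pi[:, None] * t).T, atol=1e-8)

    def test_disconnected_state_excluded(self):
        dtrajs = DiscreteTrajectories(
            [np.array([0, 1] * 30), np.full(30, 2)], n_states=3
        )
        msm = fit_msm(dtrajs, lag=1)
        assert set(msm.active_set_.tolist()) == {0, 1}
        assert msm.index_map_[2] == -1

    def test_pseudocount_rownorm_matches_arithmetic(self):
        dtrajs = DiscreteTrajectories([np.array([0, 0, 1, 0, 1, 1, 0])], n_states=2)
        msm = fit_msm(dtrajs, lag=1, estimator="pseudocount_rownorm")
        c = count_matrix(dtrajs, 1)
        expected = (c + 0.5) / (c + 0.5).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(msm.transition_matrix_, expected, atol=1e-12)
        pi = msm.stationary_distribution_
        np.testing.assert_allclose(pi @ msm.transition_matrix_, pi, atol=1e-10)

    def test_no_transitions_raises(self):
        dtrajs = DiscreteTrajectories([np.array([0])], n_states=1)
        with pytest.raises(ValueError):
            fit_msm(dtrajs, lag=1)


class TestFrameWeights:
    def test_uniform_two_state(self):
        dtrajs = DiscreteTrajectories([np.array([0, 1] * 5)], n_states=2)
        msm = fit_msm(dtrajs, lag=1)
        fw = frame_weights(msm, dtrajs)
        np.testing.assert_allclose(fw.weights[0], 0.1, atol=1e-6)

    def test_single_state_gives_one_over_F(self):
        dtrajs = DiscreteTrajectories([np.zeros(25, int)], n_states=1)
        msm = fit_msm(dtrajs, lag=1)
        fw = frame_weights(msm, dtrajs)
        np.testing.assert_allclose(fw.weights[0], 1 / 25)

    def test_skewed_pi_arithmetic(self):
        # pi = (0.9, 0.1), N = (9, 1): every frame weighs 0.1; per-state sums 0.9/0.1
        from pocketensemble.kinetics import MarkovStateModel

        dtrajs = DiscreteTrajectories([np.array([0] * 9 + [1])], n_states=2)
        msm = MarkovStateModel(lag=1)
        msm.active_set_ = np.array([0, 1])
        msm.index_map_ = np.array([0, 1])
        msm.stationary_distribution_ = np.array([0.9, 0.1])
        msm.transition_matrix_ = np.array([[0.99, 0.01], [0.09, 0.91]])
        msm.n_states_full_ = 2
        fw = frame_weights(msm, dtrajs)
        np.testing.assert_allclose(fw.weights[0], 0.1, atol=1e-12)
        assert fw.total == pytest.approx(1.0, abs=1e-12)

    def test_total_one_and_relabel_invariance(self):
        states = simulate_chain([[0.9, 0.1], [0.2, 0.8]], 5000, seed=1)
        dtrajs = DiscreteTrajectories([states], n_states=2)
        msm = fit_msm(dtrajs, lag=1)
        fw = frame_weights(msm, dtrajs)
        assert fw.total == pytest.approx(1.0, abs=1e-12)
        swapped = DiscreteTrajectories([1 - states], n_states=2)
        fw2 = frame_weights(fit_msm(swapped, lag=1), swapped)
        np.testing.assert_allclose(np.sort(fw.weights[0]),
                                   np.sort(fw2.weights[0]), atol=1e-12)


class TestValidationAndTimescales:
    def test_implied_timescales_lag_independent_for_markov_chain(self):
        T = np.array([[0.98, 0.02], [0.04, 0.96]])
        states = simulate_chain(T, 200_000, seed=11)
        dtrajs = DiscreteTrajectories([states], n_states=2)
        its = implied_timescales(dtrajs, lags=[1, 2, 5, 10], n_its=1)[:, 0]
        # exact value: -1/ln(lambda_2), lambda_2 = 1 - 0.02 - 0.04
        exact = -1.0 / np.log(1 - 0.06)
        np.testing.assert_allclose(its, exact, rtol=0.15)

    def test_validate_msm_selects_resolving_k(self, rng):
        centers = np.array([[0.0, 0], [15, 0], [0, 15]])
        xs = []
        for seed in range(4):
            states = simulate_chain(
                [[0.95, 0.03, 0.02], [0.05, 0.93, 0.02], [0.05, 0.03, 0.92]],
                3000, seed=seed)
            xs.append(centers[states] + rng.normal(scale=0.5, size=(3000, 2)))
        report = validate_msm(xs, k_grid=[2, 3], msm_lag=1, n_splits=2, seed=0)
        assert set(report.scores_mean) == {2, 3}
        assert all(s <= 10 + 1e-9 for s in report.scores_mean.values())
        # 3 metastable states need at least 3 microstates to capture
        assert report.scores_mean[3] > report.scores_mean[2]
        assert report.chosen_k == 3

    def test_validate_needs_two_trajectories(self, rng):
        with pytest.raises(ValueError):
            validate_msm([rng.normal(size=(100, 2))], k_grid=[2], msm_lag=1)
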