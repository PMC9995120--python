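"""State sampling, docking box, score ingestion, and free-energy aggregation."""

import numpy as np
import pytest

from pocketensemble.constants import R_KCAL_PER_MOL_K
from pocketensemble.kinetics import DiscreteTrajectories, MarkovStateModel
from pocketensemble.msm_dock import (
    DockingRecord,
    Kd_to_deltaG,
    StateSample,
    aggregate_binding_free_energy,
    define_docking_box,
    deltaG_to_Kd,
    ingest_docking_scores,
    sample_docking_structures,
)
from pocketensemble.structure_io import AtomSelection, Trajectory
from tests.conftest import make_structure

RT310 = R_KCAL_PER_MOL_K * 310.0


def make_msm(pi, n_states=None):
    """Hand-assembled fitted MSM with a given stationary distribution."""
    pi = np.asarray(pi, float)
    n = n_states or pi.size
    msm = MarkovStateModel(lag=1)
    msm.active_set_ = np.flatnonzero(pi > 0)
    msm.stationary_distribution_ = pi[pi > 0]
    msm.transition_matrix_ = np.eye(msm.active_set_.size)
    msm.n_states_full_ = n
    msm.index_map_ = -np.ones(n, dtype=int)
    msm.index_map_[msm.active_set_] = np.arange(msm.active_set_.size)
    return msm


def dtrajs_with_occupancy(counts):
    """One trajectory visiting state s `counts[s]` times."""
    seq = np.concatenate([np.full(c, s) for s, c in enumerate(counts)])
    return DiscreteTrajectories([seq], n_states=len(counts))


class TestSampling:
    def test_rule_max_of_base_and_pi_scale(self):
        # pi*2000 below 3 -> base of 3; pi = 0.01 -> 20
        dtrajs = dtrajs_with_occupancy([1000, 1000])
        msm = make_msm([0.001, 0.999])
        samples = {s.state: s for s in
                   sample_docking_structures(msm, dtrajs, base=3, scale=2000, seed=0)}
        assert samples[0].n == 3
        msm2 = make_msm([0.01, 0.99])
        samples2 = {s.state: s for s in
                    sample_docking_structures(msm2, dtrajs, seed=0)}
        assert samples2[0].n == 20

    def test_capped_at_available_frames_with_warning(self):
        dtrajs = dtrajs_with_occupancy([2, 100])
        msm = make_msm([0.5, 0.5])
        with pytest.warns(UserWarning, match="taking all"):
            samples = {s.state: s for s in
                       sample_docking_structures(msm, dtrajs, seed=0)}
        assert samples[0].n == 2

    def test_frames_unique_and_belong_to_state(self):
        dtrajs = dtrajs_with_occupancy([50, 50])
        msm = make_msm([0.4, 0.6])
        for s in sample_docking_structures(msm, dtrajs, seed=5):
            assert len(set(s.frames)) == len(s.frames)
            for t, f in s.frames:
                assert dtrajs.dtrajs[t][f] == s.state


class TestDockingBox:
    def _traj(self, frames):
        top = make_structure(
            [("CA", "C", i + 1, "ALA", "A", 0, 0, 0) for i in range(frames.shape[1])]
        )
        return Trajectory(top, frames, 1.0)

    def test_single_frame_centroid(self, rng):
        frames = rng.normal(size=(1, 5, 3))
        box = define_docking_box(self._traj(frames), AtomSelection(np.arange(5)),
                                 edge=20.0)
        np.testing.assert_allclose(box.center, frames[0].mean(axis=0))

    def test_two_frame_arithmetic(self):
        # selection centroids (0,0,0) and (2,0,0), no rotation -> center (1,0,0)
        f0 = np.array([[0.0, 0, 0], [1, 1, 0], [-1, -1, 0]])
        f0 -= f0.mean(axis=0)
        frames = np.stack([f0, f0 + np.array([2.0, 0, 0])])
        box = define_docking_box(self._traj(frames), AtomSelection(np.arange(3)))
        np.testing.assert_allclose(box.center, [1.0, 0, 0], atol=1e-12)

    def test_rigid_translation_removed_by_alignment(self, rng):
        from pocketensemble.superposition import iterative_ensemble_align

        base = rng.normal(size=(6, 3))
        frames = np.stack([base + rng.normal(size=3) * 10 for _ in range(4)])
        sel = AtomSelection(np.arange(6))
        traj = self._traj(frames)
        aligned, _ = iterative_ensemble_align(traj, sel)
        box1 = define_docking_box(aligned, sel)
        shifted, _ = iterative_ensemble_align(
            self._traj(frames + np.array([50.0, 0, 0])), sel)
        box2 = define_docking_box(shifted, sel)
        np.testing.assert_allclose(box1.center, box2.center, atol=1e-6)

    def test_box_text_export(self):
        from pocketensemble.msm_dock import DockingBox

        box = DockingBox(np.array([1.0, 2.0, 3.0]), np.array([22.5, 22.5, 22.5]))
        text = box.to_text()
        assert "center_x = 1.0" in text and "size_z = 22.5" in text


class TestIngest:
    def test_best_pose_per_frame(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("traj_id,frame,score_kcal_mol\n0,0,-5.1\n0,0,-4.2\n0,0,-3.0\n")
        dtrajs = dtrajs_with_occupancy([5])
        recs = ingest_docking_scores(p, dtrajs)
        assert len(recs) == 1
        assert recs[0].score == -5.1

    def test_inactive_frame_dropped_with_warning(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("traj_id,frame,score_kcal_mol\n0,0,-5.0\n0,6,-4.0\n")
        dtrajs = dtrajs_with_occupancy([6, 4])  # frame 6 is in state 1
        msm = make_msm([1.0, 0.0], n_states=2)
        with pytest.warns(UserWarning, match="active set"):
            recs = ingest_docking_scores(p, dtrajs, msm)
        assert len(recs) == 1

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("traj_id,frame,score_kcal_mol\n")
        with pytest.raises(ValueError, match="no docking records"):
            ingest_docking_scores(p, dtrajs_with_occupancy([5]))

    def test_unknown_frame_raises(self, tmp_path):
        p = tmp_path / "scores.csv"
        p.write_text("traj_id,frame,score_kcal_mol\n0,99,-5.0\n")
        with pytest.raises(KeyError):
            ingest_docking_scores(p, dtrajs_with_occupancy([5]))


class TestAggregation:
    def test_degenerate_equal_scores_exact(self):
        msm = make_msm([0.3, 0.7])
        records = [DockingRecord(0, 0, 0, -6.2), DockingRecord(0, 1, 1, -6.2)]
        est = aggregate_binding_free_energy(records, msm, temperature=310.0)
        assert est.dG_total == pytest.approx(-6.2, abs=1e-12)

    def test_two_state_worked_example(self):
        # pi = (0.9, 0.1), scores (-2, -8), T = 310 K; direct-arithmetic oracle
        msm = make_msm([0.9, 0.1])
        records = [DockingRecord(0, 0, 0, -2.0), DockingRecord(0, 1, 1, -8.0)]
        est = aggregate_binding_free_energy(records, msm, temperature=310.0)
        oracle = -RT310 * np.log(0.9 * np.exp(2.0 / RT310) + 0.1 * np.exp(8.0 / RT310))
        assert est.dG_total == pytest.approx(oracle, abs=1e-10)
        assert oracle == pytest.approx(-6.58, abs=0.01)

    def test_single_structure_per_state_reduces_to_state_formula(self, rng):
        pi = rng.dirichlet(np.ones(4))
        scores = rng.uniform(-9, -2, size=4)
        msm = make_msm(pi)
        records = [DockingRecord(0, s, s, scores[s]) for s in range(4)]
        est = aggregate_binding_free_energy(records, msm, temperature=310.0)
        direct = -RT310 * np.log(np.sum(pi * np.exp(-scores / RT310)))
        assert est.dG_total == pytest.approx(direct, abs=1e-10)

    def test_invariant_under_record_duplication(self):
        msm = make_msm([0.6, 0.4])
        records = [DockingRecord(0, 0, 0, -5.0), DockingRecord(0, 1, 1, -7.0)]
        once = aggregate_binding_free_energy(records, msm, temperature=310.0)
        doubled = records + [DockingRecord(1, 0, 0, -5.0), DockingRecord(1, 1, 1, -7.0)]
        twice = aggregate_binding_free_energy(doubled, msm, temperature=310.0)
        assert twice.dG_total == pytest.approx(once.dG_total, abs=1e-10)

    def test_soft_min_bounds_and_monotonicity(self, rng):
        # random instances: min score <= dG <= score_f + RT ln(1/w_f); making a
        # score more negative never raises dG
        for _ in range(200):
            k = rng.integers(2, 6)
            pi = rng.dirichlet(np.ones(k))
            n_rec = rng.integers(k, 3 * k)
            states = np.concatenate([np.arange(k), rng.integers(k, size=n_rec - k)])
            scores = rng.uniform(-10, 0, size=n_rec)
            msm = make_msm(pi)
            records = [DockingRecord(0, i, int(states[i]), float(scores[i]))
                       for i in range(n_rec)]
            est = aggregate_binding_free_energy(records, msm, temperature=310.0)
            counts = np.bincount(states, minlength=k)
            assert est.dG_total >= scores.min() - 1e-9
            for r in records:
                w = pi[r.state] / counts[r.state]
                assert est.dG_total <= r.score + RT310 * np.log(1.0 / w) + 1e-9
            j = rng.integers(n_rec)
            better = [DockingRecord(r.traj, r.frame, r.state,
                                    r.score - (1.0 if i == j else 0.0))
                      for i, r in enumerate(records)]
            est2 = aggregate_binding_free_energy(better, msm, temperature=310.0)
            assert est2.dG_total <= est.dG_total + 1e-12

    def test_sample_counts_used_when_given(self):
        msm = make_msm([0.5, 0.5])
        samples = [StateSample(0, 2, [(0, 0), (0, 1)], 0),
                   StateSample(1, 1, [(0, 2)], 0)]
        # only one of the two sampled structures of state 0 was docked:
        # its weight must still be pi_0 / 2
        records = [DockingRecord(0, 0, 0, -5.0), DockingRecord(0, 2, 1, -5.0)]
        est = aggregate_binding_free_energy(records, msm, samples, temperature=310.0)
        expected = -RT310 * np.log((0.5 / 2 + 0.5) * np.exp(5.0 / RT310))
        assert est.dG_total == pytest.approx(expected, abs=1e-10)


class TestUnitConversion:
    def test_zero_dG_is_one_molar(self):
        assert deltaG_to_Kd(0.0, 310.0) == pytest.approx(1.0)

    def test_printed_prediction_consistency(self):
        # dG = -8.8 kcal/mol at 310 K lands in the sub-micromolar window
        kd = deltaG_to_Kd(-8.8, 310.0)
        assert 0.57e-6 <= kd <= 0.68e-6

    def test_round_trip_identity(self, rng):
        for dg in rng.uniform(-12, 0, size=20):
            assert Kd_to_deltaG(deltaG_to_Kd(dg, 310.0), 310.0) == pytest.approx(
                dg, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            deltaG_to_Kd(np.inf)
        with pytest.raises(ValueError):
            Kd_to_deltaG(-1.0)
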