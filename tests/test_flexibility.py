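import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ssdesign import flexibility as flex
from ssdesign import synthetic_data as syn
from ssdesign.flexibility import (
    RmsdSeries,
    bfactor_profile,
    compare_rigidity,
    gnm_fluctuations,
    kabsch_superpose,
    rank_candidates,
    rmsd_mode,
    rmsd_series,
)
from ssdesign.ssbond_design import CandidatePair


def _random_points(rng, n=10):
    return rng.normal(size=(n, 3)) * 3.0


class TestKabsch:
    def test_self_superposition_is_identity(self, helix30):
        res = kabsch_superpose(helix30.ca_coords(), helix30.ca_coords())
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_superposes_exactly(self, helix30):
        A = helix30.ca_coords()
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        B = A @ R90.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(A, B)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.apply(B), A, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_quaternion_solver(self, seed):
        rng = np.random.default_rng(seed)
        A, B = _random_points(rng), _random_points(rng)
        ours = kabsch_superpose(A, B)
        a0 = A - A.mean(axis=0)
        b0 = B - B.mean(axis=0)
        _, rssd = Rotation.align_vectors(a0, b0)
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(A)), abs=1e-9)
        # and no sampled rotation does better
        sampled = Rotation.random(500, random_state=rng)
        best = min(np.sqrt(((b0 @ M.T - a0) ** 2).sum() / len(A))
                   for M in sampled.as_matrix())
        assert ours.rmsd <= best + 1e-12

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            res = kabsch_superpose(_random_points(rng), _random_points(rng))
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)

    def test_rmsd_is_symmetric(self):
        rng = np.random.default_rng(7)
        A, B = _random_points(rng), _random_points(rng)
        assert kabsch_superpose(A, B).rmsd == pytest.approx(
            kabsch_superpose(B, A).rmsd, abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(line[:2], line[:2])


class TestRmsdSeries:
    def test_identical_frames_are_all_zero(self, helix30):
        traj = syn.make_trajectory(helix30, syn.TrajectorySpec(frames=5, jitter_sigma=0.0))
        series = rmsd_series(traj)
        assert np.allclose(series.values, 0.0)
        assert series.values[series.reference_frame] == 0.0

    def test_rigid_motion_only_gives_zero(self, helix30):
        traj = syn.make_trajectory(helix30, syn.TrajectorySpec(
            frames=20, jitter_sigma=0.0, rigid_motion=True, seed=3))
        assert np.allclose(rmsd_series(traj).values, 0.0, atol=1e-9)

    def test_gaussian_jitter_matches_monte_carlo_oracle(self, helix30):
        sigma = 0.3
        traj = syn.make_trajectory(helix30, syn.TrajectorySpec(
            frames=200, jitter_sigma=sigma, seed=7))
        empirical = rmsd_series(traj).values[1:].mean()
        # independent oracle: fresh Gaussian perturbations + quaternion solver
        rng = np.random.default_rng(1234)
        ref = helix30.ca_coords()
        n = ref.shape[0]
        mc = []
        for _ in range(400):
            pert = ref + rng.normal(0.0, sigma, ref.shape)
            _, rssd = Rotation.align_vectors(ref - ref.mean(0), pert - pert.mean(0))
            mc.append(rssd / np.sqrt(n))
        assert empirical == pytest.approx(np.mean(mc), rel=0.05)

    def test_equilibration_detected_after_decaying_drift(self, helix30):
        traj = syn.make_trajectory(helix30, syn.TrajectorySpec(
            frames=100, jitter_sigma=0.1, drift_amplitude=3.0, drift_tau=10.0, seed=2))
        series = rmsd_series(traj)
        assert series.equilibration_start > 0
        # post-equilibration values sit near the jitter plateau, not the drift peak
        assert series.post_equilibration.mean() < 0.5 * series.values[1]

    def test_missing_selection_is_an_error(self, helix30):
        traj = syn.make_trajectory(helix30, syn.TrajectorySpec(frames=3))
        with pytest.raises(ValueError, match="selection"):
            rmsd_series(traj, selection="ZZ")


class TestRmsdMode:
    def test_constant_series_maps_to_bin_center(self):
        series = RmsdSeries(times=np.arange(50.0), values=np.full(50, 0.47))
        assert rmsd_mode(series).mode_center == pytest.approx(0.475)

    def test_gaussian_sample_recovers_its_center(self):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(0.825, 0.02, 500))
        summary = rmsd_mode(RmsdSeries(times=np.arange(500.0), values=values))
        assert summary.mode_center == pytest.approx(0.825)

    def test_bimodal_sample_picks_the_heavier_component(self):
        values = np.concatenate([np.full(60, 0.52), np.full(40, 0.82)])
        summary = rmsd_mode(RmsdSeries(times=np.arange(100.0), values=values))
        assert summary.mode_center == pytest.approx(0.525)

    def test_counts_conserve_frames_and_centers_align(self):
        rng = np.random.default_rng(9)
        values = np.abs(rng.normal(0.6, 0.1, 321))
        summary = rmsd_mode(RmsdSeries(times=np.arange(321.0), values=values))
        assert summary.counts.sum() == 321
        k = round(summary.mode_center / summary.bin_width - 0.5)
        assert summary.mode_center == pytest.approx((k + 0.5) * summary.bin_width)

    def test_ties_flagged_and_lowest_center_wins(self):
        values = np.concatenate([np.full(10, 0.42), np.full(10, 0.77)])
        summary = rmsd_mode(RmsdSeries(times=np.arange(20.0), values=values))
        assert summary.tie
        assert summary.mode_center == pytest.approx(0.425)


class TestBfactorProfile:
    def test_planted_hot_region_contains_its_residues(self):
        s = syn.make_structure(syn.FixtureSpec(
            length=200, bfactor_base=20.0, bfactor_hot=[(120, 130, 60.0)]))
        profile = bfactor_profile(s)
        assert any(lo <= 126 <= hi for lo, hi in profile.hotspots)

    def test_single_spike_is_the_hotspot(self):
        s = syn.make_structure(syn.FixtureSpec(
            length=60, bfactor_base=15.0, bfactor_hot=[(30, 30, 80.0)]))
        profile = bfactor_profile(s)
        assert len(profile.hotspots) == 1
        lo, hi = profile.hotspots[0]
        assert lo <= 30 <= hi

    def test_window_one_equals_raw_means(self):
        s = syn.make_structure(syn.FixtureSpec(
            length=40, bfactor_base=20.0, bfactor_hot=[(10, 14, 50.0)],
            bfactor_noise=2.0, seed=4))
        profile = bfactor_profile(s, window=1)
        assert np.allclose(profile.smoothed, profile.raw)

    def test_uninformative_b_column_rejected(self, helix30):
        with pytest.raises(ValueError, match="uninformative|all equal"):
            bfactor_profile(helix30)  # flat default B everywhere


class TestGnm:
    def test_linear_chain_matches_path_graph_closed_form(self, helix30):
        # cutoff below the i,i+2 distance: only chain neighbours connect
        result = gnm_fluctuations(helix30, cutoff=4.0)
        n = len(helix30)
        # resistance-distance closed form for the path-graph Laplacian pseudoinverse
        R = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        expected = R.mean(axis=1) - R[np.triu_indices(n, 1)].sum() / n ** 2
        assert np.allclose(result.fluctuations, expected, atol=1e-8)
        assert result.total == pytest.approx(expected.sum())

    def test_extra_contact_strictly_decreases_total(self, helix30):
        base = gnm_fluctuations(helix30, cutoff=7.3)
        bridged = gnm_fluctuations(helix30, cutoff=7.3, extra_contacts=[(0, 29)])
        assert bridged.total < base.total

    def test_already_contacting_pair_changes_nothing(self, helix30):
        base = gnm_fluctuations(helix30, cutoff=7.3)
        same = gnm_fluctuations(helix30, cutoff=7.3, extra_contacts=[(0, 2)])
        assert same.total == pytest.approx(base.total)

    def test_deterministic_across_calls(self, dumbbell40):
        a = gnm_fluctuations(dumbbell40)
        b = gnm_fluctuations(dumbbell40)
        assert np.array_equal(a.fluctuations, b.fluctuations)

    def test_disconnected_network_is_an_error(self, helix30):
        with pytest.raises(ValueError, match="disconnected"):
            gnm_fluctuations(helix30, cutoff=2.0)


class TestCompareRigidity:
    def test_delta_never_positive(self, dumbbell40):
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = int(rng.integers(1, 38))
            j = int(rng.integers(i + 2, 41))
            pair = CandidatePair.from_labels(f"A{i}", f"A{j}")
            assert compare_rigidity(dumbbell40, pair).delta <= 1e-9

    def test_contacting_pair_has_zero_delta(self, helix30):
        pair = CandidatePair.from_labels("A1", "A3")
        assert compare_rigidity(helix30, pair).delta == pytest.approx(0.0, abs=1e-9)

    def test_interdomain_bridge_outranks_intradomain(self):
        s = syn.make_structure(syn.FixtureSpec(motif="dumbbell", length=40))
        # brute force over all pairs: the best bridge must span the linker
        best = None
        for i in range(1, 39):
            for j in range(i + 2, 41):
                d = compare_rigidity(s, CandidatePair.from_labels(f"A{i}", f"A{j}"))
                if best is None or d.delta < best.delta:
                    best = d
        assert best.pair.res1.seqnum <= 16 and best.pair.res2.seqnum >= 25
        inter = compare_rigidity(s, CandidatePair.from_labels("A10", "A35"))
        intra = compare_rigidity(s, CandidatePair.from_labels("A5", "A12"))
        assert inter.delta < intra.delta

    def test_ranking_orders_by_fluctuation_drop(self, dumbbell40):
        pairs = [CandidatePair.from_labels("A10", "A35"),
                 CandidatePair.from_labels("A5", "A12"),
                 CandidatePair.from_labels("A3", "A38")]
        ranked = rank_candidates(dumbbell40, pairs)
        deltas = [r.delta for r in ranked]
        assert deltas == sorted(deltas)
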