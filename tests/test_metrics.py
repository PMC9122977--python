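import numpy as np
import pytest

import loopfold as lf
from loopfold.metrics import imj_orientation_free


def _rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta), 0],
                     [np.sin(theta), np.cos(theta), 0],
                     [0, 0, 1]])


class TestDistanceMap:
    def test_two_beads(self):
        dm = lf.distance_map(np.array([[0, 0, 0], [5, 0, 0]], float))
        np.testing.assert_allclose(dm.matrix, [[0, 5], [5, 0]])

    def test_matches_brute_force(self, saw_truths):
        beads = saw_truths[0].beads
        dm = lf.distance_map(beads).matrix
        n = len(beads)
        naive = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                naive[i, j] = np.linalg.norm(beads[i] - beads[j])
        np.testing.assert_allclose(dm, naive, atol=1e-9)

    def test_rigid_motion_invariant(self, saw_truths):
        beads = saw_truths[0].beads
        moved = beads @ _rot(1.1).T + np.array([10.0, -3.0, 8.0])
        np.testing.assert_allclose(
            lf.distance_map(moved).matrix, lf.distance_map(beads).matrix, atol=1e-8
        )


class TestAverageDistanceMap:
    def test_mean_of_copies_is_identity(self, saw_truths):
        dm = lf.distance_map(saw_truths[0])
        avg = lf.average_distance_map([dm, dm, dm])
        np.testing.assert_allclose(avg.matrix, dm.matrix)

    def test_elementwise_mean(self):
        a = np.array([[0, 2], [2, 0]], float)
        b = np.array([[0, 4], [4, 0]], float)
        avg = lf.average_distance_map([a, b])
        assert avg.matrix[0, 1] == pytest.approx(3.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lf.average_distance_map([np.zeros((3, 3)), np.zeros((4, 4))])

    def test_saw_ensemble_band_profile_monotone(self):
        """Mean distance grows with genomic separation in a random-coil ensemble."""
        models = lf.saw_ensemble(100, lf.SAWConfig(n_beads=80, seed=21))
        avg = lf.average_distance_map([lf.distance_map(m) for m in models]).matrix
        n = avg.shape[0]
        profile = np.array([np.mean(np.diagonal(avg, offset=s)) for s in range(1, n)])
        from scipy.stats import spearmanr

        rho, _ = spearmanr(np.arange(1, n), profile)
        assert rho > 0.99


class TestIMJ:
    def test_identical_maps_score_100(self, saw_truths):
        dm = lf.distance_map(saw_truths[0])
        for variant in ("contact", "weighted"):
            assert lf.imj(dm, dm, variant=variant) == pytest.approx(100.0)

    def test_hand_computed_weighted_example(self):
        # off-diagonal entries a=(2,4,6), b=(4,4,3):
        # 100 * (min sums) / (max sums) = 100 * 9 / 14 = 64.29
        a = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float)
        b = np.array([[0, 4, 4], [4, 0, 3], [4, 3, 0]], float)
        score = lf.imj(a, b, variant="weighted", normalize=False)
        assert score == pytest.approx(64.29, abs=0.01)

    def test_symmetry_and_range(self, saw_truths):
        maps = [lf.distance_map(m) for m in saw_truths]
        for variant in ("contact", "weighted"):
            s_ab = lf.imj(maps[0], maps[1], variant=variant)
            s_ba = lf.imj(maps[1], maps[0], variant=variant)
            assert s_ab == pytest.approx(s_ba)
            assert 0.0 <= s_ab <= 100.0

    def test_scale_invariance_with_normalization(self, saw_truths):
        a = lf.distance_map(saw_truths[0])
        b = lf.distance_map(saw_truths[1])
        b_scaled = lf.DistanceMap(b.matrix * 2.0)
        for variant in ("contact", "weighted"):
            assert lf.imj(a, b, variant=variant) == pytest.approx(
                lf.imj(a, b_scaled, variant=variant)
            )

    def test_degenerate_all_zero_maps(self):
        z = np.zeros((4, 4))
        nz = lf.distance_map(np.random.default_rng(0).random((4, 3))).matrix
        assert lf.imj(z, z) == 100.0
        assert lf.imj(z, nz) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lf.imj(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_orientation_free_handles_reversal(self, saw_truths):
        m = saw_truths[0]
        rev = lf.distance_map(m.beads[::-1])
        fwd = lf.distance_map(m)
        assert imj_orientation_free(rev, fwd) == pytest.approx(100.0)


class TestPairwiseIMJ:
    def test_two_copies_mean_100(self, saw_truths):
        sim, mean = lf.pairwise_imj([saw_truths[0], saw_truths[0]])
        assert mean == pytest.approx(100.0)
        np.testing.assert_allclose(np.diag(sim), 100.0)

    def test_three_models_mean_of_pairs(self, saw_truths):
        sim, mean = lf.pairwise_imj(saw_truths[:3])
        pairs = [sim[0, 1], sim[0, 2], sim[1, 2]]
        assert mean == pytest.approx(np.mean(pairs))
        np.testing.assert_allclose(sim, sim.T)

    def test_mismatched_bead_counts_rejected(self, saw_truths):
        small = lf.PolymerModel(saw_truths[0].beads[:50])
        with pytest.raises(ValueError):
            lf.pairwise_imj([saw_truths[0], small])


class TestKabsch:
    def test_self_alignment_rmsd_zero(self, saw_truths):
        _, rmsd = lf.kabsch_align(saw_truths[0], saw_truths[0])
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_rigid_motion(self, saw_truths):
        beads = saw_truths[0].beads
        moved = beads @ _rot(np.pi / 2).T + np.array([100.0, 50.0, -30.0])
        aligned, rmsd = lf.kabsch_align(beads, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(aligned, beads, atol=1e-6)

    def test_mirror_image_of_chiral_model_not_superposable(self):
        t = np.linspace(0, 6 * np.pi, 60)
        helix = np.column_stack([np.cos(t), np.sin(t), 0.2 * t]) * 50
        mirror = helix * np.array([1, 1, -1])
        _, rmsd = lf.kabsch_align(helix, mirror, allow_reflection=False)
        assert rmsd > 1.0
        _, rmsd_ref = lf.kabsch_align(helix, mirror, allow_reflection=True)
        assert rmsd_ref == pytest.approx(0.0, abs=1e-6)

    def test_invariant_under_premotion_of_target(self, saw_truths):
        a = saw_truths[0].beads
        b = saw_truths[1].beads
        _, rmsd = lf.kabsch_align(a, b)
        a_moved = a @ _rot(0.3).T + 7.0
        _, rmsd2 = lf.kabsch_align(a_moved, b)
        assert rmsd2 == pytest.approx(rmsd, rel=1e-6)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            lf.kabsch_align(np.zeros((2, 3)), np.zeros((2, 3)))


class TestOrderRecovery:
    def test_identical_orders(self):
        rec = lf.order_recovery(np.arange(340), np.arange(340))
        assert rec.rho == pytest.approx(1.0)
        assert rec.significant

    def test_reversed_order_counts_as_recovered(self):
        rec = lf.order_recovery(np.arange(340), np.arange(340)[::-1])
        assert rec.rho == pytest.approx(1.0)
        assert rec.orientation == "reversed"

    def test_null_significance_calibrated(self):
        """Random permutations are flagged at about the alpha rate."""
        rng = np.random.default_rng(0)
        hits = sum(
            lf.order_recovery(np.arange(340), rng.permutation(340)).significant
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_length_mismatch_and_label_checks(self):
        with pytest.raises(ValueError):
            lf.order_recovery(np.arange(5), np.arange(6))
        with pytest.raises(ValueError):
            lf.order_recovery(np.arange(5), np.arange(1, 6))


class TestBinDistanceMap:
    def test_bins_to_common_resolution(self, saw_truths):
        dm = lf.distance_map(saw_truths[0])  # 120 beads
        binned = lf.bin_distance_map(dm, bead_bp=100, bin_bp=300)
        assert binned.matrix.shape == (40, 40)
        np.testing.assert_allclose(np.diag(binned.matrix), 0.0)
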