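import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import loopfold as lf


class TestSAW:
    def test_bond_lengths_exact(self):
        model = lf.saw_generate(lf.SAWConfig(n_beads=340, step=30.0, seed=0))
        bonds = np.linalg.norm(np.diff(model.beads, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 30.0, atol=1e-6)

    def test_excluded_volume_holds_for_every_pair(self):
        cfg = lf.SAWConfig(n_beads=200, step=30.0, excluded_radius=20.0, seed=4)
        model = lf.saw_generate(cfg)
        D = squareform(pdist(model.beads))
        non_adjacent = D[np.triu_indices(200, k=2)]
        assert non_adjacent.min() >= 20.0

    def test_default_excluded_radius_is_bond_length(self):
        cfg = lf.SAWConfig(n_beads=50, step=30.0, seed=1)
        model = lf.saw_generate(cfg)
        D = squareform(pdist(model.beads))
        assert D[np.triu_indices(50, k=2)].min() >= 30.0

    def test_same_seed_reproducible(self):
        cfg = lf.SAWConfig(n_beads=100, seed=42)
        a = lf.saw_generate(cfg)
        b = lf.saw_generate(cfg)
        np.testing.assert_array_equal(a.beads, b.beads)

    def test_impossible_radius_rejected(self):
        with pytest.raises(ValueError):
            lf.SAWConfig(n_beads=10, step=30.0, excluded_radius=60.0)

    def test_ensemble_reproducible_and_independent(self):
        cfg = lf.SAWConfig(n_beads=60, seed=7)
        e1 = lf.saw_ensemble(3, cfg)
        e2 = lf.saw_ensemble(3, cfg)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.beads, b.beads)
        assert not np.allclose(e1[0].beads, e1[1].beads)


class TestMDS:
    def _path_contacts(self, n):
        m = np.zeros((n, n))
        idx = np.arange(n - 1)
        m[idx, idx + 1] = m[idx + 1, idx] = 1.0
        return lf.ContactMatrix(m)

    def test_path_graph_embeds_monotonically(self):
        models = lf.mds_models_from_contacts(self._path_contacts(20), 2, seed=4)
        assert len(models) == 2
        for model in models:
            X = model.beads - model.beads.mean(axis=0)
            _, _, vt = np.linalg.svd(X, full_matrices=False)
            rho, _ = spearmanr(np.arange(20), X @ vt[0])
            assert abs(rho) > 0.99

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((5, 5))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            lf.ContactMatrix(m)

    def test_disconnected_graph_reports_isolated_bins(self):
        m = np.zeros((6, 6))
        for i in (0, 1):
            m[i, i + 1] = m[i + 1, i] = 1.0
        m[4, 5] = m[5, 4] = 1.0
        with pytest.raises(ValueError, match="isolated"):
            lf.mds_models_from_contacts(lf.ContactMatrix(m), 1)

    def test_distinct_initializations_give_distinct_models(self):
        models = lf.mds_models_from_contacts(self._path_contacts(15), 2, seed=0)
        assert not np.allclose(models[0].beads, models[1].beads)


class TestRescale:
    def test_matches_largest_axis(self, saw_truths):
        out = lf.rescale_to_volume(saw_truths[0], 500.0)
        extent = out.beads.max(axis=0) - out.beads.min(axis=0)
        assert extent.max() == pytest.approx(500.0)

    def test_idempotent(self, saw_truths):
        once = lf.rescale_to_volume(saw_truths[0], 500.0)
        twice = lf.rescale_to_volume(once, 500.0)
        np.testing.assert_allclose(once.beads, twice.beads, atol=1e-9)

    def test_normalized_imj_unchanged_by_rescaling(self, saw_truths):
        model = saw_truths[0]
        scaled = lf.rescale_to_volume(model, 123.0)
        score = lf.imj(lf.distance_map(model), lf.distance_map(scaled))
        assert score == pytest.approx(100.0)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            lf.rescale_to_volume(lf.PolymerModel(np.zeros((5, 3))), 100.0)


class TestSynthLocalizations:
    def test_noise_free_events_coincide_with_oligos(self, target_truth_model):
        cfg = lf.SynthImageConfig(efficiency=1.0, events_per_oligo=1,
                                  sigma_xyz=(0, 0, 0), seed=0, poisson_events=False)
        table, truth = lf.synth_localizations(target_truth_model, cfg)
        assert len(table) == len(truth) == 336
        np.testing.assert_allclose(
            table.positions, truth[["x", "y", "z"]].to_numpy(), atol=1e-9
        )

    def test_retention_is_binomial(self, target_truth_model):
        # mean retained over 200 seeded runs ~ Binomial(336, 0.5):
        # per-run SD = sqrt(336*0.25) = 9.17, SE of the mean = 0.65
        counts = []
        for seed in range(200):
            cfg = lf.SynthImageConfig(efficiency=0.5, events_per_oligo=1,
                                      seed=seed, poisson_events=False)
            _, truth = lf.synth_localizations(target_truth_model, cfg)
            counts.append(truth["retained"].sum())
        assert np.mean(counts) == pytest.approx(168.0, abs=2 * 0.65)

    def test_noise_moments_match_config(self, target_truth_model):
        cfg = lf.SynthImageConfig(efficiency=1.0, events_per_oligo=200,
                                  sigma_xyz=(10, 10, 10), seed=3,
                                  poisson_events=False)
        table, truth = lf.synth_localizations(target_truth_model, cfg)
        # events of the first oligo only: first 200 rows
        first = table.positions[:200]
        spread = first.std(axis=0, ddof=1)
        np.testing.assert_allclose(spread, 10.0, rtol=0.25)

    def test_deterministic_given_seed(self, target_truth_model):
        cfg = lf.SynthImageConfig(efficiency=0.7, seed=11)
        t1, g1 = lf.synth_localizations(target_truth_model, cfg)
        t2, g2 = lf.synth_localizations(target_truth_model, cfg)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        assert (g1["retained"] == g2["retained"]).all()


class TestSubsampleBeads:
    def test_contiguous_gap_230_of_340(self):
        model = lf.PolymerModel(np.random.default_rng(0).random((340, 3)))
        pts, surv = lf.subsample_beads(model, "contiguous_gap", 230, 5)
        assert len(pts) == 110
        runs = np.split(surv, np.flatnonzero(np.diff(surv) > 1) + 1)
        assert len(runs) <= 2

    def test_fraction_one_is_identity(self, saw_truths):
        pts, surv = lf.subsample_beads(saw_truths[0], "random_fraction", 1.0, 0)
        np.testing.assert_array_equal(surv, np.arange(saw_truths[0].n_beads))
        np.testing.assert_allclose(pts, saw_truths[0].beads)

    def test_fraction_030_of_340(self):
        model = lf.PolymerModel(np.zeros((340, 3)))
        pts, surv = lf.subsample_beads(model, "random_fraction", 0.30, 1)
        assert len(pts) == 102  # round(0.3 * 340)

    def test_gap_must_be_smaller_than_chain(self, saw_truths):
        with pytest.raises(ValueError):
            lf.subsample_beads(saw_truths[0], "contiguous_gap",
                               saw_truths[0].n_beads, 0)


def test_pipeline_closed_loop_on_noise_free_fixture(noise_free_image,
                                                    target_truth_model):
    """Grouping + TSP on a full-efficiency noise-free image recovers the
    exact oligo order (up to reversal)."""
    table, truth = noise_free_image
    groups = lf.group_peaks(table, radius=2.0, min_events=2)
    assert len(groups) == 336
    from scipy.spatial.distance import cdist

    nearest = cdist(groups.positions, truth[["x", "y", "z"]].to_numpy()).argmin(axis=1)
    ordering = lf.reconstruct_path(groups.positions)
    rec = lf.order_recovery(np.sort(nearest), nearest[ordering.order])
    assert rec.rho == pytest.approx(1.0)
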