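import numpy as np
import pytest

from relabeler.adasampler import (
    adasample,
    estimate_epsilon,
    reclassify,
    weighted_resample,
)
from relabeler.data import CellAnnotation

from conftest import make_blob_scores


def ann(labels, label_set=None):
    return CellAnnotation(labels, [f"c{i}" for i in range(len(labels))],
                          label_set=label_set)


class TestEstimateEpsilon:
    def test_one_hot_on_own_label_gives_zero(self):
        y = ann(["A", "B"], ["A", "B"])
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(estimate_epsilon(probs, y), [0.0, 0.0])

    def test_uniform_row_k4(self):
        y = ann(["A", "B", "C", "D"])
        probs = np.full((4, 4), 0.25)
        np.testing.assert_allclose(estimate_epsilon(probs, y), [0.75] * 4)

    def test_direct_complement(self):
        y = ann(["C"], ["A", "B", "C"])
        probs = np.array([[0.2, 0.5, 0.3]])
        assert estimate_epsilon(probs, y)[0] == pytest.approx(0.7)

    def test_label_outside_class_order_rejected(self):
        y = ann(["A", "Z"], ["A", "Z"])
        probs = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="class order"):
            estimate_epsilon(probs, y, class_order=["A", "B"])


class TestWeightedResample:
    def test_uniform_limit_is_per_class_bootstrap(self):
        y = ann(["A"] * 6 + ["B"] * 4)
        idx = weighted_resample(y, np.zeros(10), np.random.default_rng(0))
        assert len(idx) == 10
        assert np.sum(idx < 6) == 6  # six draws from class A members
        assert np.sum(idx >= 6) == 4

    def test_zero_weight_cell_never_drawn(self):
        y = ann(["A"] * 8 + ["B"] * 8)
        eps = np.zeros(16)
        eps[3] = 1.0
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert 3 not in weighted_resample(y, eps, rng)

    def test_all_zero_weights_fall_back_to_uniform(self):
        y = ann(["A"] * 4 + ["B"] * 4)
        eps = np.concatenate([np.ones(4), np.zeros(4)])
        with pytest.warns(UserWarning, match="uniform"):
            idx = weighted_resample(y, eps, np.random.default_rng(0))
        assert np.sum(idx < 4) == 4

    def test_inclusion_frequency_tracks_weights(self):
        """Empirical draw frequency matches (1-eps)/sum(1-eps) within 3 SE."""
        n = 8
        y = ann(["A"] * n + ["B"] * 2)
        eps = np.concatenate([np.linspace(0.0, 0.7, n), [0.0, 0.0]])
        w = 1.0 - eps[:n]
        p = w / w.sum()
        rng = np.random.default_rng(1)
        reps = 10_000
        counts = np.zeros(n)
        for _ in range(reps):
            idx = weighted_resample(y, eps, rng)
            for i in idx[idx < n]:
                counts[i] += 1
        draws = reps * n  # n draws per repeat within class A
        freq = counts / draws
        se = np.sqrt(p * (1 - p) / draws)
        assert np.all(np.abs(freq - p) <= 3 * se + 1e-12)


class TestAdasample:
    def test_correct_labels_on_separable_data_get_low_epsilon(self, separable_blobs):
        red, truth = separable_blobs
        eps = adasample(red, truth, "svm", L=3, rng=np.random.default_rng(5))
        assert np.all(eps < 0.5)

    def test_single_iteration_is_one_fit_predict(self, separable_blobs):
        """L=1 equals a single uniform-bootstrap fit-predict with the same stream."""
        red, truth = separable_blobs
        eps_a = adasample(red, truth, "rf", L=1, rng=np.random.default_rng(9))
        eps_b = adasample(red, truth, "rf", L=1, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(eps_a, eps_b)
        assert eps_a.shape == (red.n_cells,)
        assert np.all((eps_a >= 0) & (eps_a <= 1))

    def test_planted_outlier_gets_high_epsilon(self, separable_blobs):
        red, truth = separable_blobs
        labels = list(truth.labels)
        # plant one class-A cell labelled as B, deep inside A's blob
        labels[0] = truth.label_set[1]
        noisy = CellAnnotation(labels, list(truth.cell_ids),
                               label_set=list(truth.label_set))
        eps = adasample(red, noisy, "svm", L=3, rng=np.random.default_rng(5))
        assert eps[0] > 0.5

    def test_small_class_precondition(self):
        red, truth = make_blob_scores(3, np.eye(2) * 10, seed=0)
        with pytest.raises(ValueError, match="at least 4 cells"):
            adasample(red, truth, "svm", L=1, rng=np.random.default_rng(0))


class TestReclassify:
    def test_single_model_variant_runs(self, separable_blobs):
        red, truth = separable_blobs
        res = reclassify(red, truth, "rf", L=1, B_ensemble=1,
                         rng=np.random.default_rng(2))
        np.testing.assert_allclose(res.ensemble_probs.sum(axis=1), 1.0, atol=1e-9)

    def test_averaged_rows_still_sum_to_one(self, separable_blobs):
        red, truth = separable_blobs
        res = reclassify(red, truth, "rf", L=1, B_ensemble=4,
                         rng=np.random.default_rng(2))
        np.testing.assert_allclose(res.ensemble_probs.sum(axis=1), 1.0, atol=1e-9)

    def test_corrected_is_argmax_and_changed_mask_consistent(self, separable_blobs):
        red, truth = separable_blobs
        res = reclassify(red, truth, "svm", L=2, B_ensemble=3,
                         rng=np.random.default_rng(3))
        argmax_labels = [res.class_order[k]
                         for k in res.ensemble_probs.argmax(axis=1)]
        assert res.corrected.labels == argmax_labels
        changed = [a != b for a, b in zip(res.corrected.labels, truth.labels)]
        np.testing.assert_array_equal(res.changed_mask, changed)

    def test_restores_planted_flips(self, separable_blobs):
        """Cells flipped to the wrong type on separable data are restored."""
        red, truth = separable_blobs
        rng = np.random.default_rng(7)
        labels = list(truth.labels)
        flipped = rng.choice(red.n_cells, size=6, replace=False)
        k = len(truth.label_set)
        codes = truth.codes()
        for i in flipped:
            labels[i] = truth.label_set[(codes[i] + 1) % k]
        noisy = CellAnnotation(labels, list(truth.cell_ids),
                               label_set=list(truth.label_set))
        res = reclassify(red, noisy, "svm", L=3, B_ensemble=5,
                         rng=np.random.default_rng(8))
        restored = sum(res.corrected.labels[i] == truth.labels[i] for i in flipped)
        assert restored > len(flipped) / 2

    def test_fixed_seed_bit_reproducible(self, separable_blobs):
        red, truth = separable_blobs
        runs = [
            reclassify(red, truth, "svm", L=2, B_ensemble=2,
                       rng=np.random.default_rng(13))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].ensemble_probs, runs[1].ensemble_probs)
        assert runs[0].corrected.labels == runs[1].corrected.labels

    def test_permutation_equivariance_of_class_names(self, separable_blobs):
        """Renaming cell types changes nothing but the names in the output."""
        red, truth = separable_blobs
        rename = {"t0": "alpha", "t1": "beta", "t2": "gamma"}
        renamed = CellAnnotation([rename[l] for l in truth.labels],
                                 list(truth.cell_ids))
        res_a = reclassify(red, truth, "rf", L=2, B_ensemble=2,
                           rng=np.random.default_rng(21))
        res_b = reclassify(red, renamed, "rf", L=2, B_ensemble=2,
                           rng=np.random.default_rng(21))
        np.testing.assert_array_equal(res_a.epsilon_final, res_b.epsilon_final)
        np.testing.assert_array_equal(res_a.ensemble_probs, res_b.ensemble_probs)
        assert [rename[l] for l in res_a.corrected.labels] == res_b.corrected.labels

    def test_min_prob_keeps_uncertain_labels(self, separable_blobs):
        red, truth = separable_blobs
        res = reclassify(red, truth, "rf", L=1, B_ensemble=2,
                         rng=np.random.default_rng(4), min_prob=1.1)
        # impossible confidence bar: nothing may change
        assert res.corrected.labels == truth.labels

    def test_invalid_ensemble_size(self, separable_blobs):
        red, truth = separable_blobs
        with pytest.raises(ValueError, match="B_ensemble"):
            reclassify(red, truth, "svm", B_ensemble=0)


def test_correction_quality_decreases_with_noise_rate():
    """Seed-averaged corrected accuracy is monotone non-increasing over
    noise rates 0.1, 0.3, 0.5 for a fixed generator."""
    from relabeler.evaluate import benchmark
    from relabeler.synthesize import SimulationConfig

    cfg = SimulationConfig(n_types=5, cells_per_type=50, n_genes=800, de_prob=0.1)
    df = benchmark(cfg, rho_grid=[0.1, 0.3, 0.5], classifier_kinds=["svm"],
                   repeats=10, seed=3, L=3, B_ensemble=5)
    means = df.groupby("rho")["corrected_accuracy"].mean()
    assert means[0.1] >= means[0.3] >= means[0.5]
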