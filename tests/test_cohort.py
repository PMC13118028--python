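"""Synthetic cohort generation, splitting, PCA and classification."""

import numpy as np
import pytest

from lungident import (
    CohortConfig,
    CohortDataset,
    FrequencyGrid,
    NoiseSpec,
    generate_cohort,
    reduce_pca,
    split_stratified,
    train_and_evaluate,
)


@pytest.fixture(scope="module")
def small_cohort_config():
    """Reduced grid keeps module tests fast; full-size runs live elsewhere."""
    return CohortConfig(
        per_class=10,
        grid=FrequencyGrid(np.linspace(5.0, 150.0, 60)),
        noise=NoiseSpec(relative_sigma=0.02, seed=0),
        seed=123,
    )


@pytest.fixture(scope="module")
def small_cohort(small_cohort_config, model):
    return generate_cohort(small_cohort_config, model)


class TestGenerateCohort:
    def test_shapes_and_counts(self, small_cohort):
        assert small_cohort.features.shape == (30, 4 * 60)
        counts = dict(zip(*np.unique(small_cohort.labels, return_counts=True)))
        assert all(c == 10 for c in counts.values()) and len(counts) == 3

    def test_full_size_default_dimensions(self):
        cfg = CohortConfig()
        assert cfg.per_class == 30
        assert len(cfg.grid) == 300
        assert cfg.grid.frequencies[0] == 5.0 and cfg.grid.frequencies[-1] == 150.0

    def test_deterministic_given_seed(self, small_cohort_config, model):
        a = generate_cohort(small_cohort_config, model)
        b = generate_cohort(small_cohort_config, model)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_noise_zero_jitter_rows_identical_within_class(self, model):
        cfg = CohortConfig(
            per_class=3,
            grid=FrequencyGrid(np.linspace(5.0, 150.0, 40)),
            noise=NoiseSpec(relative_sigma=0.0),
            jitter_sigma=0.0,
            seed=1,
        )
        ds = generate_cohort(cfg, model)
        for label in cfg.conditions:
            rows = ds.features[ds.labels == label]
            assert np.ptp(rows, axis=0).max() == 0.0

    def test_classes_distinct_without_noise(self, model):
        cfg = CohortConfig(
            per_class=1,
            grid=FrequencyGrid(np.linspace(5.0, 150.0, 40)),
            noise=NoiseSpec(relative_sigma=0.0),
            seed=1,
        )
        ds = generate_cohort(cfg, model)
        assert len({tuple(row) for row in ds.features}) == 3

    def test_jitter_varies_subjects(self, model):
        cfg = CohortConfig(
            per_class=3,
            grid=FrequencyGrid(np.linspace(5.0, 150.0, 40)),
            noise=NoiseSpec(relative_sigma=0.0),
            jitter_sigma=0.05,
            seed=1,
        )
        ds = generate_cohort(cfg, model)
        healthy = ds.features[ds.labels == "healthy"]
        assert np.ptp(healthy, axis=0).max() > 0.0
        # provenance records the jittered spring values
        assert ds.provenance[0]["springs"]["k01"] != ds.provenance[1]["springs"]["k01"]

    def test_feature_layout_dof_major(self, small_cohort_config, model):
        """Row = [|X_0| over grid, |X_1| over grid, ...]."""
        from lungident import add_magnitude_noise, solve_frf

        rng = np.random.default_rng(small_cohort_config.seed)
        frf = solve_frf(model, small_cohort_config.grid)
        noisy = add_magnitude_noise(frf, small_cohort_config.noise, rng=rng)
        ds = generate_cohort(small_cohort_config, model)
        np.testing.assert_array_equal(ds.features[0], noisy.magnitude.ravel())


class TestSplitStratified:
    def test_reference_split_arithmetic(self, model):
        cfg = CohortConfig(grid=FrequencyGrid(np.linspace(5.0, 150.0, 20)))
        ds = generate_cohort(cfg, model)
        train, test = split_stratified(ds, 0.30, seed=0)
        assert train.n_realizations == 63 and test.n_realizations == 27
        _, counts = np.unique(test.labels, return_counts=True)
        assert list(counts) == [9, 9, 9]

    def test_deterministic_partition(self, small_cohort):
        a_train, a_test = split_stratified(small_cohort, 0.30, seed=5)
        b_train, b_test = split_stratified(small_cohort, 0.30, seed=5)
        np.testing.assert_array_equal(a_test.features, b_test.features)
        np.testing.assert_array_equal(a_train.features, b_train.features)

    def test_counts_partition_total(self, small_cohort):
        train, test = split_stratified(small_cohort, 0.30, seed=2)
        assert train.n_realizations + test.n_realizations == small_cohort.n_realizations

    def test_invalid_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_stratified(small_cohort, 1.5)

    def test_too_small_class_rejected(self, model):
        cfg = CohortConfig(
            per_class=1, grid=FrequencyGrid(np.linspace(5.0, 150.0, 10))
        )
        ds = generate_cohort(cfg, model)
        with pytest.raises(ValueError, match="stratify"):
            split_stratified(ds, 0.30)


class TestReducePCA:
    def test_reduced_width(self, small_cohort):
        train, test = split_stratified(small_cohort, 0.30, seed=0)
        tr, te, pca = reduce_pca(train.features, test.features, n_components=6)
        assert tr.shape[1] == 6 and te.shape[1] == 6

    def test_training_mean_maps_to_origin(self, small_cohort):
        train, test = split_stratified(small_cohort, 0.30, seed=0)
        tr, te, pca = reduce_pca(train.features, test.features, 6)
        origin = pca.transform(train.features.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(origin, 0.0, atol=1e-8)

    def test_reconstruction_error_non_increasing(self, small_cohort):
        train, _ = split_stratified(small_cohort, 0.30, seed=0)
        X = train.features
        errors = []
        for n in range(1, 11):
            _, _, pca = reduce_pca(X, X, n_components=n)
            recon = pca.inverse_transform(pca.transform(X))
            errors.append(np.sum((X - recon) ** 2))
        assert all(b <= a + 1e-9 for a, b in zip(errors, errors[1:]))

    def test_excessive_components_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            reduce_pca(small_cohort.features[:4], small_cohort.features, 10)


class TestTrainAndEvaluate:
    def test_perfect_separation_at_default_conditions(self, small_cohort):
        train, test = split_stratified(small_cohort, 0.30, seed=0)
        report = train_and_evaluate(train, test)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.f1.values())
        assert report.converged

    def test_confusion_matrix_consistency(self, small_cohort):
        train, test = split_stratified(small_cohort, 0.30, seed=1)
        report = train_and_evaluate(train, test)
        assert report.confusion.sum() == test.n_realizations
        row_sums = report.confusion.sum(axis=1)
        supports = [report.support[c] for c in report.classes]
        np.testing.assert_array_equal(row_sums, supports)
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum()
        )

    def test_resubstitution_on_separable_data(self, small_cohort):
        report = train_and_evaluate(small_cohort, small_cohort)
        assert report.accuracy == 1.0

    def test_permuted_labels_drop_to_chance(self, small_cohort):
        rng = np.random.default_rng(99)
        perm = small_cohort.labels.copy()
        rng.shuffle(perm)
        shuffled = CohortDataset(
            features=small_cohort.features,
            labels=perm,
            grid=small_cohort.grid,
            n_dof=small_cohort.n_dof,
        )
        train, test = split_stratified(shuffled, 0.30, seed=0)
        report = train_and_evaluate(train, test)
        assert report.accuracy < 0.75  # far from the separable-case 1.0

    def test_accuracy_degrades_gradually_with_noise(self, model):
        """No cliff: accuracy stays high as sigma grows to 20 %."""
        grid = FrequencyGrid(np.linspace(5.0, 150.0, 60))
        accs = []
        for sigma in (0.02, 0.05, 0.1, 0.2):
            cfg = CohortConfig(
                per_class=10,
                grid=grid,
                noise=NoiseSpec(relative_sigma=sigma),
                seed=7,
            )
            ds = generate_cohort(cfg, model)
            train, test = split_stratified(ds, 0.30, seed=0)
            accs.append(train_and_evaluate(train, test).accuracy)
        assert accs[0] == 1.0
        assert all(a >= 0.5 for a in accs)
        assert all(b <= a + 0.15 for a, b in zip(accs, accs[1:]))

    def test_pc_scores_cluster_separation(self, small_cohort):
        """Between-class centroid distances exceed within-class spread."""
        train, test = split_stratified(small_cohort, 0.30, seed=0)
        report = train_and_evaluate(train, test)
        scores, labels = report.pc_scores, report.pc_labels
        centroids = {c: scores[labels == c].mean(axis=0) for c in report.classes}
        spreads = {
            c: np.linalg.norm(scores[labels == c] - centroids[c], axis=1).mean()
            for c in report.classes
        }
        for a in report.classes:
            for b in report.classes:
                if a < b:
                    dist = np.linalg.norm(centroids[a] - centroids[b])
                    assert dist > max(spreads[a], spreads[b])
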