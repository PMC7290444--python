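import numpy as np
import pytest

from somgait.som import (
    SOMModel,
    SOMTrainConfig,
    bmu,
    bmu_batch,
    component_planes,
    hit_map,
    normalize_features,
    quantization_error,
    topographic_error,
    train_som,
)


@pytest.fixture(scope="module")
def two_blobs():
    """Two well-separated 13-d blobs (centers 10 within-blob SDs apart)."""
    rng = np.random.default_rng(7)
    c1 = np.zeros(13)
    c2 = np.zeros(13)
    c2[:3] = 10.0
    data = np.vstack(
        [rng.normal(c1, 1.0, (50, 13)), rng.normal(c2, 1.0, (50, 13))]
    )
    return data


@pytest.fixture(scope="module")
def blob_model(two_blobs):
    return train_som(two_blobs, SOMTrainConfig(seed=3))


class TestNormalize:
    def test_zscore_definition(self):
        z, p = normalize_features(np.array([[1.0], [2.0], [3.0]]))
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        z, p = normalize_features(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_allclose(z[:, 0], 0.0)
        assert p["zero_variance"][0] and not p["zero_variance"][1]

    def test_inverse_round_trip(self):
        x = np.random.default_rng(0).normal(3, 2, (10, 4))
        z, p = normalize_features(x)
        back = z * p["sd"] + p["mean"]
        np.testing.assert_allclose(back, x, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            normalize_features(np.ones((1, 3)))


class TestTraining:
    def test_repeated_point_fixed_point(self):
        point = np.arange(13.0)
        data = np.tile(point, (20, 1))
        model = train_som(data, SOMTrainConfig(seed=0, n_epochs_rough=10,
                                               n_epochs_finetune=10))
        np.testing.assert_allclose(
            model.codebook, np.tile(point, (model.n_units, 1)), atol=1e-6
        )

    def test_determinism(self, two_blobs):
        m1 = train_som(two_blobs, SOMTrainConfig(seed=5))
        m2 = train_som(two_blobs, SOMTrainConfig(seed=5))
        np.testing.assert_array_equal(m1.codebook, m2.codebook)

    def test_blobs_get_disjoint_bmu_regions(self, two_blobs, blob_model):
        units1 = set(bmu_batch(blob_model, two_blobs[:50]).tolist())
        units2 = set(bmu_batch(blob_model, two_blobs[50:]).tolist())
        assert units1.isdisjoint(units2)
        assert blob_model.qe_history[-1] < blob_model.qe_history[0]

    def test_prototypes_in_convex_hull_after_one_epoch(self):
        # 1-d data: the convex hull is just [min, max]
        rng = np.random.default_rng(1)
        data = rng.uniform(-2.0, 3.0, (30, 1))
        model = train_som(
            data, SOMTrainConfig(grid_rows=4, grid_cols=4, seed=0,
                                 n_epochs_rough=1, n_epochs_finetune=0)
        )
        assert np.all(model.codebook >= data.min() - 1e-12)
        assert np.all(model.codebook <= data.max() + 1e-12)

    def test_qe_non_increasing_in_finetune_phase(self, two_blobs):
        model = train_som(two_blobs, SOMTrainConfig(seed=2))
        fine = model.qe_history[model.config.n_epochs_rough:]
        diffs = np.diff(fine)
        assert np.all(diffs <= 1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train_som(np.empty((0, 13)), SOMTrainConfig())


class TestBMU:
    def test_exact_prototype_match(self, blob_model):
        assert bmu(blob_model, blob_model.codebook[37]) == 37

    def test_tie_breaks_to_lowest_index(self):
        config = SOMTrainConfig(grid_rows=2, grid_cols=5, n_epochs_rough=1,
                                n_epochs_finetune=0, radius_initial=1.0,
                                radius_final=1.0, seed=0)
        model = train_som(np.zeros((5, 3)), config)
        # all prototypes identical -> every sample is equidistant to all units
        assert bmu(model, np.ones(3)) == 0

    def test_agrees_with_brute_force_scan(self, blob_model):
        rng = np.random.default_rng(11)
        for sample in rng.normal(0, 5, (25, 13)):
            expected = min(
                range(blob_model.n_units),
                key=lambda u: (np.sum((blob_model.codebook[u] - sample) ** 2), u),
            )
            assert bmu(blob_model, sample) == expected

    def test_duplicate_sample_leaves_other_bmus_unchanged(self, two_blobs, blob_model):
        before = bmu_batch(blob_model, two_blobs)
        augmented = np.vstack([two_blobs, two_blobs[0]])
        after = bmu_batch(blob_model, augmented)
        np.testing.assert_array_equal(before, after[:-1])


class TestMapDiagnostics:
    def test_hit_map_conservation(self, two_blobs, blob_model):
        hits = hit_map(blob_model, two_blobs)
        assert hits.shape == (10, 10)
        assert hits.sum() == len(two_blobs)

    def test_hit_map_empty(self, blob_model):
        hits = hit_map(blob_model, np.empty((0, 13)))
        assert hits.sum() == 0

    def test_component_planes_flat_for_constant_data(self):
        data = np.tile(np.array([2.0, -1.0, 0.5]), (10, 1))
        model = train_som(data, SOMTrainConfig(seed=0, n_epochs_rough=10,
                                               n_epochs_finetune=5))
        planes = component_planes(model)
        for i, value in enumerate([2.0, -1.0, 0.5]):
            np.testing.assert_allclose(planes[i], value, atol=1e-6)

    def test_separating_feature_plane_is_bimodal(self, two_blobs, blob_model):
        planes = component_planes(blob_model)
        units1 = bmu_batch(blob_model, two_blobs[:50])
        units2 = bmu_batch(blob_model, two_blobs[50:])
        plane0 = planes[0].ravel()  # feature 0 separates the blobs (0 vs 10)
        assert plane0[units1].mean() < 2.0
        assert plane0[units2].mean() > 8.0

    def test_qe_zero_on_codebook_and_matches_brute_force(self, blob_model, two_blobs):
        assert quantization_error(blob_model, blob_model.codebook) == pytest.approx(0.0)
        qe = quantization_error(blob_model, two_blobs)
        dists = [
            np.min(np.linalg.norm(blob_model.codebook - s, axis=1)) for s in two_blobs
        ]
        assert qe == pytest.approx(np.mean(dists))

    def test_topographic_error_in_unit_interval(self, blob_model, two_blobs):
        te = topographic_error(blob_model, two_blobs)
        assert 0.0 <= te <= 1.0


class TestSerialization:
    def test_json_round_trip(self, blob_model, tmp_path):
        path = tmp_path / "model.json"
        blob_model.to_json(path)
        back = SOMModel.from_json(path)
        np.testing.assert_array_equal(back.codebook, blob_model.codebook)
        np.testing.assert_array_equal(back.norm_mean, blob_model.norm_mean)
        assert back.config == blob_model.config

    def test_version_checked(self, blob_model, tmp_path):
        path = tmp_path / "model.json"
        blob_model.to_json(path)
        path.write_text(path.read_text().replace("somgait-1", "other-9"))
        with pytest.raises(ValueError, match="version"):
            SOMModel.from_json(path)
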