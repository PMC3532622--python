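"""Centroid construction, cosine index, three-way calls, platform reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from msisig.classifier import (
    build_centroids,
    classify,
    classify_matrix,
    msi_index,
    msi_index_matrix,
    reduce_to_platform,
)
from msisig.errors import ValidationError
from msisig.io_formats import MSI, MSI_LIKE, MSS, ExpressionMatrix, SignatureModel


def _model(n=64, seed=0, thresholds=(0.0, 0.3)):
    rng = np.random.default_rng(seed)
    return SignatureModel(
        [f"g{i:03d}" for i in range(n)],
        rng.normal(size=n),
        rng.normal(size=n),
        *thresholds,
    )


def _orthogonal_model(thresholds=None):
    c_msi = np.array([1.0, 0.0, 1.0, 0.0])
    c_mss = np.array([0.0, 1.0, 0.0, 1.0])
    primary, secondary = thresholds if thresholds else (None, None)
    return SignatureModel(["a", "b", "c", "d"], c_msi, c_mss, primary, secondary)


class TestBuildCentroids:
    def test_centroids_are_class_means(self):
        m = ExpressionMatrix(
            ["s1", "s2", "s3", "s4"],
            ["g1", "g2"],
            [[1.0, 1.0], [3.0, 3.0], [0.0, 2.0], [0.0, 4.0]],
        )
        model = build_centroids(m, [1, 1, 0, 0], ["g1", "g2"])
        np.testing.assert_allclose(model.centroid_msi, [2.0, 2.0])
        np.testing.assert_allclose(model.centroid_mss, [0.0, 3.0])

    def test_single_sample_per_class_copies_profiles(self):
        m = ExpressionMatrix(["a", "b"], ["g1", "g2"], [[1.0, -1.0], [2.0, 0.5]])
        model = build_centroids(m, [1, 0], ["g1", "g2"])
        np.testing.assert_allclose(model.centroid_msi, m.values[0])
        np.testing.assert_allclose(model.centroid_mss, m.values[1])

    def test_sample_order_irrelevant(self, rng):
        vals = rng.normal(size=(10, 5))
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        genes = [f"g{j}" for j in range(5)]
        m1 = ExpressionMatrix([f"s{i}" for i in range(10)], genes, vals)
        perm = rng.permutation(10)
        m2 = ExpressionMatrix([f"s{i}" for i in perm], genes, vals[perm])
        a = build_centroids(m1, labels, genes)
        b = build_centroids(m2, labels[perm], genes)
        np.testing.assert_allclose(a.centroid_msi, b.centroid_msi)

    def test_missing_gene_listed(self, small_matrix):
        with pytest.raises(ValidationError, match="gX"):
            build_centroids(small_matrix, [1, 0, 0], ["gA", "gX"])


class TestMsiIndex:
    def test_profile_equal_to_msi_centroid_orthogonal(self):
        model = _orthogonal_model()
        corr_msi, corr_mss, idx = msi_index(model.centroid_msi, model)
        assert corr_msi == pytest.approx(1.0)
        assert corr_mss == pytest.approx(0.0)
        assert idx == pytest.approx(1.0)

    def test_negated_mss_centroid_orthogonal(self):
        model = _orthogonal_model()
        _, corr_mss, idx = msi_index(-model.centroid_mss, model)
        assert corr_mss == pytest.approx(-1.0)
        assert idx == pytest.approx(1.0)

    def test_matches_brute_force_dot_product(self, rng):
        model = _model()
        x = rng.normal(size=64)
        corr_msi, corr_mss, idx = msi_index(x, model)

        def cos(u, v):
            return float(np.dot(u, v) / (np.sqrt(np.dot(u, u)) * np.sqrt(np.dot(v, v))))

        assert abs(corr_msi - cos(x, model.centroid_msi)) < 1e-12
        assert abs(corr_mss - cos(x, model.centroid_mss)) < 1e-12
        assert abs(idx - (corr_msi - corr_mss)) < 1e-12

    def test_scale_invariance(self, rng):
        model = _model()
        x = rng.normal(size=64)
        assert msi_index(x, model)[2] == pytest.approx(msi_index(17.3 * x, model)[2], abs=1e-12)

    def test_antisymmetry_under_centroid_swap(self, rng):
        model = _model()
        swapped = SignatureModel(model.gene_ids, model.centroid_mss, model.centroid_msi)
        x = rng.normal(size=64)
        assert msi_index(x, model)[2] == pytest.approx(-msi_index(x, swapped)[2], abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x=arrays(np.float64, 8, elements=st.floats(-5, 5)),
        lam=st.floats(0.01, 100),
    )
    def test_scale_invariance_and_range_property(self, x, lam):
        if np.linalg.norm(x) < 1e-6:
            return
        model = _model(n=8, seed=99)
        _, _, idx = msi_index(x, model)
        assert -2.0 <= idx <= 2.0
        assert msi_index(lam * x, model)[2] == pytest.approx(idx, abs=1e-9)

    def test_zero_norm_profile_rejected(self):
        with pytest.raises(ValidationError, match="zero-norm"):
            msi_index(np.zeros(4), _orthogonal_model())

    def test_matrix_variant_agrees_with_scalar(self, rng):
        model = _model(n=5)
        m = ExpressionMatrix([f"s{i}" for i in range(4)], model.gene_ids, rng.normal(size=(4, 5)))
        table = msi_index_matrix(m, model)
        for i in range(4):
            assert table["index"][i] == pytest.approx(msi_index(m.values[i], model)[2], abs=1e-12)

    def test_separation_of_class_clouds(self):
        # samples drawn around each centroid: MSI cloud gets higher indices
        for seed in range(10):
            rng = np.random.default_rng(seed)
            model = _model(seed=seed)
            near_msi = model.centroid_msi + rng.normal(0, 0.5, size=(30, 64))
            near_mss = model.centroid_mss + rng.normal(0, 0.5, size=(30, 64))
            idx_msi = np.mean([msi_index(x, model)[2] for x in near_msi])
            idx_mss = np.mean([msi_index(x, model)[2] for x in near_mss])
            assert idx_msi > idx_mss


class TestClassify:
    @pytest.mark.parametrize(
        "index,expected",
        [(-0.1, MSS), (0.1, MSI_LIKE), (0.0, MSI_LIKE), (0.3, MSI), (0.5, MSI)],
    )
    def test_boundary_convention(self, index, expected):
        model = _orthogonal_model(thresholds=(0.0, 0.3))
        assert classify(index, model) == expected

    def test_unset_thresholds_rejected(self):
        with pytest.raises(ValidationError, match="unset"):
            classify(0.5, _orthogonal_model())

    def test_stale_thresholds_rejected(self):
        model = _model()
        model.thresholds_stale = True
        with pytest.raises(ValidationError, match="stale"):
            classify(0.5, model)


class TestReduceToPlatform:
    def test_reduction_records_drops_and_flags_stale(self):
        model = _model(64)
        available = model.gene_ids[:58]
        reduced = reduce_to_platform(model, available)
        assert reduced.n_genes == 58
        assert len(reduced.provenance["dropped_genes"]) == 6
        assert reduced.thresholds_stale

    def test_all_genes_available_not_stale(self):
        model = _model(64)
        reduced = reduce_to_platform(model, model.gene_ids)
        assert reduced.gene_ids == model.gene_ids
        assert not reduced.thresholds_stale

    def test_reduced_index_equals_subvector_computation(self, rng):
        model = _model(64)
        reduced = reduce_to_platform(model, model.gene_ids[:58])
        x = rng.normal(size=64)
        direct = msi_index(x[:58], reduced)

        def cos(u, v):
            return np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))

        expected = cos(x[:58], model.centroid_msi[:58]) - cos(x[:58], model.centroid_mss[:58])
        assert direct[2] == pytest.approx(expected, abs=1e-12)

    def test_floor_enforced(self):
        model = _model(64)
        with pytest.raises(ValidationError, match="floor"):
            reduce_to_platform(model, model.gene_ids[:40])

    def test_rethresholded_reduced_model_classifies(self, rng):
        model = _model(64)
        reduced = reduce_to_platform(model, model.gene_ids[:58]).with_thresholds(0.0, 0.2)
        m = ExpressionMatrix(["s"], reduced.gene_ids, rng.normal(size=(1, 58)))
        calls = classify_matrix(m, reduced)
        assert calls["call"][0] in (MSS, MSI_LIKE, MSI)
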