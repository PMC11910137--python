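"""Dimensionality reduction: oracle equivalences, bounds and geometry."""

import numpy as np
import pandas as pd
import pytest

import ramantax as rt
from ramantax import benchmark as bm
from ramantax.dimred import (DimensionError, GridMismatchError, DRSpec,
                             class_centroid_distance, fit_dr,
                             lda_directions, supervised_pca_directions,
                             transform)


def _ds_from(X, y=None, stages=None):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    grid = rt.WavenumberGrid(np.arange(p, dtype=float) + 600.0)
    labels = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "strain": y if y is not None else ["s0"] * n,
        "genus": "g", "phylum": "p",
        "stage": stages if stages is not None else ["Exp"] * n,
    })
    return rt.SpectraDataset(grid=grid, intensities=X, labels=labels)


def _match_up_to_sign(A, B, atol=1e-8):
    assert A.shape == B.shape
    for j in range(A.shape[1]):
        col_ok = (np.allclose(A[:, j], B[:, j], atol=atol)
                  or np.allclose(A[:, j], -B[:, j], atol=atol))
        assert col_ok, f"column {j} differs beyond sign"


class TestSpecValidation:
    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown DR"):
            DRSpec("TSNE")

    def test_out_dim_positive(self):
        with pytest.raises(DimensionError):
            DRSpec("PCA", out_dim=0)


class TestNone:
    def test_identity(self, tiny_ds):
        fdr = fit_dr(DRSpec("NONE"), tiny_ds)
        rd = transform(fdr, tiny_ds)
        np.testing.assert_array_equal(rd.features, tiny_ds.intensities)


class TestPCA:
    def test_line_data_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=40)
        X = np.outer(t, [1.0, 2.0, -1.0, 0.5]) + 5.0
        fdr = fit_dr(DRSpec("PCA", out_dim=2), _ds_from(X))
        model = fdr.payload["model"]
        assert model.explained_variance_ratio_[0] > 0.999

    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        ds = _ds_from(X)
        rd = transform(fit_dr(DRSpec("PCA", out_dim=3), ds), ds)
        # brute-force covariance eigendecomposition oracle
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / X.shape[0])
        scores = Xc @ evecs[:, ::-1][:, :3]
        _match_up_to_sign(rd.features, scores)


class TestKPCA:
    def test_linear_kernel_equals_pca(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 6))
        ds = _ds_from(X)
        pca = transform(fit_dr(DRSpec("PCA", out_dim=3), ds), ds)
        kpca = transform(fit_dr(DRSpec("KPCA", out_dim=3, kernel="linear"), ds),
                         ds)
        _match_up_to_sign(pca.features, kpca.features, atol=1e-6)

    def test_rbf_finite_and_right_shape(self, tiny_ds):
        rd = transform(fit_dr(DRSpec("KPCA", out_dim=4), tiny_ds), tiny_ds)
        assert rd.features.shape == (tiny_ds.n_cells, 4)
        assert np.all(np.isfinite(rd.features))


class TestLDA:
    def test_four_class_bound(self, tiny_ds):
        ok = fit_dr(DRSpec("LDA", out_dim=3), tiny_ds, label_field="stage")
        assert ok.out_dim == 3
        with pytest.raises(DimensionError, match="n_classes - 1 = 3"):
            fit_dr(DRSpec("LDA", out_dim=4), tiny_ds, label_field="stage")

    def test_matches_generalized_eigensolver(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (6, 5)), rng.normal(2, 1, (6, 5)),
                       rng.normal(-2, 1, (6, 5))])
        y = np.repeat(["a", "b", "c"], 6)
        W = lda_directions(X, y, 2)
        # independent oracle: eig of inv(Sw) Sb with identical scatter defs
        from ramantax.dimred import _scatter_matrices
        Sb, Sw = _scatter_matrices(X, y)
        evals, evecs = np.linalg.eig(np.linalg.inv(Sw) @ Sb)
        order = np.argsort(evals.real)[::-1]
        V = evecs[:, order[:2]].real
        # compare as unit vectors up to sign
        _match_up_to_sign(W / np.linalg.norm(W, axis=0),
                          V / np.linalg.norm(V, axis=0), atol=1e-8)

    def test_requires_labels(self, tiny_ds):
        with pytest.raises(ValueError, match="label_field"):
            fit_dr(DRSpec("LDA", out_dim=2), tiny_ds)


class TestSupervisedPCA:
    def test_top_direction_follows_class_mean_difference(self):
        rng = np.random.default_rng(4)
        mean_diff = np.array([3.0, 0.0, 0.0, 0.0])
        X = np.vstack([rng.normal(0, 0.3, (100, 4)),
                       rng.normal(0, 0.3, (100, 4)) + mean_diff])
        y = np.repeat(["a", "b"], 100)
        W = supervised_pca_directions(X, y, 1)
        cosine = abs(W[:, 0] @ (mean_diff / np.linalg.norm(mean_diff)))
        assert np.degrees(np.arccos(min(cosine, 1.0))) < 5.0


class TestISM:
    def test_deterministic_and_finite(self, tiny_ds):
        f1 = fit_dr(DRSpec("ISM_SDR", out_dim=3), tiny_ds, label_field="strain")
        f2 = fit_dr(DRSpec("ISM_SDR", out_dim=3), tiny_ds, label_field="strain")
        np.testing.assert_array_equal(f1.payload["components"],
                                      f2.payload["components"])
        rd = transform(f1, tiny_ds)
        assert np.all(np.isfinite(rd.features))
        assert f1.payload["n_iter"] <= 100


@pytest.mark.parametrize("method", ["NONE", "PCA", "KPCA", "LDA", "SUP_PCA",
                                    "ISM_SDR"])
def test_every_method_produces_out_dim_finite_features(method, tiny_ds):
    spec = DRSpec(method, out_dim=3)
    fdr = fit_dr(spec, tiny_ds,
                 label_field="strain" if spec.supervised else None)
    rd = transform(fdr, tiny_ds)
    expected = tiny_ds.n_channels if method == "NONE" else 3
    assert rd.features.shape == (tiny_ds.n_cells, expected)
    assert np.all(np.isfinite(rd.features))


def test_transform_rejects_other_grid(tiny_ds, small_ds):
    fdr = fit_dr(DRSpec("PCA", out_dim=2), tiny_ds)
    with pytest.raises(GridMismatchError):
        transform(fdr, small_ds)


class TestCentroidDistance:
    def test_identical_centroids(self):
        rd = rt.ReducedDataset(
            features=np.array([[1.0, 2.0], [1.0, 2.0]]),
            labels=pd.DataFrame({"strain": ["a", "b"]}))
        assert class_centroid_distance(rd, "strain", "a", "b") == 0.0

    def test_single_points(self):
        rd = rt.ReducedDataset(
            features=np.array([[0.0, 0.0], [3.0, 4.0]]),
            labels=pd.DataFrame({"strain": ["a", "b"]}))
        assert class_centroid_distance(rd, "strain", "a", "b") == 5.0

    def test_empty_class(self):
        rd = rt.ReducedDataset(features=np.zeros((2, 2)),
                               labels=pd.DataFrame({"strain": ["a", "a"]}))
        with pytest.raises(ValueError, match="no samples"):
            class_centroid_distance(rd, "strain", "a", "b")


def test_supervised_separates_overlapping_pair_better_than_pca(small_ds):
    """LDA pulls the attenuated strain pair further apart than PCA (in
    spread-normalized reduced space) — single-seed smoke version."""
    pair = ("strain00", "strain01")
    dists = {}
    for method in ("LDA", "PCA"):
        spec = DRSpec(method, out_dim=5)
        fdr = fit_dr(spec, small_ds,
                     label_field="strain" if spec.supervised else None)
        rd = transform(fdr, small_ds)
        scale = np.sqrt(rd.features.var(axis=0).sum())
        rd.features /= scale
        dists[method] = class_centroid_distance(rd, "strain", *pair)
    assert dists["LDA"] > dists["PCA"]
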