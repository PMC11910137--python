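"""Six dimensionality-reduction methods behind a single fit/transform surface.

========  ==========================================================  ==========
name      construction                                                supervised
========  ==========================================================  ==========
NONE      identity (classifiers see the full spectrum)                no
PCA       principal component analysis                                no
KPCA      kernel PCA, RBF kernel by default                           no
LDA       Fisher discriminant directions, generalized eigenproblem    yes
SUP_PCA   supervised PCA: eigenvectors of X_c' (H Y)(H Y)' X_c,       yes
          the HSIC-weighted covariance with a one-hot label kernel
ISM_SDR   iterative supervised kernel dimension reduction:            yes
          alternate a dependence-weighted scatter eigendecomposition
          with an RBF kernel-scale update in the current subspace
========  ==========================================================  ==========

PCA and KPCA delegate to scikit-learn; LDA, SUP_PCA and ISM_SDR are solved
here directly so projections are deterministic and checkable against dense
eigensolvers.  Component signs are fixed so the largest-magnitude loading of
each direction is positive.

Note on SUP_PCA: with a one-hot label kernel the target matrix has rank at
most ``n_classes``; requesting more output dimensions appends the
(deterministic) near-null eigenvectors.

The ISM_SDR variant implemented here follows the iterative-spectral recipe
(scatter eigendecomposition + median-heuristic kernel-scale update,
convergence on subspace angle); numerical equality with other
implementations of the method is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SKPCA
from sklearn.decomposition import KernelPCA as _SKKernelPCA

from .dataset import SpectraDataset, WavenumberGrid

DR_METHODS = ("NONE", "ISM_SDR", "PCA", "LDA", "KPCA", "SUP_PCA")
SUPERVISED_DR = frozenset({"ISM_SDR", "LDA", "SUP_PCA"})


class DimensionError(ValueError):
    """Requested output dimensionality is infeasible for the method."""


class GridMismatchError(ValueError):
    """Dataset grid differs from the grid the transform was fitted on."""


@dataclass(frozen=True)
class DRSpec:
    """A named DR method with its output dimensionality.

    ``kernel_scale`` (sigma of the RBF kernel) applies to KPCA and ISM_SDR;
    when None the median pairwise-distance heuristic is used.  ``kernel``
    lets KPCA run with a linear kernel for oracle checks.
    """

    method: str
    out_dim: int = 35
    kernel_scale: float | None = None
    kernel: str = "rbf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in DR_METHODS:
            raise ValueError(f"unknown DR method {self.method!r}; known: {DR_METHODS}")
        if self.out_dim < 1:
            raise DimensionError("out_dim must be >= 1")
        if self.kernel_scale is not None and self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")

    @property
    def supervised(self) -> bool:
        return self.method in SUPERVISED_DR


@dataclass
class FittedDR:
    """A fitted transform mapping spectra on the training grid to out_dim."""

    spec: DRSpec
    grid: WavenumberGrid
    payload: dict = field(default_factory=dict)

    @property
    def out_dim(self) -> int:
        return self.payload.get("out_dim", self.spec.out_dim)


@dataclass
class ReducedDataset:
    """Post-DR features with the label table carried along."""

    features: np.ndarray
    labels: pd.DataFrame


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def median_pairwise_distance(X: np.ndarray, seed: int = 0,
                             max_points: int = 512) -> float:
    """Median Euclidean pairwise distance on a (subsampled) point set."""
    if X.shape[0] > max_points:
        idx = np.random.default_rng(seed).choice(X.shape[0], max_points,
                                                 replace=False)
        X = X[idx]
    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-|loading| entry of each is positive."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def _one_hot_centered(y: np.ndarray) -> np.ndarray:
    classes, yi = np.unique(y, return_inverse=True)
    Y = np.zeros((y.size, classes.size))
    Y[np.arange(y.size), yi] = 1.0
    return Y - Y.mean(axis=0)


def _scatter_matrices(X: np.ndarray, y: np.ndarray,
                      ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and (ridge-stabilised) within-class scatter, both /n."""
    n, p = X.shape
    mu = X.mean(axis=0)
    classes = np.unique(y)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        d = Xc - Xc.mean(axis=0)
        Sw += d.T @ d
        m = Xc.mean(axis=0) - mu
        Sb += Xc.shape[0] * np.outer(m, m)
    Sw /= n
    Sb /= n
    Sw += ridge * (np.trace(Sw) / p + 1e-12) * np.eye(p)
    return Sb, Sw


def lda_directions(X: np.ndarray, y: np.ndarray, out_dim: int,
                   ridge: float = 1e-8) -> np.ndarray:
    """Top Fisher directions from eigh(Sb, Sw); Sw-orthonormal columns."""
    n_classes = np.unique(y).size
    if out_dim > n_classes - 1:
        raise DimensionError(
            f"LDA supports at most n_classes - 1 = {n_classes - 1} output "
            f"dimensions for a {n_classes}-class problem, got {out_dim}"
        )
    Sb, Sw = _scatter_matrices(X, y, ridge=ridge)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    W = evecs[:, ::-1][:, :out_dim]
    return _fix_signs(W)


def supervised_pca_directions(X: np.ndarray, y: np.ndarray,
                              out_dim: int) -> np.ndarray:
    """Top eigenvectors of the label-kernel-weighted covariance X_c' Yc Yc' X_c."""
    Xc = X - X.mean(axis=0)
    M = Xc.T @ _one_hot_centered(y)  # p x n_classes
    B = M @ M.T
    evals, evecs = np.linalg.eigh(B)
    return _fix_signs(evecs[:, ::-1][:, :out_dim])


def _ism_directions(X: np.ndarray, y: np.ndarray, out_dim: int,
                    kernel_scale: float | None, max_iter: int = 100,
                    tol: float = 1e-6) -> tuple[np.ndarray, dict]:
    Xc = X - X.mean(axis=0)
    Yc = _one_hot_centered(y)
    Psi = Yc @ Yc.T  # n x n centered label kernel
    W = supervised_pca_directions(X, y, out_dim)  # warm start
    info = {"converged": False, "n_iter": 0}
    for it in range(1, max_iter + 1):
        Z = Xc @ W
        D2 = squareform(pdist(Z) ** 2)
        if kernel_scale is not None:
            sigma = kernel_scale
        else:
            pos = D2[D2 > 0]
            sigma = float(np.sqrt(np.median(pos))) if pos.size else 1.0
        K = np.exp(-D2 / (2.0 * sigma ** 2))
        M = Xc.T @ (Psi * K) @ Xc
        M = 0.5 * (M + M.T)
        evals, evecs = np.linalg.eigh(M)
        W_new = _fix_signs(evecs[:, ::-1][:, :out_dim])
        angle = scipy.linalg.subspace_angles(W, W_new)
        W = W_new
        info["n_iter"] = it
        if angle.size and angle.max() < tol:
            info["converged"] = True
            break
    info["sigma"] = sigma
    return W, info


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------


def fit_dr(spec: DRSpec, ds: SpectraDataset,
           label_field: str | None = None) -> FittedDR:
    """Fit the requested DR on a dataset.

    Supervised methods (LDA, SUP_PCA, ISM_SDR) require ``label_field``
    (one of strain/genus/phylum/stage); unsupervised methods ignore it.
    """
    X = ds.intensities
    n, p = X.shape
    method = spec.method

    if method != "NONE" and spec.out_dim > p:
        raise DimensionError(
            f"out_dim {spec.out_dim} exceeds the {p} available channels"
        )

    y = None
    if spec.supervised:
        if label_field is None:
            raise ValueError(f"{method} is supervised and needs a label_field")
        y = ds.labels[label_field].to_numpy()

    payload: dict = {}
    if method == "NONE":
        payload = {"out_dim": p}
    elif method == "PCA":
        if spec.out_dim > min(n, p):
            raise DimensionError(
                f"PCA out_dim {spec.out_dim} exceeds min(n_samples, n_channels)"
            )
        model = _SKPCA(n_components=spec.out_dim, svd_solver="full")
        model.fit(X)
        payload = {"model": model, "out_dim": spec.out_dim}
    elif method == "KPCA":
        if spec.kernel == "rbf":
            sigma = spec.kernel_scale or median_pairwise_distance(X, spec.seed)
            gamma = 1.0 / (2.0 * sigma ** 2)
        else:
            sigma, gamma = None, None
        model = _SKKernelPCA(n_components=spec.out_dim, kernel=spec.kernel,
                             gamma=gamma)
        model.fit(X)
        payload = {"model": model, "sigma": sigma, "out_dim": spec.out_dim}
    elif method == "LDA":
        W = lda_directions(X, y, spec.out_dim)
        payload = {"mean": X.mean(axis=0), "components": W,
                   "out_dim": spec.out_dim}
    elif method == "SUP_PCA":
        W = supervised_pca_directions(X, y, spec.out_dim)
        payload = {"mean": X.mean(axis=0), "components": W,
                   "out_dim": spec.out_dim}
    elif method == "ISM_SDR":
        W, info = _ism_directions(X, y, spec.out_dim, spec.kernel_scale)
        payload = {"mean": X.mean(axis=0), "components": W,
                   "out_dim": spec.out_dim, **info}

    return FittedDR(spec=spec, grid=ds.grid, payload=payload)


def transform(fdr: FittedDR, ds: SpectraDataset) -> ReducedDataset:
    """Map spectra (on the training grid) into the fitted reduced space."""
    if ds.grid != fdr.grid:
        raise GridMismatchError(
            "dataset grid differs from the grid the DR was fitted on"
        )
    X = ds.intensities
    method = fdr.spec.method
    if method == "NONE":
        Z = X.copy()
    elif method in ("PCA", "KPCA"):
        Z = fdr.payload["model"].transform(X)
    else:
        Z = (X - fdr.payload["mean"]) @ fdr.payload["components"]
    return ReducedDataset(features=np.asarray(Z, dtype=float),
                          labels=ds.labels.copy())


def class_centroid_distance(rd: ReducedDataset, label_field: str,
                            class_a: str, class_b: str) -> float:
    """Euclidean distance between two class centroids in reduced space."""
    y = rd.labels[label_field].to_numpy()
    dist_points = []
    for c in (class_a, class_b):
        mask = y == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no samples in field {label_field!r}")
        dist_points.append(rd.features[mask].mean(axis=0))
    return float(np.linalg.norm(dist_points[0] - dist_points[1]))


def capped_spec(spec: DRSpec, n_classes: int, n_channels: int,
                n_samples: int | None = None) -> DRSpec:
    """Shrink ``out_dim`` to what the method admits on a given problem.

    LDA is capped at ``n_classes - 1``; every method at the channel count;
    PCA additionally at the sample count.  Used by the benchmark runner so
    one grid-wide default (35 for taxonomy, 3 for the 4-class stage task)
    applies across methods of different feasible ranges.
    """
    cap = n_channels
    if spec.method == "LDA":
        cap = min(cap, n_classes - 1)
    if spec.method == "PCA" and n_samples is not None:
        cap = min(cap, n_samples)
    if spec.out_dim > cap:
        return replace(spec, out_dim=cap)
    return spec
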