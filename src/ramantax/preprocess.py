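"""Spectral preprocessing: background subtraction, smoothing, baseline
correction, normalization and resampling.

The default pipeline order is background -> smooth -> baseline -> normalize.
Baseline estimation uses asymmetric least squares (ALS): a smoothness-
penalized fit in which points above the current baseline (peaks) get weight
``p`` and points below get ``1 - p``, so the fit hugs the slowly-varying
background under the peaks.  Smoothing is Savitzky-Golay.

Every operation returns a new dataset; labels and row order are never
touched, and only :func:`resample` changes the grid.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .dataset import SpectraDataset, WavenumberGrid


class ParameterError(ValueError):
    """Invalid preprocessing parameter."""


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


def _record(ds: SpectraDataset, X: np.ndarray, step: str, params: dict,
            grid: WavenumberGrid | None = None) -> SpectraDataset:
    out = ds.with_intensities(X, grid=grid)
    steps = list(out.meta.get("preprocess_steps", []))
    steps.append({"step": step, **params})
    out.meta["preprocess_steps"] = steps
    return out


def subtract_background(ds: SpectraDataset, background: np.ndarray) -> SpectraDataset:
    """Subtract a measured background spectrum (same grid) from every cell."""
    bg = np.asarray(background, dtype=float).ravel()
    if bg.size != ds.n_channels:
        raise ParameterError(
            f"background has {bg.size} channels, dataset has {ds.n_channels}"
        )
    return _record(ds, ds.intensities - bg[None, :], "subtract_background", {})


def smooth(ds: SpectraDataset, window: int = 11, polyorder: int = 3) -> SpectraDataset:
    """Savitzky-Golay smoothing applied per spectrum."""
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError("window must exceed polyorder")
    if window > ds.n_channels:
        raise ParameterError("window exceeds channel count")
    X = savgol_filter(ds.intensities, window_length=window,
                      polyorder=polyorder, axis=1)
    return _record(ds, X, "smooth", {"window": window, "polyorder": polyorder})


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    P = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + P).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(ds: SpectraDataset, lam: float = 1e5, p: float = 0.01,
                     n_iter: int = 10) -> SpectraDataset:
    """Estimate and subtract an ALS baseline from every spectrum.

    ``lam`` weighs baseline smoothness (larger = stiffer), ``p`` in (0, 1)
    is the asymmetry: intensity above the baseline is down-weighted by
    ``p`` so peaks do not pull the fit up.
    """
    if lam <= 0:
        raise ParameterError("lam must be positive")
    if not 0.0 < p < 1.0:
        raise ParameterError("p must lie strictly between 0 and 1")
    X = ds.intensities
    if not np.all(np.isfinite(X)):
        raise ParameterError("non-finite intensities; clean the data first")
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = X[i] - _als_baseline(X[i], lam, p, n_iter)
    return _record(ds, out, "baseline_correct",
                   {"lam": lam, "p": p, "n_iter": n_iter})


def normalize(ds: SpectraDataset, mode: str = "vector_norm") -> SpectraDataset:
    """Per-spectrum scaling: Euclidean norm 1, unit area, or unit maximum."""
    X = ds.intensities
    if mode == "vector_norm":
        denom = np.linalg.norm(X, axis=1)
    elif mode == "area":
        denom = X.sum(axis=1)
    elif mode == "max":
        denom = X.max(axis=1)
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        cid = ds.labels["cell_id"].iloc[zero[0]]
        raise ParameterError(
            f"cannot normalize all-zero spectrum (cell_id {cid!r})"
        )
    return _record(ds, X / denom[:, None], "normalize", {"mode": mode})


def resample(ds: SpectraDataset, target: WavenumberGrid) -> SpectraDataset:
    """Linear interpolation onto ``target``; extrapolation is refused."""
    src = ds.grid.values
    tgt = target.values
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise ParameterError(
            f"target grid [{tgt[0]}, {tgt[-1]}] extends beyond source "
            f"[{src[0]}, {src[-1]}]; extrapolation is not supported"
        )
    X = np.vstack([np.interp(tgt, src, row) for row in ds.intensities])
    return _record(ds, X, "resample",
                   {"n_channels": len(target)}, grid=target)


#: step name -> callable registry used by :func:`preprocess_pipeline`
STEP_REGISTRY = {
    "subtract_background": subtract_background,
    "smooth": smooth,
    "baseline_correct": baseline_correct,
    "normalize": normalize,
    "resample": resample,
}


def preprocess_pipeline(ds: SpectraDataset, config) -> SpectraDataset:
    """Apply an ordered list of steps, each ``{"step": name, **params}``.

    An empty list is the identity.  The applied steps are recorded in
    ``out.meta["preprocess_steps"]``.
    """
    out = ds
    for entry in config:
        if not isinstance(entry, dict) or "step" not in entry:
            raise ConfigError(f"each step must be a dict with a 'step' key, got {entry!r}")
        params = {k: v for k, v in entry.items() if k != "step"}
        name = entry["step"]
        fn = STEP_REGISTRY.get(name)
        if fn is None:
            raise ConfigError(
                f"unknown preprocessing step {name!r}; "
                f"known: {sorted(STEP_REGISTRY)}"
            )
        try:
            out = fn(out, **params)
        except TypeError as exc:
            raise ConfigError(f"bad parameters for step {name!r}: {exc}") from exc
    return out
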