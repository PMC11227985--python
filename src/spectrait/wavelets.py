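"""Continuous wavelet transform features for GPC-sensitive band selection.

A spectrum f(lambda) is decomposed against scaled/translated copies of a
Gaussian second-derivative ("Mexican hat") mother wavelet,

    psi_{a,b}(x) = a^{-1/2} psi((x - b) / a),
    W_f(a, b)    = sum_x f(x) psi_{a,b}(x),

evaluated densely: the translation b runs over every band position, so
each coefficient WF_{lambda,a} is directly comparable to the original band
at lambda.  The transform runs in band-index coordinates (uniform grid)
with symmetric-reflection boundary handling; scales default to {2,3,4,5}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import SpectrumSet

DEFAULT_SCALES = (2, 3, 4, 5)

#: half-width of the truncated mother-wavelet support, in units of the scale
#: (the Mexican hat is below 1e-12 beyond 8 standard widths)
SUPPORT_RADIUS_SCALES = 8.0


def mexican_hat(x: np.ndarray) -> np.ndarray:
    """L2-normalized Gaussian second derivative: (2/(sqrt(3) pi^{1/4}))
    (1 - x^2) exp(-x^2/2)."""
    x = np.asarray(x, dtype=float)
    c = 2.0 / (math.sqrt(3.0) * math.pi ** 0.25)
    return c * (1.0 - x * x) * np.exp(-x * x / 2.0)


@dataclass
class WaveletFeatureMatrix:
    """samples x (bands * scales) CWT coefficients with WF_{lambda,a} labels."""

    values: np.ndarray
    labels: list[str]
    wavelengths_nm: np.ndarray   # per column
    scales: np.ndarray           # per column
    edge_flags: np.ndarray       # per column: True if boundary-affected

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate WF labels")


@dataclass
class FeatureSubset:
    """An ordered selection of WF columns with their GPC correlations."""

    labels: list[str]
    correlations: np.ndarray
    provenance: str = "top-fraction"
    cv_mse_by_size: Optional[dict[int, float]] = None


def _reflect_pad(values: np.ndarray, pad: int) -> np.ndarray:
    """Symmetric (mirror-without-repeat) padding along the last axis."""
    return np.pad(values, [(0, 0)] * (values.ndim - 1) + [(pad, pad)], mode="reflect")


def cwt_spectrum(values: np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Dense CWT of spectra (last axis = bands) -> stacked per-scale blocks.

    Returns an array of shape (..., len(scales) * n_bands) ordered
    scale-major to match the label layout of :func:`cwt_transform`.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_bands = values.shape[-1]
    blocks = []
    for a in scales:
        if a <= 0:
            raise ValueError("scales must be positive")
        if a > n_bands / 2:
            warnings.warn(
                f"scale {a} exceeds half the band count ({n_bands}); "
                "coefficients are dominated by boundary reflection",
                RuntimeWarning,
            )
        half = int(math.ceil(SUPPORT_RADIUS_SCALES * a))
        offs = np.arange(-half, half + 1)
        kernel = mexican_hat(offs / a) / math.sqrt(a)
        padded = _reflect_pad(values, half)
        # coefficient at band b: sum_x f(x) psi((x-b)/a)/sqrt(a); the kernel is
        # symmetric so correlation and convolution coincide
        windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * half + 1, axis=-1)
        blocks.append(windows @ kernel)
    return np.concatenate(blocks, axis=-1)


def cwt_transform(
    spectrum_set: SpectrumSet, scales: Sequence[float] = DEFAULT_SCALES
) -> WaveletFeatureMatrix:
    """CWT feature matrix for every sample in a spectrum set."""
    if spectrum_set.n_bands < 8:
        raise ValueError("need at least 8 bands for a meaningful CWT")
    wl = spectrum_set.grid.wavelengths_nm
    n_bands = wl.size
    coeffs = cwt_spectrum(spectrum_set.spectra, scales)
    labels, col_wl, col_scale, edge = [], [], [], []
    for a in scales:
        half = int(math.ceil(SUPPORT_RADIUS_SCALES * a))
        for j in range(n_bands):
            labels.append(f"WF_{wl[j]:.0f}_{a:g}")
            col_wl.append(wl[j])
            col_scale.append(a)
            edge.append(j < half or j >= n_bands - half)
    return WaveletFeatureMatrix(
        coeffs, labels, np.array(col_wl), np.array(col_scale), np.array(edge)
    )


def feature_gpc_correlations(
    wf: WaveletFeatureMatrix, gpc: np.ndarray
) -> np.ndarray:
    """Pearson r between every WF column and GPC; constant columns -> 0."""
    gpc = np.asarray(gpc, dtype=float)
    if gpc.size < 3:
        raise ValueError("need at least 3 samples for correlations")
    if np.ptp(gpc) == 0:
        raise ValueError("GPC is constant; correlations undefined")
    X = wf.values
    xc = X - X.mean(axis=0)
    yc = gpc - gpc.mean()
    sx = np.sqrt((xc * xc).sum(axis=0))
    sy = math.sqrt(float(yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    return r


def select_top_fraction(
    wf: WaveletFeatureMatrix,
    correlations: np.ndarray,
    fraction: float = 0.05,
) -> FeatureSubset:
    """Keep the ceil(fraction * n) columns with largest |r|.

    Ties in |r| break by column (label) order, which makes the selection
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = math.ceil(fraction * len(wf.labels))
    # stable sort on -|r| preserves label order among ties
    order = np.argsort(-np.abs(correlations), kind="stable")[:n_keep]
    order = np.sort(order)  # report in label order
    return FeatureSubset(
        [wf.labels[i] for i in order],
        correlations[order],
        provenance=f"top-fraction({fraction})",
    )


def _cv_mse(X: np.ndarray, y: np.ndarray, make_estimator, cv: int, seed: int) -> float:
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    errs = []
    for tr, te in kf.split(X):
        est = make_estimator(X[tr].shape)
        est.fit(X[tr], y[tr])
        pred = np.asarray(est.predict(X[te])).ravel()
        errs.append(float(np.mean((y[te] - pred) ** 2)))
    return float(np.mean(errs))


def rfe_optimal_subset(
    wf: WaveletFeatureMatrix,
    candidates: FeatureSubset,
    y: np.ndarray,
    cv: int = 5,
    seed: int = 0,
    max_components: int = 10,
) -> FeatureSubset:
    """Recursive feature elimination with a PLSR backbone.

    Starting from the candidate set, the feature with the smallest absolute
    standardized coefficient is dropped one at a time; mean CV MSE is
    recorded at every size and the size minimizing it wins (ties -> the
    smaller subset).
    """
    from sklearn.cross_decomposition import PLSRegression

    if not candidates.labels:
        raise ValueError("empty candidate set")
    y = np.asarray(y, dtype=float)
    col_of = {lab: i for i, lab in enumerate(wf.labels)}
    active = [col_of[lab] for lab in candidates.labels]

    def make_estimator(shape):
        n, p = shape
        return PLSRegression(n_components=max(1, min(max_components, p, n - 1)),
                             scale=True)

    mse_by_size: dict[int, float] = {}
    sets_by_size: dict[int, list[int]] = {}
    while active:
        X = wf.values[:, active]
        mse_by_size[len(active)] = _cv_mse(X, y, make_estimator, cv, seed)
        sets_by_size[len(active)] = list(active)
        if len(active) == 1:
            break
        est = make_estimator(X.shape)
        est.fit(X, y)
        coef = np.asarray(est.coef_).reshape(-1)
        importance = np.abs(coef) * X.std(axis=0)
        drop = int(np.argmin(importance))  # argmin: first minimum on ties
        active.pop(drop)

    best_size = min(sorted(mse_by_size), key=lambda s: (mse_by_size[s], s))
    chosen = sorted(sets_by_size[best_size])
    corr = feature_gpc_correlations(wf, y)
    return FeatureSubset(
        [wf.labels[i] for i in chosen],
        corr[chosen],
        provenance="rfe",
        cv_mse_by_size=mse_by_size,
    )


def feature_matrix_for(wf: WaveletFeatureMatrix, subset: FeatureSubset) -> np.ndarray:
    """Column-restricted view of the WF matrix for a selected subset."""
    col_of = {lab: i for i, lab in enumerate(wf.labels)}
    return wf.values[:, [col_of[lab] for lab in subset.labels]]
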