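"""Fluctuation fingerprints: windowed Fourier spectra of WD series and PCA.

The WD vector of an atom measures, snapshot to snapshot, how much its
ring-polymer shape changed.  To characterize the *spectrum* of that
fluctuation, the series is cut into sliding windows of 2 * half_width + 1
entries, each window is mean-subtracted and discrete-Fourier transformed, and
the magnitudes of the nonnegative-frequency coefficients become one feature
vector per window.  A joint PCA over all windows (all atoms, all classes)
then yields low-dimensional scores in which atom populations with different
fluctuation dynamics separate.

All nonnegative-frequency magnitudes are kept by default; ``top_k`` restricts
the features to the k globally largest-magnitude coefficients.  The DFT is
unnormalized (numpy convention), so Parseval reads
sum_k |X_k|^2 = n * sum_t |x_t|^2 for a window of length n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .transport import WDVector

__all__ = [
    "SpectralFeatures",
    "PCAEmbedding",
    "fourier_features",
    "stack_features",
    "pca_embed",
    "separation_report",
    "SeparationReport",
]

DEFAULT_HALF_WIDTH = 20  # snapshots on each side of the window center
TARGET_VARIANCE = 0.90


@dataclass
class SpectralFeatures:
    """Per-window Fourier magnitudes of one atom's WD series.

    ``magnitudes`` has one row per sliding window and one column per retained
    nonnegative frequency; ``frequencies`` are in cycles per snapshot.
    """

    atom_id: int | None
    window_half_width: int
    frequencies: np.ndarray
    magnitudes: np.ndarray
    window_centers: np.ndarray
    class_label: str | None = None


@dataclass
class PCAEmbedding:
    """Joint PCA of stacked spectral features."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    labels: np.ndarray | None = None


def fourier_features(
    wd_vector: WDVector | np.ndarray,
    half_width: int = DEFAULT_HALF_WIDTH,
    hann: bool = False,
    top_k: int | None = None,
    class_label: str | None = None,
) -> SpectralFeatures:
    """Sliding-window DFT magnitudes of a WD series (stride 1).

    Each window of n = 2 * half_width + 1 entries is mean-subtracted (the
    baseline carries no fluctuation information), optionally Hann-tapered,
    and transformed; the magnitudes of the nonnegative-frequency coefficients
    form the feature vector.  Adding a constant to the series leaves the
    features unchanged.
    """
    if isinstance(wd_vector, WDVector):
        series, atom_id = wd_vector.entries, wd_vector.atom_id
    else:
        series, atom_id = np.asarray(wd_vector, dtype=float), None
    n = 2 * half_width + 1
    if half_width < 1 or series.size < n:
        raise ValueError(
            f"series of length {series.size} too short for window of {n}"
        )
    windows = sliding_window_view(series, n)
    centered = windows - windows.mean(axis=1, keepdims=True)
    if hann:
        centered = centered * np.hanning(n)
    mags = np.abs(np.fft.rfft(centered, axis=1))
    freqs = np.fft.rfftfreq(n)
    if top_k is not None:
        if not 1 <= top_k <= freqs.size:
            raise ValueError(f"top_k must be in 1..{freqs.size}")
        keep = np.sort(np.argsort(mags.mean(axis=0))[::-1][:top_k])
        mags, freqs = mags[:, keep], freqs[keep]
    return SpectralFeatures(
        atom_id=atom_id,
        window_half_width=half_width,
        frequencies=freqs,
        magnitudes=mags,
        window_centers=np.arange(windows.shape[0]) + half_width,
        class_label=class_label,
    )


def stack_features(
    features: list[SpectralFeatures],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-atom features into one (windows, frequencies) matrix plus the
    aligned class-label array (label ``""`` where unset)."""
    if not features:
        raise ValueError("no features to stack")
    widths = {f.magnitudes.shape[1] for f in features}
    if len(widths) != 1:
        raise ValueError("feature vectors differ in length across atoms")
    mat = np.vstack([f.magnitudes for f in features])
    labels = np.concatenate(
        [
            np.full(f.magnitudes.shape[0], f.class_label or "", dtype=object)
            for f in features
        ]
    )
    return mat, labels


def pca_embed(
    features: np.ndarray | list[SpectralFeatures],
    n_components: int | None = None,
    target_variance: float = TARGET_VARIANCE,
    labels: np.ndarray | None = None,
) -> PCAEmbedding:
    """Centered PCA over stacked feature vectors.

    When ``n_components`` is None the smallest component count whose
    cumulative explained variance reaches ``target_variance`` (default 90%)
    is used.  Raises on a zero-variance feature matrix.
    """
    if isinstance(features, list):
        mat, labels = stack_features(features)
    else:
        mat = np.asarray(features, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors")
    if np.allclose(mat.var(axis=0), 0.0):
        raise ValueError("zero-variance feature matrix; PCA is undefined")
    if n_components is None:
        # sklearn's fractional n_components picks the count reaching the target
        n_comp: float | int = min(target_variance, 1.0 - 1e-12)
    else:
        if not 1 <= n_components <= mat.shape[1]:
            raise ValueError("n_components must be in 1..feature length")
        n_comp = n_components
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(mat)
    return PCAEmbedding(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_,
        labels=labels,
    )


@dataclass
class SeparationReport:
    """How well class labels separate in PC space."""

    centroids: dict[str, np.ndarray]
    silhouette: float
    pc1_overlap: float
    pc1_iqr: dict[str, tuple[float, float]]


def separation_report(
    embedding: PCAEmbedding, labels: np.ndarray | None = None, n_bins: int = 50
) -> SeparationReport:
    """Per-class centroids, silhouette score, and PC1 marginal statistics.

    ``pc1_overlap`` is the overlap coefficient of the classes' normalized PC1
    histograms on shared bins (defined pairwise; for >2 classes the maximum
    pairwise overlap is reported).  Identical classes give silhouette ~ 0 and
    overlap ~ 1; well-separated classes give a positive silhouette and
    overlap ~ 0.  The report is invariant under renaming class labels.
    """
    labels = embedding.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("class labels are required")
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if np.sum(labels == cls) < 2:
            warnings.warn(f"class {cls!r} has fewer than 2 members", stacklevel=2)
    scores = embedding.scores
    centroids = {cls: scores[labels == cls].mean(axis=0) for cls in classes}
    sil = float(silhouette_score(scores, labels))
    pc1 = scores[:, 0]
    edges = np.linspace(pc1.min(), pc1.max() if pc1.max() > pc1.min() else pc1.min() + 1,
                        n_bins + 1)
    hists = {
        cls: np.histogram(pc1[labels == cls], bins=edges)[0]
        / max(int(np.sum(labels == cls)), 1)
        for cls in classes
    }
    overlap = max(
        float(np.minimum(hists[a], hists[b]).sum())
        for i, a in enumerate(classes)
        for b in classes[i + 1 :]
    )
    iqr = {
        cls: (
            float(np.percentile(pc1[labels == cls], 25)),
            float(np.percentile(pc1[labels == cls], 75)),
        )
        for cls in classes
    }
    return SeparationReport(
        centroids=centroids, silhouette=sil, pc1_overlap=overlap, pc1_iqr=iqr
    )


def scores_table(embedding: PCAEmbedding) -> pd.DataFrame:
    """PC scores (and labels when present) as a CSV-ready table."""
    cols = {f"pc{i + 1}": embedding.scores[:, i]
            for i in range(embedding.scores.shape[1])}
    df = pd.DataFrame(cols)
    if embedding.labels is not None:
        df["class"] = embedding.labels
    return df
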