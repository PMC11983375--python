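"""Imaging multivariate analysis: PCA, k-means, difference spectra, ion images.

PCA and k-means are complementary on hyperspectral SIMS images: k-means gives
a hard partition whose label image maps directly onto tissue features, while
PCA loadings split the variables into positive/negative sets that are simpler
to interpret chemically.  Cluster mean spectra are reported relative to the
overall mean ("difference spectra"), and candidate marker peaks are validated
by rendering single-ion images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .msio import CompositeImage
from .peaks import FeatureImage, PeakTable


def _as_feature_image(img: FeatureImage | CompositeImage) -> FeatureImage:
    return img.image if isinstance(img, CompositeImage) else img


def _require_normalized(fi: FeatureImage) -> None:
    if fi.normalized_flag != "sum1_sqrt":
        raise ValueError(
            f"multivariate analysis expects sum1_sqrt-normalized data, got {fi.normalized_flag!r}"
        )


@dataclass
class PcaModel:
    """Mean-centered PCA: orthonormal loadings, per-pixel scores as images."""

    loadings: np.ndarray          # components x centroids
    scores: np.ndarray            # pixels x components
    explained_variance: np.ndarray
    mean: np.ndarray
    shape: tuple[int, int]
    peak_table: PeakTable

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def score_image(self, component: int) -> np.ndarray:
        """Score image for a 1-based component index (PC1 = greatest variance)."""
        if not 1 <= component <= self.n_components:
            raise IndexError(f"component {component} out of range 1..{self.n_components}")
        return self.scores[:, component - 1].reshape(self.shape)


@dataclass
class ClusterModel:
    """k-means partition: one label per pixel plus cluster mean spectra."""

    k: int
    labels: np.ndarray
    means: np.ndarray             # k x centroids
    inertia: float
    seed: int
    shape: tuple[int, int]
    peak_table: PeakTable

    def label_image(self) -> np.ndarray:
        return self.labels.reshape(self.shape)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class DifferenceSpectra:
    """Cluster mean spectra minus the overall mean spectrum.

    Size-weighted differences sum to the zero vector.  ``display_inversion``
    flags clusters whose trace is sign-flipped when plotted; stored values are
    never inverted.
    """

    overall_mean: np.ndarray
    per_cluster: dict[int, np.ndarray]
    sizes: dict[int, int]
    display_inversion: dict[int, bool] = field(default_factory=dict)


def run_pca(
    img: FeatureImage | CompositeImage,
    n_components: int,
    fit_on: str = "all",
) -> PcaModel:
    """Mean-centered PCA of a normalized image (no variance scaling).

    ``fit_on='all'`` fits on every canvas pixel including zero-filled
    substrate, so PC1 typically captures tissue versus substrate;
    ``fit_on='tissue'`` fits on masked-in pixels only and scores the rest
    through the same model.
    """
    fi = _as_feature_image(img)
    _require_normalized(fi)
    X = fi.matrix
    fit_idx = np.flatnonzero(fi.mask) if fit_on == "tissue" else np.arange(X.shape[0])
    if fit_on not in ("all", "tissue"):
        raise ValueError(f"fit_on must be 'all' or 'tissue', got {fit_on!r}")
    max_comp = min(len(fit_idx), X.shape[1])
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(pixels, centroids)={max_comp}")

    if np.allclose(X[fit_idx].var(axis=0), 0.0):
        warnings.warn("constant image: PCA has no variance to explain", stacklevel=2)
        return PcaModel(
            loadings=np.empty((0, X.shape[1])),
            scores=np.empty((X.shape[0], 0)),
            explained_variance=np.empty(0),
            mean=X[fit_idx].mean(axis=0),
            shape=fi.shape,
            peak_table=fi.peak_table,
        )

    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X[fit_idx])
    loadings = pca.components_.copy()
    # deterministic sign: the largest-|loading| channel of each PC is positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = (X - pca.mean_) @ loadings.T
    return PcaModel(
        loadings=loadings,
        scores=scores,
        explained_variance=pca.explained_variance_.copy(),
        mean=pca.mean_.copy(),
        shape=fi.shape,
        peak_table=fi.peak_table,
    )


def run_kmeans(
    img: FeatureImage | CompositeImage,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """k-means over all canvas pixels (zero-filled substrate included).

    With the substrate left in, one cluster trivially captures it, matching
    the three-cluster substrate/healthy/cancer reading of a two-condition
    composite.  Deterministic under a fixed seed.
    """
    fi = _as_feature_image(img)
    _require_normalized(fi)
    X = fi.matrix
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds pixel count {X.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(X)
    means = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterModel(
        k=k,
        labels=labels,
        means=means,
        inertia=float(km.inertia_),
        seed=seed,
        shape=fi.shape,
        peak_table=fi.peak_table,
    )


def kmeans_sweep(
    img: FeatureImage | CompositeImage,
    ks=range(3, 11),
    seed: int = 0,
) -> dict[int, ClusterModel]:
    """Run k-means for each k in ``ks`` (3..10 by default)."""
    return {int(k): run_kmeans(img, int(k), seed=seed) for k in ks}


def difference_spectra(
    model: ClusterModel, img: FeatureImage | CompositeImage
) -> DifferenceSpectra:
    """Subtract the overall mean spectrum from each cluster mean spectrum."""
    fi = _as_feature_image(img)
    X = fi.matrix
    if model.labels.shape != (X.shape[0],):
        raise ValueError("cluster model was not fit on this image")
    overall = X.mean(axis=0)
    per_cluster = {}
    sizes = {}
    for c in range(model.k):
        sel = model.labels == c
        sizes[c] = int(sel.sum())
        per_cluster[c] = (X[sel].mean(axis=0) - overall) if sizes[c] else np.zeros(X.shape[1])
    return DifferenceSpectra(overall_mean=overall, per_cluster=per_cluster, sizes=sizes)


def ion_image(img: FeatureImage | CompositeImage, mz: float, tol: float = 0.1) -> np.ndarray:
    """Render the centroid channel nearest to ``mz`` (within ``tol``) as a 2-D image.

    Ties between two equidistant centroids go to the lower m/z.
    """
    fi = _as_feature_image(img)
    centers = fi.peak_table.mz_center
    if len(centers) == 0:
        raise ValueError("image has no centroids")
    d = np.abs(centers - mz)
    j = int(np.argmin(d))  # argmin returns the first (lower-m/z) minimum on ties
    if d[j] > tol:
        raise ValueError(
            f"no centroid within {tol} of m/z {mz}; nearest is {centers[j]:.4f} (delta {d[j]:.4f})"
        )
    return fi.image(j)


def loading_report(model: PcaModel, component: int, top_n: int) -> pd.DataFrame:
    """Top-N most positive and most negative loading peaks of one component."""
    if not 1 <= component <= model.n_components:
        raise IndexError(f"component {component} out of range 1..{model.n_components}")
    v = model.loadings[component - 1]
    centers = model.peak_table.mz_center
    if top_n > len(centers):
        warnings.warn(
            f"top_n={top_n} exceeds centroid count {len(centers)}; truncating", stacklevel=2
        )
        top_n = len(centers)
    order = np.argsort(v)
    neg = [i for i in order[:top_n] if v[i] < 0]
    pos = [i for i in order[::-1][:top_n] if v[i] > 0]
    rows = [
        {"mz_center": float(centers[i]), "loading": float(v[i]), "sign": "positive"}
        for i in pos
    ] + [
        {"mz_center": float(centers[i]), "loading": float(v[i]), "sign": "negative"}
        for i in neg
    ]
    return pd.DataFrame(rows, columns=["mz_center", "loading", "sign"])
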