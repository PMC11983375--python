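"""Per-pixel normalization and substrate (ITO slide) masking.

Every pixel's peak-intensity vector is sum-normalized to 1 and square-rooted
(a variance-stabilizing transform for counting data).  Pixels dominated by the
bare conductive slide are detected with a 2-cluster k-means mask — the cluster
with lower mean raw TIC is the substrate — and zero-filled before multivariate
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .peaks import FeatureImage

logger = logging.getLogger(__name__)


class StageError(ValueError):
    """Raised when an operation is applied at the wrong processing stage."""


@dataclass
class MaskResult:
    """Outcome of k=2 substrate detection.

    ``mask`` is True for tissue pixels; ``substrate_cluster`` names the
    zero-filled cluster; ``diagnostics`` holds per-cluster mean TIC.
    """

    mask: np.ndarray
    method: str
    cluster_assignment: np.ndarray
    substrate_cluster: int
    diagnostics: dict[int, float]


def normalize_pixels(img: FeatureImage) -> FeatureImage:
    """Sum-normalize each pixel row to 1, then take the element-wise square root.

    All-zero rows are left zero and counted.  The output row of any nonzero
    pixel has unit sum of squares.
    """
    if img.normalized_flag != "raw":
        raise StageError(
            f"normalize_pixels expects a raw image, got stage {img.normalized_flag!r}"
        )
    out = img.copy()
    sums = out.matrix.sum(axis=1)
    nonzero = sums > 0
    n_empty = int((~nonzero).sum())
    if n_empty:
        logger.info("normalize_pixels: %d all-zero pixels left untouched", n_empty)
    out.matrix[nonzero] = np.sqrt(out.matrix[nonzero] / sums[nonzero, None])
    out.normalized_flag = "sum1_sqrt"
    return out


def substrate_mask(
    img: FeatureImage,
    tic: np.ndarray | None = None,
    seed: int = 0,
    n_init: int = 10,
) -> MaskResult:
    """Partition pixels into tissue/substrate with k-means (k=2).

    Clustering runs on the image's current feature space (raw or normalized);
    the substrate label goes to the cluster with lower mean raw TIC, supplied
    via ``tic`` (falling back to current row sums), so the labeling does not
    depend on arbitrary cluster indices.
    """
    X = img.matrix
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("degenerate clustering input: fewer than 2 distinct pixel profiles")
    tic = np.asarray(tic, float) if tic is not None else X.sum(axis=1)
    if tic.shape != (X.shape[0],):
        raise ValueError("tic vector length must equal pixel count")
    km = KMeans(n_clusters=2, random_state=seed, n_init=n_init)
    assignment = km.fit_predict(X)
    means = {c: float(tic[assignment == c].mean()) for c in (0, 1)}
    substrate = min(means, key=lambda c: (means[c], c))
    return MaskResult(
        mask=assignment != substrate,
        method="kmeans2",
        cluster_assignment=assignment,
        substrate_cluster=substrate,
        diagnostics=means,
    )


def apply_mask(img: FeatureImage, mask: MaskResult | np.ndarray) -> FeatureImage:
    """Zero-fill substrate pixels and record the mask on the image."""
    m = mask.mask if isinstance(mask, MaskResult) else np.asarray(mask, bool)
    if m.shape != (img.n_pixels,):
        raise ValueError(
            f"mask length {m.shape} does not match pixel count {img.n_pixels}"
        )
    out = img.copy()
    out.matrix[~m] = 0.0
    out.mask = m.copy()
    return out
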