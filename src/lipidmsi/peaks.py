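"""Peak picking, centroiding, and feature-image construction.

Averaged TIC-normalized spectra are peak-picked with a second-derivative
algorithm: Gaussian smoothing, a smoothed (Savitzky-Golay) second derivative,
removal of positive derivative values, negation, and detection of local maxima.
Each contiguous non-zero feature of the processed derivative becomes one
centroid with an integration window; unresolved isobaric peaks that share a
feature collapse into a single merged centroid.  Peaks are picked separately in
configurable m/z ranges (dual tables at m/z 590-800 and 800-1190 by default)
and combined into one ascending table, which is then used to centroid every
pixel of an image into a pixels x peaks intensity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

if TYPE_CHECKING:  # pragma: no cover
    from .msio import SpectralImageCube

logger = logging.getLogger(__name__)

DEFAULT_RANGES = ((590.0, 800.0), (800.0, 1190.0))


@dataclass(frozen=True)
class PickerParams:
    """Parameters of the second-derivative peak picker.

    gaussian_sigma : width (in m/z) of the Gaussian pre-smoothing kernel.
    deriv_window   : odd sample count of the Savitzky-Golay window used for
                     the smoothed second derivative.
    n_keep         : number of most-intense centroids retained per mass range.
    ranges         : non-overlapping, ascending (lo, hi) m/z intervals.
    grid_step      : m/z spacing of the uniform resampling grid.
    """

    gaussian_sigma: float = 0.02
    deriv_window: int = 7
    n_keep: int = 300
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES
    grid_step: float = 0.005

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.deriv_window < 3 or self.deriv_window % 2 == 0:
            raise ValueError("deriv_window must be odd and >= 3")
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        rs = sorted(self.ranges)
        for (a, b) in rs:
            if b <= a:
                raise ValueError(f"empty m/z range ({a}, {b})")
        for (_, b), (c, _) in zip(rs, rs[1:]):
            if c < b:
                raise ValueError("ranges overlap")

    def grid(self) -> np.ndarray:
        lo = min(a for a, _ in self.ranges)
        hi = max(b for _, b in self.ranges)
        n = int(round((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)


@dataclass
class PeakTable:
    """Centroided peak list with half-open integration windows [lo, hi)."""

    mz_center: np.ndarray
    window_lo: np.ndarray
    window_hi: np.ndarray
    apex_intensity: np.ndarray
    merged_flag: np.ndarray

    def __post_init__(self) -> None:
        self.mz_center = np.asarray(self.mz_center, float)
        self.window_lo = np.asarray(self.window_lo, float)
        self.window_hi = np.asarray(self.window_hi, float)
        self.apex_intensity = np.asarray(self.apex_intensity, float)
        self.merged_flag = np.asarray(self.merged_flag, bool)
        self.validate()

    def validate(self) -> None:
        c, lo, hi = self.mz_center, self.window_lo, self.window_hi
        if not (len(c) == len(lo) == len(hi) == len(self.apex_intensity) == len(self.merged_flag)):
            raise ValueError("peak table columns have unequal lengths")
        if len(c) == 0:
            return
        if np.any(np.diff(c) <= 0):
            raise ValueError("centroids must be strictly ascending")
        if np.any((lo >= c) | (c >= hi)):
            raise ValueError("each window must satisfy lo < mz_center < hi")
        if np.any(hi[:-1] > lo[1:] + 1e-12):
            raise ValueError("integration windows overlap")

    def __len__(self) -> int:
        return len(self.mz_center)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz_center": self.mz_center,
                "window_lo": self.window_lo,
                "window_hi": self.window_hi,
                "apex_intensity": self.apex_intensity,
                "merged_flag": self.merged_flag.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        df = pd.read_csv(path)
        return cls(
            df["mz_center"].to_numpy(),
            df["window_lo"].to_numpy(),
            df["window_hi"].to_numpy(),
            df["apex_intensity"].to_numpy(),
            df["merged_flag"].to_numpy().astype(bool),
        )

    @classmethod
    def empty(cls) -> "PeakTable":
        z = np.empty(0)
        return cls(z, z, z, z, np.empty(0, bool))

    def equivalent(self, other: "PeakTable", tol: float = 1e-9) -> bool:
        if len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        return bool(
            np.allclose(self.mz_center, other.mz_center, atol=tol)
            and np.allclose(self.window_lo, other.window_lo, atol=tol)
            and np.allclose(self.window_hi, other.window_hi, atol=tol)
        )


@dataclass
class FeatureImage:
    """Pixels x centroids intensity matrix on a rectangular pixel canvas.

    ``matrix`` rows are row-major over ``shape``; ``mask`` marks tissue pixels
    (False rows are zero-filled); ``normalized_flag`` records the processing
    stage: ``raw`` -> ``sum1_sqrt`` (per-pixel sum-normalized then square-rooted).
    """

    peak_table: PeakTable
    matrix: np.ndarray
    shape: tuple[int, int]
    mask: np.ndarray | None = None
    normalized_flag: str = "raw"
    sample_id: str = ""
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n_rows, n_cols = self.shape
        if self.matrix.shape != (n_rows * n_cols, len(self.peak_table)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with canvas "
                f"{self.shape} and {len(self.peak_table)} centroids"
            )
        if self.mask is None:
            self.mask = np.ones(self.matrix.shape[0], bool)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != (self.matrix.shape[0],):
            raise ValueError("mask length must equal pixel count")
        if self.normalized_flag not in ("raw", "sum1", "sum1_sqrt"):
            raise ValueError(f"unknown stage flag {self.normalized_flag!r}")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    def tic(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def image(self, j: int) -> np.ndarray:
        """Render centroid column *j* on the pixel canvas."""
        return self.matrix[:, j].reshape(self.shape)

    def copy(self) -> "FeatureImage":
        return replace(self, matrix=self.matrix.copy(), mask=self.mask.copy())


# ---------------------------------------------------------------------------
# averaged spectra


def mean_tic_spectrum(cube: "SpectralImageCube", grid: np.ndarray) -> np.ndarray:
    """Average of per-pixel TIC-normalized spectra resampled onto ``grid``.

    Each pixel spectrum is linearly interpolated onto the common m/z grid,
    divided by its total (resampled) ion current, and averaged across pixels.
    Pixels with zero TIC are excluded from the average and counted.
    """
    grid = np.asarray(grid, float)
    total = np.zeros_like(grid)
    n_used = 0
    n_skipped = 0
    for mz, inten in cube.spectra():
        res = np.interp(grid, mz, inten, left=0.0, right=0.0)
        tic = res.sum()
        if tic <= 0:
            n_skipped += 1
            continue
        total += res / tic
        n_used += 1
    if n_skipped:
        logger.info("mean_tic_spectrum: excluded %d zero-TIC pixels", n_skipped)
    if n_used == 0:
        raise ValueError("all pixels have zero TIC")
    return total / n_used


# ---------------------------------------------------------------------------
# second-derivative picker


def _processed_second_derivative(
    intensity: np.ndarray, step: float, params: PickerParams
) -> np.ndarray:
    """Negated, positive-clipped smoothed second derivative (>= 0 everywhere)."""
    sigma_samples = params.gaussian_sigma / step
    smoothed = gaussian_filter1d(np.asarray(intensity, float), sigma_samples)
    d2 = savgol_filter(smoothed, params.deriv_window, polyorder=2, deriv=2, delta=step)
    d2 = np.where(d2 > 0, 0.0, d2)
    return -d2


def _segments(proc: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous index runs where ``proc`` > 0, as inclusive (start, stop)."""
    idx = np.flatnonzero(proc > 0)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(a), int(b)) for a, b in zip(starts, stops)]


def _n_local_maxima(y: np.ndarray) -> int:
    if len(y) < 3:
        return 1 if len(y) else 0
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    n = int(interior.sum())
    return max(n, 1)


def pick_peaks(grid: np.ndarray, intensity: np.ndarray, params: PickerParams) -> PeakTable:
    """Pick and centroid peaks on a uniform-grid spectrum.

    Pipeline: Gaussian smoothing -> smoothed second derivative -> clip positive
    values to zero -> negate -> every contiguous positive feature becomes one
    centroid (weighted by the processed derivative), with its window spanning
    the feature.  Within each range of ``params.ranges`` the ``n_keep`` highest
    apex-intensity centroids are retained; apex ties break toward lower m/z.
    """
    grid = np.asarray(grid, float)
    intensity = np.asarray(intensity, float)
    if len(grid) != len(intensity):
        raise ValueError("grid and intensity lengths differ")
    if len(grid) < params.deriv_window:
        raise ValueError(
            f"spectrum ({len(grid)} samples) shorter than deriv_window ({params.deriv_window})"
        )
    step = float(np.median(np.diff(grid)))
    proc = _processed_second_derivative(intensity, step, params)

    rows = []
    for i0, i1 in _segments(proc):
        w = proc[i0 : i1 + 1]
        seg_grid = grid[i0 : i1 + 1]
        center = float(np.dot(seg_grid, w) / w.sum())
        lo = grid[i0] - step / 2.0
        hi = grid[i1] + step / 2.0
        apex = float(intensity[i0 : i1 + 1].max())
        merged = _n_local_maxima(w) >= 2
        rows.append((center, lo, hi, apex, merged))

    kept: list[tuple[float, float, float, float, bool]] = []
    for rlo, rhi in params.ranges:
        in_range = [r for r in rows if rlo <= r[0] < rhi]
        in_range.sort(key=lambda r: (-r[3], r[0]))
        for center, lo, hi, apex, merged in in_range[: params.n_keep]:
            # clip windows to the range so dual-range tables never overlap
            kept.append((center, max(lo, rlo), min(hi, rhi), apex, merged))

    kept.sort(key=lambda r: r[0])
    if not kept:
        return PeakTable.empty()
    arr = np.array([r[:4] for r in kept], float)
    return PeakTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], np.array([r[4] for r in kept]))


def build_peak_tables(
    mean_spectra: Sequence[np.ndarray], grid: np.ndarray, params: PickerParams
) -> PeakTable:
    """Grand-mean the per-image averaged spectra and pick one combined table.

    Peaks are picked per range and the per-range tables concatenated into a
    single ascending table covering the full analysis range.
    """
    if len(mean_spectra) == 0:
        raise ValueError("no mean spectra provided")
    stack = np.vstack([np.asarray(s, float) for s in mean_spectra])
    if stack.shape[1] != len(grid):
        raise ValueError("mean spectra are not on the provided grid")
    grand = stack.mean(axis=0)
    return pick_peaks(grid, grand, params)


# ---------------------------------------------------------------------------
# centroiding of images


def centroid_image(cube: "SpectralImageCube", table: PeakTable) -> FeatureImage:
    """Integrate every pixel spectrum over the table's half-open windows.

    The intensity of centroid *j* in a pixel is the sum of that pixel's
    spectral intensity in [window_lo_j, window_hi_j).
    """
    shape = cube.layout.shape
    n_rows, n_cols = shape
    matrix = np.zeros((n_rows * n_cols, len(table)))
    present = np.zeros(n_rows * n_cols, bool)
    for (row, col), (mz, inten) in zip(cube.coords, cube.spectra()):
        idx = row * n_cols + col
        present[idx] = True
        if len(table) == 0:
            continue
        csum = np.concatenate(([0.0], np.cumsum(inten)))
        lo_idx = np.searchsorted(mz, table.window_lo, side="left")
        hi_idx = np.searchsorted(mz, table.window_hi, side="left")
        matrix[idx] = csum[hi_idx] - csum[lo_idx]
    return FeatureImage(
        peak_table=table,
        matrix=matrix,
        shape=shape,
        mask=present,
        normalized_flag="raw",
        sample_id=cube.sample_id,
        condition=cube.condition,
    )
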