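"""MSI input/output, mosaic tile geometry, and composite-image assembly.

Images are acquired in tiled/mosaic mode (e.g. 900 um x 900 um tiles at a
128 x 128 pixel raster); multiple sample images are combined into one
composite canvas for joint multivariate analysis.  imzML (+ .ibd) is the sole
on-disk spectral format; inputs are assumed mass-calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .peaks import FeatureImage, PeakTable


class FormatError(ValueError):
    """Raised when an on-disk file is malformed."""


@dataclass(frozen=True)
class TileLayout:
    """Regular mosaic geometry: square tiles on a rows x cols grid.

    Pixel indices are 0-based, row-major, origin top-left; physical
    coordinates refer to pixel centers.
    """

    tile_edge_um: float
    raster_px: int
    mosaic_rows: int = 1
    mosaic_cols: int = 1
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.tile_edge_um <= 0:
            raise ValueError("tile_edge_um must be > 0")
        if self.raster_px < 2:
            raise ValueError("raster_px must be >= 2")
        if self.mosaic_rows < 1 or self.mosaic_cols < 1:
            raise ValueError("mosaic dimensions must be >= 1")

    @property
    def pixel_size(self) -> float:
        return self.tile_edge_um / self.raster_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.mosaic_rows * self.raster_px, self.mosaic_cols * self.raster_px)

    @property
    def n_pixels(self) -> int:
        r, c = self.shape
        return r * c


class PixelSize(NamedTuple):
    exact_um: float
    nearest_um: int


def pixel_size_um(tile_edge_um: float, raster_px: float) -> PixelSize:
    """Physical pixel size of a tile, exact and rounded to the nearest micron.

    A 900 um tile at a 128-pixel raster gives 7.03125 um, i.e. a nominal
    7 um pixel.
    """
    if tile_edge_um <= 0 or raster_px <= 0:
        raise ValueError("tile edge and raster size must both be > 0")
    exact = tile_edge_um / raster_px
    return PixelSize(exact, int(math.floor(exact + 0.5)))


@dataclass
class SpectralImageCube:
    """Pixel grid of mass spectra with mosaic geometry and sample labels.

    ``coords`` holds 0-based (row, col) pixel positions; ``mzs[i]`` /
    ``intensities[i]`` are the paired spectrum arrays of pixel i (m/z strictly
    ascending, intensities non-negative).  Per-pixel m/z axes may differ
    (processed-mode data) or be shared (continuous mode).
    """

    layout: TileLayout
    coords: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    mz_range: tuple[float, float]
    sample_id: str = ""
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, int).reshape(-1, 2)
        self.validate()

    def validate(self) -> None:
        n = len(self.coords)
        if not (len(self.mzs) == len(self.intensities) == n):
            raise ValueError("coords, mzs and intensities must have equal length")
        rows, cols = self.layout.shape
        if n:
            if self.coords.min() < 0 or np.any(self.coords[:, 0] >= rows) or np.any(
                self.coords[:, 1] >= cols
            ):
                raise ValueError("pixel coordinate outside layout bounds")
            flat = self.coords[:, 0] * cols + self.coords[:, 1]
            if len(np.unique(flat)) != n:
                raise ValueError("duplicate pixel coordinates")
        for i, (mz, inten) in enumerate(zip(self.mzs, self.intensities)):
            if len(mz) != len(inten):
                raise ValueError(f"pixel {i}: m/z and intensity lengths differ")
            if len(mz) > 1 and np.any(np.diff(mz) <= 0):
                raise ValueError(f"pixel {i}: m/z axis not strictly increasing")
            if len(inten) and float(np.min(inten)) < 0:
                raise ValueError(f"pixel {i}: negative intensity")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def spectra(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        yield from zip(self.mzs, self.intensities)

    def total_intensity(self) -> float:
        return float(sum(inten.sum() for inten in self.intensities))

    def split_tiles(self) -> list["SpectralImageCube"]:
        """Split a mosaic cube into one single-tile cube per mosaic cell."""
        out = []
        r = self.layout.raster_px
        for tr in range(self.layout.mosaic_rows):
            for tc in range(self.layout.mosaic_cols):
                sel = (
                    (self.coords[:, 0] // r == tr)
                    & (self.coords[:, 1] // r == tc)
                )
                idx = np.flatnonzero(sel)
                if idx.size == 0:
                    continue
                sub_layout = TileLayout(self.layout.tile_edge_um, r)
                out.append(
                    SpectralImageCube(
                        layout=sub_layout,
                        coords=self.coords[idx] - [tr * r, tc * r],
                        mzs=[self.mzs[i] for i in idx],
                        intensities=[self.intensities[i] for i in idx],
                        mz_range=self.mz_range,
                        sample_id=f"{self.sample_id}/tile{tr}_{tc}" if self.sample_id else f"tile{tr}_{tc}",
                        condition=self.condition,
                    )
                )
        return out


# ---------------------------------------------------------------------------
# imzML


def write_imzml(cube: SpectralImageCube, path) -> None:
    """Write a cube to imzML/.ibd (processed mode, float64 m/z, float32 counts)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    if cube.n_pixels == 0:
        raise ValueError("no pixels to write")
    polarity = "negative"
    with ImzMLWriter(
        str(path), polarity=polarity, mz_dtype=np.float64, intensity_dtype=np.float32
    ) as w:
        for (row, col), (mz, inten) in zip(cube.coords, cube.spectra()):
            # imzML coordinates are 1-based (x, y, z)
            w.addSpectrum(mz, inten, (int(col) + 1, int(row) + 1, 1))


def read_imzml(path, layout: TileLayout | None = None) -> SpectralImageCube:
    """Read an imzML file (continuous or processed mode) into a cube.

    When no layout is given, a single-tile layout is inferred from the pixel
    extent, using the imzML pixel-size metadata when present (1 um otherwise).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML, missing .ibd companion, ...
        raise FormatError(f"cannot read imzML file {path}: {exc}") from exc

    coords = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        coords.append((int(y) - 1, int(x) - 1))
        mzs.append(np.asarray(mz, float))
        intens.append(np.asarray(inten, float))
    if not coords:
        raise FormatError(f"imzML file {path} contains no spectra")

    carr = np.asarray(coords, int)
    if layout is None:
        extent = int(carr.max()) + 1
        px = float(parser.imzmldict.get("pixel size x", 1.0) or 1.0)
        layout = TileLayout(tile_edge_um=px * extent, raster_px=max(extent, 2))
    lo = min(float(m[0]) for m in mzs if len(m))
    hi = max(float(m[-1]) for m in mzs if len(m))
    return SpectralImageCube(
        layout=layout,
        coords=carr,
        mzs=mzs,
        intensities=intens,
        mz_range=(lo, hi),
    )


# ---------------------------------------------------------------------------
# composite assembly


@dataclass
class CompositeImage:
    """Several sample FeatureImages packed side by side on one canvas.

    ``image`` is the combined canvas; ``member_of`` maps each canvas pixel to a
    member index (-1 for filler pixels outside every member), ``local_index``
    to the pixel's row-major index within its member.
    """

    members: list[tuple[str, str]]
    image: FeatureImage
    offsets: dict[str, tuple[int, int, int, int]]
    member_of: np.ndarray
    local_index: np.ndarray

    @property
    def n_member_pixels(self) -> int:
        return int((self.member_of >= 0).sum())

    def canvas_to_member(self, canvas_idx: int) -> tuple[str, int]:
        m = int(self.member_of[canvas_idx])
        if m < 0:
            raise KeyError(f"canvas pixel {canvas_idx} belongs to no member")
        return self.members[m][0], int(self.local_index[canvas_idx])

    def member_to_canvas(self, sample_id: str, local_idx: int) -> int:
        row_off, col_off, rows, cols = self.offsets[sample_id]
        r, c = divmod(int(local_idx), cols)
        _, canvas_cols = self.image.shape
        return (row_off + r) * canvas_cols + (col_off + c)

    def manifest(self) -> pd.DataFrame:
        recs = []
        for sid, cond in self.members:
            row_off, col_off, rows, cols = self.offsets[sid]
            recs.append(
                {
                    "sample_id": sid,
                    "condition": cond,
                    "row_offset": row_off,
                    "col_offset": col_off,
                    "rows": rows,
                    "cols": cols,
                }
            )
        return pd.DataFrame(recs)


def assemble_composite(members: Iterable[FeatureImage]) -> CompositeImage:
    """Pack member images side by side (row-packed, member order) on one canvas.

    All members must share an identical peak table; every member pixel appears
    exactly once on the canvas and a reverse map canvas->member is built.
    """
    members = list(members)
    if not members:
        raise ValueError("no members to assemble")
    table = members[0].peak_table
    for m in members[1:]:
        if not table.equivalent(m.peak_table):
            a = set(np.round(table.mz_center, 6))
            b = set(np.round(m.peak_table.mz_center, 6))
            diff = sorted(a.symmetric_difference(b))
            raise ValueError(
                f"peak-table mismatch between members (differing centroids: {diff[:10]})"
            )

    canvas_rows = max(m.shape[0] for m in members)
    canvas_cols = sum(m.shape[1] for m in members)
    n = canvas_rows * canvas_cols
    matrix = np.zeros((n, len(table)))
    mask = np.zeros(n, bool)
    member_of = np.full(n, -1, int)
    local_index = np.full(n, -1, int)
    offsets: dict[str, tuple[int, int, int, int]] = {}
    labels: list[tuple[str, str]] = []

    col_off = 0
    flags = {m.normalized_flag for m in members}
    if len(flags) != 1:
        raise ValueError(f"members at mixed processing stages: {sorted(flags)}")
    for mi, m in enumerate(members):
        rows, cols = m.shape
        sid = m.sample_id or f"member{mi}"
        labels.append((sid, m.condition))
        offsets[sid] = (0, col_off, rows, cols)
        for r in range(rows):
            canvas_start = r * canvas_cols + col_off
            local_start = r * cols
            sl = slice(canvas_start, canvas_start + cols)
            matrix[sl] = m.matrix[local_start : local_start + cols]
            mask[sl] = m.mask[local_start : local_start + cols]
            member_of[sl] = mi
            local_index[sl] = np.arange(local_start, local_start + cols)
        col_off += cols

    image = FeatureImage(
        peak_table=table,
        matrix=matrix,
        shape=(canvas_rows, canvas_cols),
        mask=mask,
        normalized_flag=flags.pop(),
        sample_id="composite",
    )
    return CompositeImage(
        members=labels,
        image=image,
        offsets=offsets,
        member_of=member_of,
        local_index=local_index,
    )
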