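"""Synthetic mosaic MSI scenes with ground truth.

Generates negative-ion lipid imaging data that mimics the statistical
structure of a lymph-node cohort: tissue regions (healthy lymphoid, DLBCL, an
aggressive sulfatide-rich DLBCL sub-region, histiocyte pockets, connective
tissue) sitting on a low-signal ITO substrate.  Each region has a lipid
abundance profile; every species contributes a Gaussian line at its [M-H]-
m/z (plus an isotopologue envelope, so e.g. the M+2 isotope of PI 38:4
interferes with PI 38:3), scaled by abundance x mean pixel TIC, and counts are
drawn per pixel from a Poisson model.  Ground-truth region labels and true
peak areas accompany every cube, so pipeline recovery can be scored without
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import annotation
from .annotation import IonType, LipidSpecies, load_lipid_table, monoisotopic_mass, mz_of
from .msio import SpectralImageCube, TileLayout

NEUTRON_SPACING = 1.00336  # mean isotopologue spacing for CHNOPS lipids, Da

#: (isotope nucleon shift, natural abundance) per element; the zero-shift
#: entry is the most abundant isotope
_ISOTOPES: dict[str, list[tuple[int, float]]] = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "P": [(0, 1.0)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "Na": [(0, 1.0)],
    "K": [(0, 0.932581), (1, 0.000117), (2, 0.067302)],
}


def _element_poly(element: str, n_atoms: int, n_keep: int) -> np.ndarray:
    """Probability of a total nucleon shift j over ``n_atoms`` atoms (binomial/multinomial convolution)."""
    base = np.zeros(n_keep)
    for shift, ab in _ISOTOPES[element]:
        if shift < n_keep:
            base[shift] += ab
    out = np.zeros(n_keep)
    out[0] = 1.0
    power = base
    n = n_atoms
    while n:  # binary exponentiation under truncated convolution
        if n & 1:
            out = np.convolve(out, power)[:n_keep]
        n >>= 1
        if n:
            power = np.convolve(power, power)[:n_keep]
    return out


def isotope_envelope(formula: str, n_isotopes: int = 3) -> list[tuple[float, float]]:
    """Aggregated isotopologue envelope of a formula.

    Returns ``n_isotopes`` pairs (m/z offset from the monoisotopic peak,
    absolute abundance).  Offsets are j * 1.00336; abundances come from the
    convolution of per-element natural isotope frequencies and sum to <= 1.
    """
    comp = annotation.parse_formula(formula)
    probs = np.zeros(n_isotopes)
    probs[0] = 1.0
    for el, n in comp.items():
        if el not in _ISOTOPES:
            raise ValueError(f"unknown element {el!r}")
        probs = np.convolve(probs, _element_poly(el, n, n_isotopes))[:n_isotopes]
    return [(j * NEUTRON_SPACING, float(p)) for j, p in enumerate(probs)]


# ---------------------------------------------------------------------------
# region profiles

REGION_TYPES = (
    "substrate",
    "healthy_lymphoid",
    "dlbcl",
    "dlbcl_aggressive",
    "histiocyte",
    "connective",
)

#: coarse 3-way grouping used for substrate/healthy/cancer recovery scoring
THREE_WAY_GROUP = {
    "substrate": 0,
    "healthy_lymphoid": 1,
    "histiocyte": 1,
    "connective": 1,
    "dlbcl": 2,
    "dlbcl_aggressive": 2,
}

#: species elevated in healthy lymphoid tissue (composite PC2 positive set)
HEALTHY_SPECIES = (
    "PI 38:4", "PI 36:4", "PS 38:3", "PS 38:4", "PS 36:1", "PE 38:4",
    "PE O-38:5", "PA 40:5", "PE 36:4", "PE O-36:5", "LPI 20:4", "LPI 18:0",
)

#: species elevated in DLBCL tissue (composite PC2 negative set)
CANCER_SPECIES = (
    "NeuAcHex2Cer 34:1;O2", "SHex2Cer 42:2", "PI 40:3", "PI 40:4", "PI 40:6",
    "PI 38:2", "PI 38:3", "PI 36:1", "PI 36:2", "PI 36:3", "PI 34:1",
    "PS 36:2", "PG 36:1", "PG 36:2", "PG 34:1", "PE 36:1", "PE 36:2",
    "PE 36:3", "PE 34:1", "PE 34:2",
)

#: sulfatide/glycosphingolipid series enriched in the aggressive subtype
SULFATIDE_SPECIES = (
    "SHex2Cer 44:2", "SHex2Cer 42:1", "SHex2Cer 42:2", "SHex2Cer 42:3",
    "SHex2Cer 40:1", "SHex2Cer 38:1", "SHex2Cer 36:1", "SHex2Cer 34:1",
    "SHexCer 42:1;OH", "SHexCer 42:2;OH", "SHexCer 41:1;OH", "SHexCer 42:1",
    "SHexCer 40:1;OH",
)

#: histiocyte contrast relative to the surrounding healthy tissue.
#: Direction comes from the histiocyte loading table; magnitudes are declared
#: defaults (slight 1.2x, small 1.5x, moderate 2x; inverses for decreases).
HISTIOCYTE_FACTORS = {
    "PI 40:5": 1.2, "PI 38:2": 1.2, "PI 38:4": 0.5, "PI 36:4": 2.0,
    "PS 40:5": 1.2, "PS 40:6": 2.0, "PS 38:3": 1.2, "PS 38:4": 1 / 1.5,
    "SM 42:2": 1.2, "PS 36:1": 0.5, "PS 36:2": 1.2, "PE 38:4": 1 / 1.5,
    "PE O-38:5": 1 / 1.5, "PE 36:2": 1.2, "PE O-36:2": 1.5, "PA 38:4": 1 / 1.5,
    "PE O-36:5": 0.5, "PE 34:1": 1.5, "PA O-38:1": 1.5, "PE O-34:1": 1 / 1.5,
    "PE O-34:2": 2.0, "SM 34:1": 1 / 1.2,
}


@dataclass
class RegionProfile:
    """Mean lipid profile of one region type.

    ``species_intensities`` maps species name -> relative abundance (sums to 1
    for tissue regions); ``tic_scale`` is the mean total counts per pixel.
    """

    region_type: str
    species_intensities: dict[str, float]
    tic_scale: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.species_intensities.values()):
            raise ValueError("abundances must be >= 0")
        total = sum(self.species_intensities.values())
        if total > 0:
            self.species_intensities = {
                k: v / total for k, v in self.species_intensities.items()
            }

    def normalized(self) -> dict[str, float]:
        return dict(self.species_intensities)


def default_profiles(
    tic_tissue: float = 2000.0,
    tic_substrate: float = 20.0,
    contrast: float = 3.0,
    sulfatide_boost: float = 10.0,
    background: float = 0.1,
) -> dict[str, RegionProfile]:
    """Region profiles emulating the cohort's lipid contrasts.

    Healthy and DLBCL profiles swap the healthy/cancer marker sets at a
    ``contrast``:1 abundance ratio; the aggressive sub-region raises the
    sulfatide series to well over 5x its level elsewhere; histiocyte and
    connective profiles modulate the healthy profile by the tabulated
    directions (connective at half strength).
    """
    healthy = {}
    dlbcl = {}
    for name in HEALTHY_SPECIES:
        healthy[name] = contrast
        dlbcl[name] = 1.0
    for name in CANCER_SPECIES:
        healthy[name] = 1.0
        dlbcl[name] = contrast
    for name in SULFATIDE_SPECIES:
        healthy.setdefault(name, background)
        dlbcl.setdefault(name, background)
    for name in HISTIOCYTE_FACTORS:
        healthy.setdefault(name, 1.0)
        dlbcl.setdefault(name, 1.0)

    aggressive = dict(dlbcl)
    for name in SULFATIDE_SPECIES:
        aggressive[name] = max(aggressive[name], background) * sulfatide_boost

    histiocyte = {
        name: v * HISTIOCYTE_FACTORS.get(name, 1.0) for name, v in healthy.items()
    }
    connective = {
        name: v * HISTIOCYTE_FACTORS.get(name, 1.0) ** 0.5 for name, v in healthy.items()
    }

    return {
        "substrate": RegionProfile("substrate", {}, tic_substrate),
        "healthy_lymphoid": RegionProfile("healthy_lymphoid", healthy, tic_tissue),
        "dlbcl": RegionProfile("dlbcl", dlbcl, tic_tissue),
        "dlbcl_aggressive": RegionProfile("dlbcl_aggressive", aggressive, tic_tissue),
        "histiocyte": RegionProfile("histiocyte", histiocyte, tic_tissue),
        "connective": RegionProfile("connective", connective, tic_tissue),
    }


# ---------------------------------------------------------------------------
# scenes


@dataclass(frozen=True)
class MemberSpec:
    """One sample tile: 'healthy', 'dlbcl', 'aggressive' or 'healthy_histiocyte'."""

    sample_id: str
    condition: str
    kind: str


def default_members() -> tuple[MemberSpec, ...]:
    return (
        MemberSpec("H1", "healthy", "healthy"),
        MemberSpec("H2", "healthy", "healthy_histiocyte"),
        MemberSpec("C1", "cancer", "dlbcl"),
        MemberSpec("C2", "cancer", "aggressive"),
        MemberSpec("C3", "cancer", "dlbcl"),
    )


@dataclass
class SceneSpec:
    """Full specification of a synthetic mosaic scene; ``seed`` fixes all randomness."""

    raster_px: int = 32
    tile_edge_um: float = 900.0
    members: tuple[MemberSpec, ...] = field(default_factory=default_members)
    noise: str = "poisson"
    resolving_fwhm: float = 0.05
    grid_step: float = 0.01
    isotopes: bool = True
    n_isotopes: int = 3
    mz_range: tuple[float, float] = (590.0, 1190.0)
    tic_tissue: float = 2000.0
    tic_substrate: float = 20.0
    tissue_margin: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if not self.members:
            raise ValueError("scene needs at least one member")

    def layout(self) -> TileLayout:
        return TileLayout(
            tile_edge_um=self.tile_edge_um,
            raster_px=self.raster_px,
            mosaic_rows=1,
            mosaic_cols=len(self.members),
        )


@dataclass
class Scene:
    """Ground-truth scene: region maps, profiles, and noise-free expected spectra."""

    spec: SceneSpec
    axis: np.ndarray
    region_map: np.ndarray          # mosaic canvas of region codes
    profiles: dict[str, RegionProfile]
    expected: dict[str, np.ndarray]  # region -> expected spectrum on axis
    line_mz: dict[str, float]        # species -> monoisotopic ion m/z

    @property
    def region_names(self) -> tuple[str, ...]:
        return REGION_TYPES


@dataclass
class GroundTruth:
    """Per-pixel truth accompanying a simulated cube."""

    region_labels: np.ndarray        # region code per pixel (row-major)
    member_index: np.ndarray         # member per pixel
    region_names: tuple[str, ...]
    true_areas: dict[str, dict[str, float]]  # region -> species -> expected counts

    def three_way(self) -> np.ndarray:
        """Ground truth collapsed to {0: substrate, 1: healthy-like, 2: cancer}."""
        lut = np.array([THREE_WAY_GROUP[r] for r in self.region_names])
        return lut[self.region_labels]


def _member_region_map(kind: str, R: int, margin_frac: float) -> np.ndarray:
    code = {name: i for i, name in enumerate(REGION_TYPES)}
    m = round(margin_frac * R)
    tile = np.full((R, R), code["substrate"], int)
    tissue = {
        "healthy": "healthy_lymphoid",
        "healthy_histiocyte": "healthy_lymphoid",
        "dlbcl": "dlbcl",
        "aggressive": "dlbcl",
    }
    if kind not in tissue:
        raise ValueError(f"unknown member kind {kind!r}")
    tile[m : R - m, m : R - m] = code[tissue[kind]]
    if kind == "aggressive":
        s = max(2, round(0.3 * R))
        c0 = (R - s) // 2
        tile[c0 : c0 + s, c0 : c0 + s] = code["dlbcl_aggressive"]
    elif kind == "healthy_histiocyte":
        s = max(2, round(0.15 * R))
        tile[m + 1 : m + 1 + s, m + 1 : m + 1 + s] = code["histiocyte"]
        w = max(1, round(0.1 * R))
        tile[m : R - m, R - m - w : R - m] = code["connective"]
    return tile


def _line_positions(
    species: LipidSpecies, n_isotopes: int, isotopes: bool
) -> list[tuple[float, float]]:
    """(m/z, envelope fraction) pairs for one species, fractions summing to 1."""
    mz0 = mz_of(species, IonType.M_MINUS_H)
    if not isotopes:
        return [(mz0, 1.0)]
    env = isotope_envelope(species.formula, n_isotopes)
    total = sum(p for _, p in env)
    return [(mz0 + off, p / total) for off, p in env]


def make_scene(
    spec: SceneSpec,
    species: list[LipidSpecies] | None = None,
    profiles: dict[str, RegionProfile] | None = None,
) -> Scene:
    """Lay out the mosaic's regions and compute noise-free expected spectra.

    The shared m/z axis covers +/-4 FWHM around every spectral line at the
    requested grid step (a sparse union, not a dense axis over the whole
    range); substrate pixels contribute a flat baseline across the axis.
    """
    if species is None:
        species = load_lipid_table()
    by_name = {s.name: s for s in species}
    if profiles is None:
        profiles = default_profiles(
            tic_tissue=spec.tic_tissue, tic_substrate=spec.tic_substrate
        )
    for name, prof in profiles.items():
        if name != "substrate" and not prof.species_intensities:
            raise ValueError(f"region {name!r} has an empty profile")

    used = sorted({n for p in profiles.values() for n in p.species_intensities})
    missing = [n for n in used if n not in by_name]
    if missing:
        raise ValueError(f"species missing from the lipid table: {missing}")

    lines: dict[str, list[tuple[float, float]]] = {
        n: _line_positions(by_name[n], spec.n_isotopes, spec.isotopes) for n in used
    }
    lo, hi = spec.mz_range
    out_of_range = [
        n for n, ls in lines.items() if any(not lo <= mz <= hi for mz, _ in ls)
    ]
    if out_of_range:
        raise ValueError(
            f"m/z range {spec.mz_range} does not cover species lines: {out_of_range}"
        )

    half = 4.0 * spec.resolving_fwhm
    step = spec.grid_step
    pieces = []
    for ls in lines.values():
        for mz, _ in ls:
            a = np.floor((mz - half) / step)
            b = np.ceil((mz + half) / step)
            pieces.append(np.arange(a, b + 1))
    axis = np.unique(np.concatenate(pieces)) * step

    sigma = spec.resolving_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    expected: dict[str, np.ndarray] = {}
    for rname, prof in profiles.items():
        e = np.zeros_like(axis)
        if rname == "substrate" or not prof.species_intensities:
            if len(axis):
                e += prof.tic_scale / len(axis)
        else:
            for sp_name, ab in prof.normalized().items():
                area = ab * prof.tic_scale
                for mz, frac in lines[sp_name]:
                    sel = np.abs(axis - mz) <= half
                    kern = np.exp(-0.5 * ((axis[sel] - mz) / sigma) ** 2)
                    e[sel] += area * frac * kern / kern.sum()
        expected[rname] = e

    tiles = [
        _member_region_map(m.kind, spec.raster_px, spec.tissue_margin)
        for m in spec.members
    ]
    region_map = np.hstack(tiles)
    return Scene(
        spec=spec,
        axis=axis,
        region_map=region_map,
        profiles=profiles,
        expected=expected,
        line_mz={n: ls[0][0] for n, ls in lines.items()},
    )


def simulate_cube(scene: Scene) -> tuple[SpectralImageCube, GroundTruth]:
    """Draw a cube from the scene's expected spectra under the noise model."""
    spec = scene.spec
    layout = spec.layout()
    rows, cols = layout.shape
    rng = np.random.default_rng(spec.seed)
    region_flat = scene.region_map.reshape(-1)
    member_index = np.repeat(
        np.arange(len(spec.members)), spec.raster_px
    )[None, :].repeat(rows, axis=0).reshape(-1)

    coords = np.stack(np.unravel_index(np.arange(rows * cols), (rows, cols)), axis=1)
    expected_by_code = [scene.expected[name] for name in REGION_TYPES]
    intensities = []
    for code in region_flat:
        e = expected_by_code[code]
        if spec.noise == "poisson":
            intensities.append(rng.poisson(e).astype(np.float64))
        else:
            intensities.append(e.copy())

    cube = SpectralImageCube(
        layout=layout,
        coords=coords,
        mzs=[scene.axis] * len(coords),
        intensities=intensities,
        mz_range=spec.mz_range,
        sample_id="synthetic_scene",
        condition="unknown",
    )
    true_areas = {
        rname: {
            n: ab * prof.tic_scale for n, ab in prof.normalized().items()
        }
        for rname, prof in scene.profiles.items()
    }
    gt = GroundTruth(
        region_labels=region_flat.copy(),
        member_index=member_index,
        region_names=REGION_TYPES,
        true_areas=true_areas,
    )
    return cube, gt


def member_cubes(cube: SpectralImageCube, spec: SceneSpec) -> list[SpectralImageCube]:
    """Split a simulated mosaic into one labeled cube per sample member."""
    tiles = cube.split_tiles()
    if len(tiles) != len(spec.members):
        raise ValueError("mosaic tile count does not match member count")
    out = []
    for tile, m in zip(tiles, spec.members):
        out.append(replace(tile, sample_id=m.sample_id, condition=m.condition))
    return out
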