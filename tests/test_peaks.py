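import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from lipidmsi import msio, peaks
from lipidmsi.peaks import PeakTable, PickerParams, build_peak_tables, pick_peaks

from conftest import gaussian_spectrum

FULL_RANGE = PickerParams(ranges=((590.0, 1190.0),))
FWHM_SIGMA = 0.05 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def oracle_centroids(grid, intensity, params):
    """Independent route: finite-difference second derivative, clip, negate,
    scan for local maxima and contiguous features."""
    step = grid[1] - grid[0]
    sm = gaussian_filter1d(np.asarray(intensity, float), params.gaussian_sigma / step)
    d2 = np.gradient(np.gradient(sm, step), step)
    proc = np.where(d2 > 0, 0.0, -d2)
    feats = []
    i = 0
    while i < len(proc):
        if proc[i] > 0:
            j = i
            while j + 1 < len(proc) and proc[j + 1] > 0:
                j += 1
            w = proc[i : j + 1]
            feats.append(float(np.dot(grid[i : j + 1], w) / w.sum()))
            i = j + 1
        else:
            i += 1
    return feats


class TestPickerParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gaussian_sigma": 0.0},
            {"deriv_window": 4},
            {"deriv_window": 1},
            {"n_keep": 0},
            {"ranges": ((590.0, 810.0), (800.0, 1190.0))},
            {"ranges": ((800.0, 700.0),)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PickerParams(**kwargs)


class TestPickPeaks:
    def test_single_noiseless_gaussian_centroid(self):
        grid = np.arange(590.0, 1190.0, 0.005)
        y = gaussian_spectrum(grid, [800.00], 0.02)
        table = pick_peaks(grid, y, FULL_RANGE)
        j = int(np.argmax(table.apex_intensity))
        assert abs(table.mz_center[j] - 800.00) <= 0.005

    def test_resolved_pair_gives_two_centroids(self):
        grid = np.arange(880.0, 892.0, 0.005)
        y = gaussian_spectrum(grid, [885.55, 887.56], 0.02)
        table = pick_peaks(grid, y, FULL_RANGE)
        assert len(table) == 2
        np.testing.assert_allclose(table.mz_center, [885.55, 887.56], atol=0.005)

    @pytest.mark.parametrize("delta", [0.004, 0.01])
    def test_unresolved_pair_merges_into_one_centroid(self, delta):
        """Peaks closer than the 0.05-FWHM resolution collapse to one centroid."""
        grid = np.arange(884.0, 888.0, 0.005)
        y = gaussian_spectrum(grid, [885.55, 885.55 + delta], FWHM_SIGMA)
        table = pick_peaks(grid, y, FULL_RANGE)
        assert len(table) == 1
        assert abs(table.mz_center[0] - (885.55 + delta / 2)) <= 0.005

    def test_touching_features_set_merged_flag(self):
        # at ~2 sigma separation the two derivative features share one run
        grid = np.arange(884.0, 888.0, 0.005)
        y = gaussian_spectrum(grid, [885.55, 885.60], FWHM_SIGMA)
        table = pick_peaks(grid, y, FULL_RANGE)
        assert len(table) == 1
        assert table.merged_flag[0]

    def test_agrees_with_finite_difference_oracle(self):
        grid = np.arange(590.0, 700.0, 0.005)
        centers = [600.0, 612.35, 640.78, 641.9, 688.2]
        y = gaussian_spectrum(grid, centers, 0.03, areas=[5, 4, 3, 2, 1])
        table = pick_peaks(grid, y, FULL_RANGE)
        oracle = oracle_centroids(grid, y, FULL_RANGE)
        assert len(table) == len(oracle)
        np.testing.assert_allclose(np.sort(table.mz_center), np.sort(oracle), atol=0.005)

    def test_top_n_keeps_most_intense(self):
        grid = np.arange(590.0, 700.0, 0.005)
        centers = [600.0 + 5 * i for i in range(10)]
        areas = list(range(10, 0, -1))
        y = gaussian_spectrum(grid, centers, 0.02, areas=areas)
        table = pick_peaks(grid, y, PickerParams(ranges=((590.0, 700.0),), n_keep=5))
        assert len(table) == 5
        np.testing.assert_allclose(table.mz_center, centers[:5], atol=0.005)

    def test_zero_padding_invariance(self):
        grid = np.arange(590.0, 650.0, 0.005)
        y = gaussian_spectrum(grid, [600.0, 620.5], 0.02)
        padded_grid = np.arange(590.0, 700.0, 0.005)
        padded = np.zeros_like(padded_grid)
        padded[: len(y)] = y
        t1 = pick_peaks(grid, y, FULL_RANGE)
        t2 = pick_peaks(padded_grid, padded, FULL_RANGE)
        np.testing.assert_allclose(t1.mz_center, t2.mz_center, atol=1e-9)

    def test_short_spectrum_rejected_and_flat_allowed(self):
        with pytest.raises(ValueError, match="shorter"):
            pick_peaks(np.array([600.0, 600.005]), np.array([1.0, 2.0]), FULL_RANGE)
        grid = np.arange(590.0, 600.0, 0.005)
        assert len(pick_peaks(grid, np.zeros_like(grid), FULL_RANGE)) == 0


class TestBuildPeakTables:
    def test_dual_range_tables_ascending_and_bounded(self):
        params = PickerParams(n_keep=300)
        grid = params.grid()
        rng = np.random.default_rng(0)
        centers = np.sort(rng.uniform(595, 1185, 40))
        y = gaussian_spectrum(grid, centers, 0.03)
        table = build_peak_tables([y], grid, params)
        assert 0 < len(table) <= 600
        assert np.all(np.diff(table.mz_center) > 0)
        for lo, hi in params.ranges:
            n_in = int(np.sum((table.mz_center >= lo) & (table.mz_center < hi)))
            assert n_in <= params.n_keep

    def test_single_image_equals_pick_peaks(self):
        params = PickerParams()
        grid = params.grid()
        y = gaussian_spectrum(grid, [700.0, 900.0], 0.02)
        assert build_peak_tables([y], grid, params).equivalent(pick_peaks(grid, y, params))

    def test_duplicated_images_idempotent(self):
        params = PickerParams()
        grid = params.grid()
        y = gaussian_spectrum(grid, [700.0, 900.0], 0.02)
        t1 = build_peak_tables([y], grid, params)
        t2 = build_peak_tables([y, y, y], grid, params)
        assert t1.equivalent(t2)


class TestMeanTicSpectrum:
    def _cube(self, intens_list, mz=None):
        mz = mz if mz is not None else np.array([600.0, 700.0, 800.0])
        n = len(intens_list)
        layout = msio.TileLayout(float(n), max(n, 2))
        coords = [(0, i) for i in range(n)]
        return msio.SpectralImageCube(
            layout=layout, coords=coords, mzs=[mz] * n,
            intensities=[np.asarray(v, float) for v in intens_list],
            mz_range=(590.0, 810.0),
        )

    def test_identical_pixels_give_unit_sum(self):
        cube = self._cube([[1.0, 2.0, 3.0]] * 3)
        grid = np.arange(590.0, 810.0, 0.5)
        m = peaks.mean_tic_spectrum(cube, grid)
        assert m.sum() == pytest.approx(1.0)

    def test_tic_normalization_removes_scale(self):
        a = np.array([1.0, 2.0, 3.0])
        grid = np.arange(590.0, 810.0, 0.5)
        m_one = peaks.mean_tic_spectrum(self._cube([a]), grid)
        m_two = peaks.mean_tic_spectrum(self._cube([a, 10 * a]), grid)
        np.testing.assert_allclose(m_one, m_two, atol=1e-12)

    def test_two_region_weighted_mean(self):
        a = np.array([4.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 8.0])
        cube = self._cube([a, a, a, b])
        grid = np.array([600.0, 700.0, 800.0])
        m = peaks.mean_tic_spectrum(cube, grid)
        np.testing.assert_allclose(m, [0.75, 0.0, 0.25])

    def test_zero_tic_pixels_excluded(self):
        cube = self._cube([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        grid = np.array([600.0, 700.0, 800.0])
        m = peaks.mean_tic_spectrum(cube, grid)
        assert m.sum() == pytest.approx(1.0)


class TestCentroidImage:
    def _table(self):
        return PeakTable(
            np.array([700.0, 801.0]),
            np.array([699.0, 800.0]),
            np.array([701.0, 802.0]),
            np.array([1.0, 1.0]),
            np.array([False, False]),
        )

    def _cube(self, mz, inten):
        return msio.SpectralImageCube(
            layout=msio.TileLayout(2.0, 2),
            coords=[(0, 0), (0, 1), (1, 0), (1, 1)],
            mzs=[np.asarray(mz, float)] * 4,
            intensities=[np.asarray(inten, float)] * 4,
            mz_range=(590.0, 1190.0),
        )

    def test_no_signal_in_windows_gives_zero_row(self):
        cube = self._cube([650.0, 750.0], [5.0, 7.0])
        fi = peaks.centroid_image(cube, self._table())
        np.testing.assert_array_equal(fi.matrix, 0.0)

    def test_half_open_windows_assign_edge_once(self):
        table = PeakTable(
            np.array([800.5, 801.5]),
            np.array([800.0, 801.0]),
            np.array([801.0, 802.0]),
            np.array([1.0, 1.0]),
            np.array([False, False]),
        )
        cube = self._cube([801.0], [9.0])  # exactly on the shared edge
        fi = peaks.centroid_image(cube, table)
        np.testing.assert_array_equal(fi.matrix[0], [0.0, 9.0])

    def test_windowed_intensity_conserved(self, small_scene):
        _, _, cube, _ = small_scene
        params = PickerParams()
        grid = params.grid()
        table = build_peak_tables([peaks.mean_tic_spectrum(cube, grid)], grid, params)
        fi = peaks.centroid_image(cube, table)
        rows, cols = cube.layout.shape
        for pix in (0, cube.n_pixels // 2, cube.n_pixels - 1):
            r, c = cube.coords[pix]
            mz, inten = cube.mzs[pix], cube.intensities[pix]
            expected = sum(
                inten[(mz >= lo) & (mz < hi)].sum()
                for lo, hi in zip(table.window_lo, table.window_hi)
            )
            assert fi.matrix[r * cols + c].sum() == pytest.approx(expected)

    def test_known_region_areas_recovered(self, small_scene, lipid_db):
        """Centroided areas in a noise-free scene match the generator truth."""
        from lipidmsi import annotation, synthetic

        spec, _, _, _ = small_scene
        import dataclasses

        nf_spec = dataclasses.replace(spec, noise="none")
        scene = synthetic.make_scene(nf_spec)
        cube, gt = synthetic.simulate_cube(scene)
        params = PickerParams()
        grid = params.grid()
        table = build_peak_tables([peaks.mean_tic_spectrum(cube, grid)], grid, params)
        fi = peaks.centroid_image(cube, table)
        by_name = {s.name: s for s in lipid_db}
        healthy_code = list(gt.region_names).index("healthy_lymphoid")
        pix = int(np.flatnonzero(gt.region_labels == healthy_code)[0])
        areas = gt.true_areas["healthy_lymphoid"]
        expected_spec = scene.expected["healthy_lymphoid"]
        for name in ("PI 38:4", "PS 36:1"):
            mz = annotation.mz_of(by_name[name])
            j = int(np.argmin(np.abs(table.mz_center - mz)))
            measured = fi.matrix[pix, j]
            # direct integration of the generating model over the same window
            sel = (scene.axis >= table.window_lo[j]) & (scene.axis < table.window_hi[j])
            assert measured == pytest.approx(expected_spec[sel].sum(), rel=1e-9)
            # the window captures the bulk of the species' line area
            env = synthetic.isotope_envelope(by_name[name].formula, nf_spec.n_isotopes)
            frac = env[0][1] / sum(p for _, p in env)
            assert measured > 0.5 * areas[name] * frac
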