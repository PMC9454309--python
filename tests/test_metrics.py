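"""HU metrics, contour agreement and the gamma engine against oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cbct2ct import (EvalCase, GammaConfig, dsc, evaluation_report,
                     gamma_index, hu_histogram, mae, make_dose_pair, mda,
                     psnr, rmse, roi_stats)
from cbct2ct.metrics import gamma_index_bruteforce
from cbct2ct.phantom import ContourMask, DoseGrid

# light search settings: the gamma closed forms hold for any candidate grid
FAST_GAMMA = GammaConfig(dose_criterion=1.0, dta=1.0, search_radius=2.0,
                         interp_step=0.25)


class TestHUMetrics:
    def test_perfect_match(self):
        y = np.arange(9.0).reshape(3, 3)
        assert mae(y, y) == 0.0
        assert rmse(y, y) == 0.0
        assert psnr(y, y) == float("inf")

    def test_unit_offset_vector(self):
        """y=(0,0,0,0), yhat=(1,1,1,1), Max_p=1: MAE=RMSE=1, PSNR=0 dB."""
        y = np.zeros(4)
        yh = np.ones(4)
        assert mae(yh, y) == 1.0
        assert rmse(yh, y) == 1.0
        assert psnr(yh, y, max_p=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_pixel_example(self):
        """y=(0,2), yhat=(1,1), Max_p=255: MAE=RMSE=1, PSNR=10log10(65025)."""
        y = np.array([0.0, 2.0])
        yh = np.array([1.0, 1.0])
        assert mae(yh, y) == 1.0
        assert rmse(yh, y) == 1.0
        assert psnr(yh, y, max_p=255.0) == pytest.approx(
            10 * np.log10(65025.0))

    def test_psnr_consistent_with_rmse(self, rng):
        y = rng.random((16, 16)) * 100
        yh = y + rng.standard_normal((16, 16))
        r = rmse(yh, y)
        assert psnr(yh, y, max_p=500.0) == pytest.approx(
            10 * np.log10(500.0 ** 2 / r ** 2))

    def test_mask_restricts_pixels(self):
        y = np.zeros((4, 4))
        yh = np.ones((4, 4))
        yh[0, 0] = 100.0
        m = np.ones((4, 4), bool)
        m[0, 0] = False
        assert mae(yh, y, m) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mae(np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2), bool))


class TestHistogramAndROI:
    def test_uniform_image_single_bin(self):
        img = np.full((10, 10), 40.0)
        counts = hu_histogram(img, None, [-100, 0, 50, 100])
        np.testing.assert_array_equal(counts, [0, 100, 0])

    def test_counts_conserved_with_outliers(self, rng):
        img = rng.standard_normal((20, 20)) * 2000
        counts = hu_histogram(img, None, np.linspace(-500, 500, 11))
        assert counts.sum() == 400

    def test_two_valued_split(self):
        img = np.zeros((4, 4))
        img[:2] = 100.0
        counts = hu_histogram(img, None, [-50, 50, 150])
        np.testing.assert_array_equal(counts, [8, 8])

    def test_roi_constant_region(self):
        img = np.full((6, 6), 700.0)
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert roi_stats(img, m) == (700.0, 0.0)

    def test_roi_population_sd(self):
        img = np.zeros((2, 2))
        img[0] = 2.0
        mean, sd = roi_stats(img, np.ones((2, 2), bool))
        assert (mean, sd) == (1.0, 1.0)


class TestDice:
    def test_equal_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool); a[0, 0] = True
        b = np.zeros((5, 5), bool); b[4, 4] = True
        assert dsc(a, b) == 0.0

    def test_counting_example(self):
        """|A|=4, |B|=2, overlap 2 -> 2*2/6."""
        a = np.zeros((4, 4), bool); a[0, :4] = True
        b = np.zeros((4, 4), bool); b[0, :2] = True
        assert dsc(a, b) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_one(self):
        e = np.zeros((3, 3), bool)
        assert dsc(e, e) == 1.0

    def test_symmetry(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        assert dsc(a, b) == dsc(b, a)


def brute_force_msd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs symmetric mean surface distance oracle."""
    from scipy.ndimage import binary_erosion

    def boundary_pts(m):
        return np.argwhere(m & ~binary_erosion(m)) * np.asarray(spacing)

    pa, pb = boundary_pts(a), boundary_pts(b)
    d = cdist(pa, pb)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


class TestMDA:
    def square(self, off=0, size=10, canvas=24):
        m = np.zeros((canvas, canvas), bool)
        m[4 + off:4 + off + size, 4 + off:4 + off + size] = True
        return m

    def test_identical_contours(self):
        m = self.square()
        assert mda(m, m) == 0.0

    def test_offset_squares_match_all_pairs_oracle(self):
        a, b = self.square(0), self.square(1)
        want = brute_force_msd(a, b, (1.0, 1.0))
        assert mda(a, b) == pytest.approx(want, abs=1e-9)

    def test_monotone_in_offset(self):
        a = self.square(0)
        vals = [mda(a, self.square(k)) for k in (1, 2, 3)]
        assert vals[0] < vals[1] < vals[2]

    def test_spacing_linearity(self):
        a, b = self.square(0), self.square(2)
        one = mda(ContourMask(a, (1.0, 1.0)), ContourMask(b, (1.0, 1.0)))
        two = mda(ContourMask(a, (2.0, 2.0)), ContourMask(b, (2.0, 2.0)))
        assert two == pytest.approx(2 * one)

    def test_symmetry(self):
        a, b = self.square(0), self.square(2)
        assert mda(a, b) == pytest.approx(mda(b, a))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mda(np.zeros((4, 4), bool), self.square(0, 2, 4))


def uniform_dose(value, prescription=50.0, shape=(8, 8, 8)):
    return DoseGrid(np.full(shape, value), (2.0, 2.0, 2.0), prescription)


class TestGamma:
    def test_identical_grids_all_zero(self):
        ref, _ = make_dose_pair((8, 8, 8), (2, 2, 2), 50.0, 0.0)
        gmap, rate = gamma_index(ref, ref, FAST_GAMMA)
        assert rate == 100.0
        assert np.nanmax(gmap) == 0.0

    def test_uniform_one_percent_offset_boundary_passes(self):
        """Dose term exactly 1, no spatial remedy on a uniform field."""
        p = 50.0
        ref = uniform_dose(p, p)
        test = uniform_dose(p * 1.01, p)
        gmap, rate = gamma_index(ref, test, FAST_GAMMA)
        np.testing.assert_allclose(gmap[~np.isnan(gmap)], 1.0, atol=1e-9)
        assert rate == 100.0

    def test_uniform_three_percent_offset_fails_everywhere(self):
        p = 50.0
        ref = uniform_dose(p, p)
        test = uniform_dose(p * 1.03, p)
        gmap, rate = gamma_index(ref, test, FAST_GAMMA)
        np.testing.assert_allclose(gmap[~np.isnan(gmap)], 3.0, atol=1e-9)
        assert rate == 0.0

    def test_low_dose_voxels_excluded(self):
        ref, test = make_dose_pair((12, 12, 12), (2, 2, 2), 50.0, 0.02)
        gmap, _ = gamma_index(ref, test, FAST_GAMMA)
        low = ref.values < 0.10 * 50.0
        assert np.all(np.isnan(gmap[low]))

    def test_optimized_equals_bruteforce_on_cube(self):
        ref, test = make_dose_pair((16, 16, 16), (2, 2, 2), 50.0, 0.015)
        cfg = GammaConfig(dose_criterion=1.0, dta=1.0, search_radius=1.5,
                          interp_step=0.5)
        g1, r1 = gamma_index(ref, test, cfg)
        g2, r2 = gamma_index_bruteforce(ref, test, cfg)
        np.testing.assert_allclose(g1, g2, atol=1e-6, equal_nan=True)
        assert r1 == r2

    def test_pass_rate_monotone_in_perturbation_and_criteria(self):
        rates_p = []
        for pert in (0.02, 0.1, 0.3):
            ref, test = make_dose_pair((10, 10, 10), (2, 2, 2), 50.0, pert)
            rates_p.append(gamma_index(ref, test, FAST_GAMMA)[1])
        assert rates_p[0] >= rates_p[1] >= rates_p[2]
        assert rates_p[0] > rates_p[2]

        ref, test = make_dose_pair((10, 10, 10), (2, 2, 2), 50.0, 0.1)
        grid = np.zeros((3, 3))
        for i, dc in enumerate((1.0, 2.0, 3.0)):
            for j, dta in enumerate((1.0, 2.0, 3.0)):
                cfg = GammaConfig(dose_criterion=dc, dta=dta,
                                  search_radius=2.0, interp_step=0.5)
                grid[i, j] = gamma_index(ref, test, cfg)[1]
        assert np.all(np.diff(grid, axis=0) >= 0)    # looser dose criterion
        assert np.all(np.diff(grid, axis=1) >= 0)    # looser dta

    def test_grid_mismatch_rejected(self):
        a = uniform_dose(50.0)
        b = DoseGrid(np.full((4, 4, 4), 50.0), (2.0, 2.0, 2.0), 50.0)
        with pytest.raises(ValueError):
            gamma_index(a, b, FAST_GAMMA)


class TestReport:
    def test_single_case_mean_is_value_sd_zero(self, rng):
        y = rng.random((16, 16)) * 100
        case = EvalCase("c1", y, y + 1.0)
        df, summary = evaluation_report([case], FAST_GAMMA)
        assert summary["mae_hu"]["mean"] == pytest.approx(1.0)
        assert summary["mae_hu"]["sd"] == 0.0

    def test_identical_pair_rows_zero(self, rng):
        y = rng.random((8, 8))
        df, summary = evaluation_report([EvalCase("c", y, y.copy())],
                                        FAST_GAMMA)
        assert summary["mae_hu"]["mean"] == 0.0

    def test_report_files_byte_identical(self, tmp_path, rng):
        y = rng.random((8, 8))
        case = EvalCase("c", y, y + 0.5)
        for d in ("a", "b"):
            evaluation_report([case], FAST_GAMMA,
                              out_csv=tmp_path / d / "m.csv",
                              out_json=tmp_path / d / "s.json")
        assert (tmp_path / "a" / "m.csv").read_bytes() == \
               (tmp_path / "b" / "m.csv").read_bytes()
        assert (tmp_path / "a" / "s.json").read_bytes() == \
               (tmp_path / "b" / "s.json").read_bytes()
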