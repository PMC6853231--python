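"""Pattern correlation, absolute-difference quantiles, Delta downscaling."""

import math

import numpy as np
import pytest

from oscillayers import (
    BioclimStack,
    ClimateRaster,
    GridSpec,
    abs_diff_quantiles,
    compare_stacks,
    delta_downscale,
    pattern_correlation,
)

from conftest import random_raster


@pytest.fixture
def spec():
    return GridSpec(5, 4, 0.0, 0.0, 1.0)


def _vecs_as_rasters(a, b):
    n = len(a)
    spec = GridSpec(n, 1, 0.0, 0.0, 1.0)
    ra = ClimateRaster(spec, np.asarray(a, dtype=float).reshape(1, n))
    rb = ClimateRaster(spec, np.asarray(b, dtype=float).reshape(1, n))
    return ra, rb


def closed_form_pearson(a, b):
    """Textbook formula, written independently of the implementation."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    sa = math.sqrt(sum((x - ma) ** 2 for x in a))
    sb = math.sqrt(sum((y - mb) ** 2 for y in b))
    return cov / (sa * sb)


class TestPatternCorrelation:
    def test_identical_rasters(self, spec):
        r = random_raster(spec, 0, missing_frac=0)
        assert pattern_correlation(r, r.copy()) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, spec):
        r = random_raster(spec, 1, missing_frac=0)
        neg = r.with_values(-r.values + 7.0)
        assert pattern_correlation(r, neg) == pytest.approx(-1.0)

    def test_five_cell_closed_form(self):
        a, b = (1, 2, 3, 4, 5), (2, 1, 4, 3, 6)
        ra, rb = _vecs_as_rasters(a, b)
        assert pattern_correlation(ra, rb) == pytest.approx(
            closed_form_pearson(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_vectors_match_closed_form(self, seed):
        rng = np.random.default_rng(300 + seed)
        a = rng.uniform(-5, 5, 17)
        b = rng.uniform(-5, 5, 17)
        ra, rb = _vecs_as_rasters(a, b)
        assert pattern_correlation(ra, rb) == pytest.approx(
            closed_form_pearson(list(a), list(b)), abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, spec):
        a = random_raster(spec, 2, missing_frac=0)
        b = random_raster(spec, 3, missing_frac=0)
        r0 = pattern_correlation(a, b)
        assert pattern_correlation(a, b.with_values(2.5 * b.values + 3)) == pytest.approx(r0)
        assert pattern_correlation(a, b.with_values(-1.5 * b.values)) == pytest.approx(-r0)

    def test_symmetry(self, spec):
        a = random_raster(spec, 4, missing_frac=0.2)
        b = random_raster(spec, 5, missing_frac=0.2)
        assert pattern_correlation(a, b) == pytest.approx(pattern_correlation(b, a))

    def test_joint_mask_only(self, spec):
        """Adding a cell that is missing in either input changes nothing."""
        a = random_raster(spec, 6, missing_frac=0)
        b = random_raster(spec, 7, missing_frac=0)
        r0 = pattern_correlation(a, b)
        a2, b2 = a.copy(), b.copy()
        a2.values[0, 0] = np.nan     # drop one side
        b2.values[0, 0] = 1e6        # wild value on the other side, ignored
        assert pattern_correlation(a2, b2) == pytest.approx(
            pattern_correlation(
                a.with_values(np.where(a2.valid, a.values, np.nan)),
                b.with_values(np.where(a2.valid, b.values, np.nan))))

    def test_degenerate_variance_rejected(self, spec):
        const = ClimateRaster(spec, np.full(spec.shape, 2.0))
        with pytest.raises(ValueError, match="variance"):
            pattern_correlation(const, random_raster(spec, 8, missing_frac=0))

    def test_too_few_cells_rejected(self, spec):
        a = ClimateRaster(spec, np.full(spec.shape, np.nan))
        a.values[0, :2] = [1.0, 2.0]
        b = random_raster(spec, 9, missing_frac=0)
        with pytest.raises(ValueError, match="3"):
            pattern_correlation(a, b)


class TestAbsDiffQuantiles:
    def test_identical_rasters(self, spec):
        r = random_raster(spec, 0, missing_frac=0)
        assert abs_diff_quantiles(r, r.copy()) == (0.0, 0.0)

    def test_uniform_1_to_40_order_statistics(self):
        """|a-b| = 1..40: the 97.5% linear-interpolated quantile sits
        between the 39th and 40th order statistic."""
        diffs = np.arange(1, 41, dtype=float)
        a, b = _vecs_as_rasters(np.zeros(40), diffs)
        lo, hi = abs_diff_quantiles(a, b)
        # sorting oracle: h = (n-1)*p; v[floor(h)] + frac*(v[floor(h)+1]-v[floor(h)])
        srt = sorted(diffs)
        for p, got in ((0.025, lo), (0.975, hi)):
            h = (len(srt) - 1) * p
            k = int(math.floor(h))
            expect = srt[k] + (h - k) * (srt[k + 1] - srt[k])
            assert got == pytest.approx(expect, abs=1e-12)

    def test_extreme_probs_give_min_max(self, spec):
        a = random_raster(spec, 1, missing_frac=0)
        b = random_raster(spec, 2, missing_frac=0)
        d = np.abs(a.values - b.values)
        assert abs_diff_quantiles(a, b, (0.0, 1.0)) == pytest.approx(
            (d.min(), d.max()))

    def test_symmetry(self, spec):
        a = random_raster(spec, 3, missing_frac=0.1)
        b = random_raster(spec, 4, missing_frac=0.1)
        assert abs_diff_quantiles(a, b) == abs_diff_quantiles(b, a)

    def test_no_shared_cells_rejected(self, spec):
        a = ClimateRaster(spec, np.full(spec.shape, np.nan))
        b = random_raster(spec, 5, missing_frac=0)
        with pytest.raises(ValueError):
            abs_diff_quantiles(a, b)


class TestDeltaDownscale:
    @pytest.fixture
    def grids(self):
        coarse = GridSpec(6, 6, 0.0, 0.0, 2.0)   # 12x12 degrees
        fine = GridSpec(16, 16, 2.0, 2.0, 0.5)   # nested 8x8 degrees
        rng = np.random.default_rng(7)
        cb = ClimateRaster(coarse, rng.uniform(0, 10, coarse.shape), "bio1")
        fb = ClimateRaster(fine, rng.uniform(0, 10, fine.shape), "bio1")
        return cb, fb

    def test_constant_anomaly_adds_constant(self, grids):
        cb, fb = grids
        cp = cb.with_values(cb.values + 2.0)
        out = delta_downscale(cp, cb, fb)
        np.testing.assert_allclose(out.values, fb.values + 2.0, atol=1e-12)

    def test_zero_anomaly_is_identity(self, grids):
        cb, fb = grids
        out = delta_downscale(cb.copy(), cb, fb)
        np.testing.assert_allclose(out.values, fb.values, atol=0)

    def test_bilinear_exact_on_affine_anomaly(self, grids):
        cb, fb = grids
        def plane(spec):
            xx, yy = np.meshgrid(spec.x_centers(), spec.y_centers())
            return 1.5 + 0.25 * xx - 0.4 * yy
        cp = cb.with_values(cb.values + plane(cb.spec))
        out = delta_downscale(cp, cb, fb)
        np.testing.assert_allclose(out.values, fb.values + plane(fb.spec), atol=1e-10)

    def test_missing_fine_cells_stay_missing(self, grids):
        cb, fb = grids
        fb.values[3, 3] = np.nan
        out = delta_downscale(cb.with_values(cb.values + 1), cb, fb)
        assert not out.valid[3, 3]

    def test_disjoint_extents_rejected(self, grids):
        cb, fb = grids
        far = ClimateRaster(GridSpec(4, 4, 100.0, 100.0, 0.5),
                            np.zeros((4, 4)), "bio1")
        with pytest.raises(ValueError, match="overlap"):
            delta_downscale(cb, cb, far)


class TestCompareStacks:
    def _stack(self, spec, seeds):
        st = BioclimStack(spec)
        for var, seed in seeds.items():
            st.add(random_raster(spec, seed, missing_frac=0, variable=var))
        return st

    def test_identical_stacks(self, spec, tmp_path):
        a = self._stack(spec, {"bio1": 1, "bio12": 2})
        results = compare_stacks(a, a, report_path=tmp_path / "r.csv")
        assert len(results) == 2
        for c in results:
            assert c.pearson_r == pytest.approx(1.0)
            assert (c.q_low, c.q_high) == (0.0, 0.0)
            assert c.n_cells == 20
        text = (tmp_path / "r.csv").read_text()
        assert "variable,pearson_r,q025,q975,n_cells" in text

    def test_uniform_offset_keeps_r_one(self, spec):
        a = self._stack(spec, {"bio1": 1})
        b = BioclimStack(spec, {"bio1": a["bio1"].with_values(a["bio1"].values + 10)})
        (c,) = compare_stacks(a, b)
        assert c.pearson_r == pytest.approx(1.0)
        assert (c.q_low, c.q_high) == pytest.approx((10.0, 10.0))

    def test_correlation_decreases_with_noise(self):
        spec = GridSpec(30, 30, 0.0, 0.0, 1.0)
        base = random_raster(spec, 10, missing_frac=0)
        a = BioclimStack(spec, {"bio1": base})
        rs = []
        rng = np.random.default_rng(99)
        noise = rng.standard_normal(spec.shape)
        for sigma in (1.0, 5.0, 25.0):
            noisy = base.with_values(base.values + sigma * noise)
            b = BioclimStack(spec, {"bio1": noisy})
            rs.append(compare_stacks(a, b)[0].pearson_r)
        assert rs[0] > rs[1] > rs[2]

    def test_no_shared_variables_rejected(self, spec):
        a = self._stack(spec, {"bio1": 1})
        b = self._stack(spec, {"bio2": 2})
        with pytest.raises(ValueError, match="share"):
            compare_stacks(a, b)
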