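"""Delta computation, period scaling, calibration, and the period loop."""

import numpy as np
import pytest

from oscillayers import (
    ClimateRaster,
    GridSpec,
    PeriodGenerator,
    TimePeriod,
    calibrate,
    compute_delta,
    scale_delta,
    scale_factor,
)

from conftest import random_raster


@pytest.fixture
def spec():
    return GridSpec(6, 5, 0.0, 0.0, 1.0)


def _raster(spec, fill, variable="bio1"):
    return ClimateRaster(spec, np.full(spec.shape, float(fill)), variable)


class TestComputeDelta:
    def test_cellwise_subtraction(self, spec):
        d = compute_delta(_raster(spec, 250), _raster(spec, 206))
        np.testing.assert_allclose(d.values, 44.0)

    def test_identical_inputs_give_zero(self, spec):
        r = random_raster(spec, 1, missing_frac=0)
        assert np.all(compute_delta(r, r.copy()).values == 0)

    def test_missing_propagates_from_either_operand(self, spec):
        a = _raster(spec, 10)
        b = _raster(spec, 4)
        a.values[1, 1] = np.nan
        b.values[2, 2] = np.nan
        d = compute_delta(a, b)
        assert not d.raster.valid[1, 1] and not d.raster.valid[2, 2]
        assert d.raster.valid.sum() == spec.ncols * spec.nrows - 2

    def test_variable_mismatch_rejected(self, spec):
        with pytest.raises(ValueError, match="variable"):
            compute_delta(_raster(spec, 1, "bio1"), _raster(spec, 1, "bio2"))

    def test_misalignment_rejected(self, spec):
        other = GridSpec(6, 5, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="misaligned"):
            compute_delta(_raster(spec, 1), _raster(other, 1))


class TestScaleDelta:
    @pytest.mark.parametrize("factor,expected", [(1.0, 44.0), (0.0, 0.0), (0.5, 22.0)])
    def test_scaling(self, spec, factor, expected):
        d = compute_delta(_raster(spec, 250), _raster(spec, 206))
        np.testing.assert_allclose(scale_delta(d, factor).values, expected)

    def test_missing_pattern_preserved_at_zero_factor(self, spec):
        a = _raster(spec, 10)
        a.values[0, 0] = np.nan
        d = compute_delta(a, _raster(spec, 4))
        scaled = scale_delta(d, 0.0)
        assert not scaled.raster.valid[0, 0]
        assert (scaled.values[scaled.raster.valid] == 0).all()

    def test_non_finite_factor_rejected(self, spec):
        d = compute_delta(_raster(spec, 1), _raster(spec, 0))
        with pytest.raises(ValueError):
            scale_delta(d, np.nan)


class TestCalibrate:
    def test_recovers_present_at_unit_factor(self, spec):
        d = compute_delta(_raster(spec, 250), _raster(spec, 206))
        out, n = calibrate(_raster(spec, 206), d)
        np.testing.assert_allclose(out.values, 250.0)
        assert n == 0

    def test_zero_factor_returns_baseline(self, spec):
        d = scale_delta(compute_delta(_raster(spec, 250), _raster(spec, 206)), 0.0)
        out, _ = calibrate(_raster(spec, 206), d)
        np.testing.assert_allclose(out.values, 206.0)

    def test_negative_precipitation_clamped_and_counted(self, spec):
        d = compute_delta(_raster(spec, 0, "bio12"), _raster(spec, 10, "bio12"))
        out, n = calibrate(_raster(spec, 3, "bio12"), d)  # 3 - 10 = -7 -> 0
        np.testing.assert_allclose(out.values, 0.0)
        assert n == spec.ncols * spec.nrows

    def test_clamp_default_off_for_temperature(self, spec):
        d = compute_delta(_raster(spec, -20, "bio6"), _raster(spec, 0, "bio6"))
        out, n = calibrate(_raster(spec, 3, "bio6"), d)
        np.testing.assert_allclose(out.values, -17.0)
        assert n == 0

    def test_clamp_switchable_off(self, spec):
        d = compute_delta(_raster(spec, 0, "bio12"), _raster(spec, 10, "bio12"))
        out, n = calibrate(_raster(spec, 3, "bio12"), d, clamp_nonnegative=False)
        np.testing.assert_allclose(out.values, -7.0)
        assert n == 0

    def test_linearity_in_factor_before_clamping(self, spec):
        rng = np.random.default_rng(5)
        isp = ClimateRaster(spec, rng.normal(20, 5, spec.shape), "bio1")
        isl = ClimateRaster(spec, rng.normal(15, 5, spec.shape), "bio1")
        delta = compute_delta(isp, isl)
        a, b = 0.4, 0.35
        lhs, _ = calibrate(isl, scale_delta(delta, a + b), clamp_nonnegative=False)
        rhs, _ = calibrate(isl, scale_delta(delta, a), clamp_nonnegative=False)
        np.testing.assert_allclose(lhs.values, rhs.values + b * delta.values, atol=1e-12)


@pytest.fixture(scope="module")
def generator(world):
    present, lgm, dem, curve = world
    return PeriodGenerator(present, lgm, dem, curve, clamp=False)


class TestPeriodGenerator:

    def test_present_anchor_reproduces_isp_on_land(self, generator):
        curve = generator.curve
        per = next(p for p in curve if abs(p.ts_c - curve.ts_present_c) < 1e-12)
        stack = generator.generate(per)
        land = generator.land_mask(per.sea_level_m).land
        for var in ("bio1", "bio12", "bio7"):
            dev = np.abs(stack[var].values - generator.isp[var].values)[land]
            assert np.nanmax(dev) <= 1e-9

    def test_lgm_anchor_reproduces_isl_on_glacial_land(self, generator):
        curve = generator.curve
        per = curve.period_at(20)
        assert abs(per.ts_c - curve.ts_lgm_c) < 1e-12
        stack = generator.generate(per)
        land = generator.land_mask(per.sea_level_m).land
        for var in ("bio1", "bio12"):
            dev = np.abs(stack[var].values - generator.isl[var].values)[land]
            assert np.nanmax(dev) <= 1e-9

    def test_output_valid_set_within_isl_and_mask(self, generator):
        per = generator.curve.periods[37]
        stack = generator.generate(per)
        land = generator.land_mask(per.sea_level_m).land
        for var in generator.variables:
            valid = stack[var].valid
            assert not (valid & ~land).any()
            assert not (valid & ~generator.isl[var].valid).any()

    def test_monotone_response_where_delta_positive(self, generator):
        """At a fixed cell with a positive anomaly, warmer periods give
        strictly larger pre-clip values."""
        curve = generator.curve
        var = "bio1"
        delta = generator.deltas[var].values
        land0 = generator.land_mask(0.0).land
        cell = tuple(np.argwhere(land0 & (delta > 0))[0])
        ts_values = np.linspace(curve.ts_lgm_c - 1, curve.ts_present_c + 1, 7)
        outs = []
        for ts in ts_values:
            f = scale_factor(ts, curve)
            outs.append(generator.isl[var].values[cell] + f * delta[cell])
        assert all(a < b for a, b in zip(outs, outs[1:]))

    def test_repeated_generation_is_deterministic(self, world):
        present, lgm, dem, curve = world
        per = curve.periods[100]
        g1 = PeriodGenerator(present, lgm, dem, curve)
        g2 = PeriodGenerator(present, lgm, dem, curve)
        s1, s2 = g1.generate(per), g2.generate(per)
        for var in s1.variables:
            np.testing.assert_array_equal(s1[var].values, s2[var].values)

    def test_temperature_layers_never_clamped(self, world):
        present, lgm, dem, curve = world
        gen = PeriodGenerator(present, lgm, dem, curve, clamp=True,
                              variables=["bio1", "bio6", "bio12"])
        per = min(curve, key=lambda p: p.ts_c)  # coldest period: most clamping
        gen.generate(per)
        stats = gen.last_period_stats["variables"]
        assert stats["bio1"]["clamped"] == 0
        assert stats["bio6"]["clamped"] == 0
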