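"""The anomaly (Delta) engine: from baselines to per-period bioclim layers.

For each bioclim variable the pipeline computes, once,

    Delta = ISP - ISL

(the interpolated present surface minus the interpolated LGM surface: the
spatial fingerprint of glacial-interglacial climate change), then for every
time period T scales it by the chronology's factor

    f(T) = (Ts_T - Ts_LGM) / (Ts_present - Ts_LGM)

and calibrates it onto the LGM baseline:

    Bio_T = ISL + f(T) * Delta.

At f = 1 this recovers the present surface, at f = 0 the LGM surface; the
spatial pattern of every reconstructed period is the LGM pattern plus a
scaled copy of the glacial-interglacial contrast.  The anomaly is additive
for all 19 variables, precipitation included; negative precipitation values
produced by large negative scaled anomalies are clamped to zero (counted,
and switchable off).

The baseline for calibration is ISL rather than the raw LGM grid so that
shelf cells — which are missing in the raw grids — receive values before
the period land mask decides their fate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from oscillayers.chronology import TemperatureCurve, TimePeriod, scale_factor
from oscillayers.coastlines import LandMask, clip, reclassify_dem
from oscillayers.interpolation import FillConfig, fill_surface, shelf_target_mask
from oscillayers.raster_core import (
    BioclimStack,
    ClimateRaster,
    PRECIPITATION_VARS,
    require_aligned,
)

logger = logging.getLogger(__name__)


@dataclass
class DeltaLayer:
    """One variable's present-minus-LGM anomaly, valid where both inputs are."""

    raster: ClimateRaster
    provenance: tuple[str, str] = ("ISP", "ISL")

    @property
    def variable(self) -> str:
        return self.raster.variable

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def compute_delta(isp: ClimateRaster, isl: ClimateRaster) -> DeltaLayer:
    """Cellwise ISP - ISL; missing where either operand is missing."""
    require_aligned(isp.spec, isl.spec, "ISP vs ISL")
    if isp.variable != isl.variable:
        raise ValueError(f"variable mismatch: {isp.variable!r} vs {isl.variable!r}")
    delta = isp.values - isl.values  # NaN propagates
    return DeltaLayer(isp.with_values(delta), provenance=("ISP", "ISL"))


def scale_delta(delta: DeltaLayer, factor: float) -> DeltaLayer:
    """Cellwise Delta * factor; the missing pattern is preserved."""
    if not np.isfinite(factor):
        raise ValueError(f"scale factor must be finite, got {factor}")
    return DeltaLayer(delta.raster.with_values(delta.values * factor), delta.provenance)


def calibrate(
    lgm_baseline: ClimateRaster,
    scaled_delta: DeltaLayer,
    clamp_nonnegative: bool | None = None,
) -> tuple[ClimateRaster, int]:
    """Baseline + scaled anomaly; optionally clamp negatives to zero.

    ``clamp_nonnegative`` defaults to True for precipitation variables
    (bio12-bio19) and False for temperature variables.  Returns the
    calibrated raster and the number of clamped cells.
    """
    require_aligned(lgm_baseline.spec, scaled_delta.raster.spec, "baseline vs anomaly")
    if lgm_baseline.variable != scaled_delta.variable:
        raise ValueError(
            f"variable mismatch: {lgm_baseline.variable!r} vs {scaled_delta.variable!r}"
        )
    if clamp_nonnegative is None:
        clamp_nonnegative = lgm_baseline.variable in PRECIPITATION_VARS
    out = lgm_baseline.values + scaled_delta.values
    n_clamped = 0
    if clamp_nonnegative:
        with np.errstate(invalid="ignore"):
            neg = out < 0
        n_clamped = int(neg.sum())
        if n_clamped:
            out = np.where(neg, 0.0, out)
            logger.info("calibrate(%s): clamped %d negative cells to 0",
                        lgm_baseline.variable, n_clamped)
    return lgm_baseline.with_values(out), n_clamped


@dataclass
class PeriodGenerator:
    """Runs the full per-period pipeline with cached baselines.

    The expensive stages — gap-filling ISP/ISL over the shelf and the
    Delta layers — depend only on the inputs, so they are computed once at
    construction; each period is then pure raster algebra plus a land-mask
    reclassification (masks are cached per sea-level stand).
    """

    present: BioclimStack
    lgm: BioclimStack
    dem: ClimateRaster
    curve: TemperatureCurve
    fill_config: FillConfig = field(default_factory=FillConfig)
    clamp: bool = True
    connectivity: int = 8
    variables: list[str] | None = None

    def __post_init__(self) -> None:
        require_aligned(self.present.spec, self.lgm.spec, "present vs LGM stacks")
        require_aligned(self.present.spec, self.dem.spec, "stacks vs DEM")
        if self.variables is None:
            self.variables = [v for v in self.present.variables if v in self.lgm]
        missing = [v for v in self.variables
                   if v not in self.present or v not in self.lgm]
        if missing:
            raise ValueError(f"variables absent from an input stack: {missing}")

        target = shelf_target_mask(self.dem, self.curve.min_sea_level_m)
        logger.info("shelf target mask: %d cells", int(target.sum()))
        self.isp = BioclimStack(self.present.spec)
        self.isl = BioclimStack(self.present.spec)
        self.deltas: dict[str, DeltaLayer] = {}
        for var in self.variables:
            self.isp.add(fill_surface(self.present[var], target, self.fill_config))
            self.isl.add(fill_surface(self.lgm[var], target, self.fill_config))
            self.deltas[var] = compute_delta(self.isp[var], self.isl[var])
        self._mask_cache: dict[float, LandMask] = {}

    def land_mask(self, sea_level_m: float) -> LandMask:
        key = round(float(sea_level_m), 6)
        if key not in self._mask_cache:
            self._mask_cache[key] = reclassify_dem(
                self.dem, sea_level_m, connectivity=self.connectivity
            )
        return self._mask_cache[key]

    def generate(self, period: TimePeriod, apply_mask: bool = True) -> BioclimStack:
        """Steps for one period: scale, calibrate, clip with its coastline."""
        factor = scale_factor(period.ts_c, self.curve)
        mask = self.land_mask(period.sea_level_m) if apply_mask else None
        out = BioclimStack(self.present.spec)
        stats: dict[str, dict[str, int]] = {}
        for var in self.variables:
            scaled = scale_delta(self.deltas[var], factor)
            layer, n_clamped = calibrate(
                self.isl[var], scaled,
                clamp_nonnegative=(None if self.clamp else False),
            )
            if mask is not None:
                layer = clip(layer, mask)
            out.add(layer)
            stats[var] = {"clamped": n_clamped, "missing": layer.n_missing}
        self.last_period_stats = {
            "age_kyr": period.age_kyr,
            "ts_c": period.ts_c,
            "sea_level_m": period.sea_level_m,
            "factor": factor,
            "variables": stats,
        }
        return out


def generate_period_stack(
    present: BioclimStack,
    lgm: BioclimStack,
    dem: ClimateRaster,
    curve: TemperatureCurve,
    period: TimePeriod,
    fill_config: FillConfig | None = None,
    clamp: bool = True,
) -> BioclimStack:
    """One-shot convenience wrapper over :class:`PeriodGenerator`.

    For many periods build a PeriodGenerator once and call ``generate``
    repeatedly — the ISP/ISL fill and Delta layers are then shared.
    """
    gen = PeriodGenerator(
        present, lgm, dem, curve,
        fill_config=fill_config or FillConfig(), clamp=clamp,
    )
    return gen.generate(period)
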