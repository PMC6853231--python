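"""Deterministic synthetic "world" generator for pipeline development/testing.

Real runs consume global 2.5-arc-minute bioclim grids, an ETOPO1-derived
DEM and an isotope-derived temperature/sea-level table.  Those are large
downloads; this module generates a miniature world with the statistical
structure the anomaly method assumes, so every stage is exercisable offline:

* spatially autocorrelated bioclim surfaces (white noise convolved with a
  Gaussian kernel) for any subset of bio1..bio19, with simple cross-variable
  construction rules (bio7 = bio5 - bio6 at generation time);
* an LGM stack that is a cooled (temperature ids, with a latitude-dependent
  amplification and per-variable cooling multipliers) and drier
  (precipitation ids, fractional reduction) perturbation of the present;
* a DEM with a continental core above sea level, a gently sloping shelf in
  (-120, 0] m of configurable width, deep ocean below -120 m, and optionally
  one walled depression below sea level (landlocked, never flooded);
* a sawtooth temperature curve over the full 20-5400 kyr BP lattice with
  eustatic sea level linearly coupled to temperature.

Everything derives from one seeded generator instance: same seed, same world.

What this world does **not** emulate: real topographic controls on climate,
monthly-climatology consistency among the 19 variables, ice sheets, and
true coastline geometry — so green tests here demonstrate the machinery,
not climatological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from oscillayers.chronology import (
    TS_LGM_C,
    TS_PRESENT_C,
    TemperatureCurve,
    TimePeriod,
    build_timeline,
)
from oscillayers.raster_core import (
    ALL_VARS,
    BioclimStack,
    ClimateRaster,
    GridSpec,
    PRECIPITATION_VARS,
    TEMPERATURE_VARS,
)

# Mean level and noise amplitude per variable, in each variable's native
# (plain, unscaled) units.  bio7 is derived as bio5 - bio6.
_BASE_AMP: dict[str, tuple[float, float]] = {
    "bio1": (18.0, 3.0), "bio2": (10.0, 2.0), "bio3": (50.0, 6.0),
    "bio4": (500.0, 100.0), "bio5": (28.0, 3.0), "bio6": (8.0, 3.0),
    "bio8": (20.0, 3.0), "bio9": (16.0, 3.0), "bio10": (24.0, 3.0),
    "bio11": (12.0, 3.0),
    "bio12": (1200.0, 300.0), "bio13": (200.0, 50.0), "bio14": (20.0, 8.0),
    "bio15": (40.0, 10.0), "bio16": (500.0, 120.0), "bio17": (80.0, 25.0),
    "bio18": (300.0, 80.0), "bio19": (150.0, 40.0),
}

# Per-variable multipliers on the mean LGM cooling: the coldest-month
# minimum (bio6) cools more than the warmest-month maximum (bio5), which
# keeps the derived annual range (bio7) anomaly nonzero.
_COOLING_MULT = {"bio5": 0.8, "bio6": 1.3}

_DEEP_OCEAN_M = -4000.0
_SHELF_BOTTOM_M = -120.0
_DEPRESSION_M = -30.0


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world.

    Defaults describe a 60x40-cell, 1-degree world spanning 30°S-10°N with a
    4-cell shelf, one landlocked depression, a mean LGM cooling equal to the
    4.44 °C global present-LGM contrast and 25% LGM drying.
    """

    ncols: int = 60
    nrows: int = 40
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = -30.0
    seed: int = 0
    autocorr_cells: float = 3.0
    lgm_cooling_c: float = TS_PRESENT_C - TS_LGM_C
    lgm_drying_frac: float = 0.25
    shelf_width_cells: int = 4
    depression: bool = True
    variables: tuple[str, ...] = ALL_VARS
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 8 or self.nrows < 8:
            raise ValueError("world must be at least 8x8 cells")
        if self.autocorr_cells < 1:
            raise ValueError("autocorr_cells must be >= 1")
        if not 0 <= self.lgm_drying_frac < 1:
            raise ValueError("lgm_drying_frac must be in [0, 1)")
        unknown = set(self.variables) - set(ALL_VARS)
        if unknown:
            raise ValueError(f"unknown variable ids {sorted(unknown)}")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            ncols=self.ncols, nrows=self.nrows,
            xllcorner=self.xllcorner, yllcorner=self.yllcorner,
            cellsize=self.cellsize, nodata_value=self.nodata_value,
        )


def smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field: filtered white noise."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (z - z.mean()) / max(z.std(), 1e-12)


def _make_dem(config: WorldConfig) -> np.ndarray:
    """Radial continent: core above 0 m, linear shelf, deep ocean, and
    optionally a small walled depression on the continental interior."""
    nr, nc = config.nrows, config.ncols
    ci, cj = (nr - 1) / 2.0, (nc - 1) / 2.0
    r_land = min(nr, nc) // 2 - config.shelf_width_cells - 3
    if r_land < 2:
        raise ValueError("grid too small for the requested shelf width")
    ii, jj = np.mgrid[0:nr, 0:nc]
    r = np.hypot(ii - ci, jj - cj)

    dem = np.full((nr, nc), _DEEP_OCEAN_M)
    shelf = (r > r_land) & (r <= r_land + config.shelf_width_cells)
    dem[shelf] = _SHELF_BOTTOM_M * (r[shelf] - r_land) / config.shelf_width_cells
    land = r <= r_land
    dem[land] = 5.0 + 600.0 * (1.0 - r[land] / (r_land + 1.0))
    if config.depression:
        di, dj = int(round(ci - r_land / 2.0)), int(round(cj))
        dem[di : di + 2, dj : dj + 2] = _DEPRESSION_M
    return dem


def _lat_grid(spec: GridSpec) -> np.ndarray:
    return np.broadcast_to(spec.y_centers()[:, None], spec.shape)


def make_curve(
    n_cycles: int = 5,
    ts_range: tuple[float, float] = (TS_LGM_C, TS_PRESENT_C),
    sealevel_range: tuple[float, float] = (-120.0, 0.0),
    ages: list[float] | None = None,
) -> TemperatureCurve:
    """Sawtooth temperature/sea-level curve over the full 10-kyr lattice.

    Temperature oscillates ``n_cycles`` times between the glacial and
    interglacial endpoints of ``ts_range`` (both attained exactly, the
    glacial endpoint at the 20-kyr LGM bin); sea level is a linear map of
    temperature onto ``sealevel_range``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    ages = ages if ages is not None else build_timeline()
    ages_arr = np.asarray(ages, dtype=float)
    t = (ages_arr - ages_arr[0]) / max(ages_arr[-1] - ages_arr[0], 1.0)
    frac = (n_cycles * t) % 1.0
    tri = np.where(frac <= 0.5, 2.0 * frac, 2.0 * (1.0 - frac))
    # rescale so both endpoints are attained exactly on the discrete lattice
    tri = (tri - tri.min()) / max(tri.max() - tri.min(), 1e-12)
    ts_lo, ts_hi = ts_range
    ts = ts_lo + tri * (ts_hi - ts_lo)
    sl_lo, sl_hi = sealevel_range
    sl = sl_lo + tri * (sl_hi - sl_lo)
    periods = [
        TimePeriod(age_kyr=float(a), ts_c=float(T), sea_level_m=float(s))
        for a, T, s in zip(ages_arr, ts, sl)
    ]
    return TemperatureCurve(periods, ts_present_c=ts_hi, ts_lgm_c=ts_lo)


def make_world(
    config: WorldConfig | None = None,
) -> tuple[BioclimStack, BioclimStack, ClimateRaster, TemperatureCurve]:
    """Generate (present stack, LGM stack, DEM, temperature curve).

    Both climate stacks are masked to the present coastline (DEM > 0 m),
    exactly as observational grids only cover today's land; the shelf is
    left for the gap-filling stage.  All randomness comes from one
    generator seeded by ``config.seed``.
    """
    config = config or WorldConfig()
    spec = config.spec
    rng = np.random.default_rng(config.seed)

    dem_values = _make_dem(config)
    dem = ClimateRaster(spec, dem_values, variable="dem")
    land_now = dem_values > 0.0
    lat = _lat_grid(spec)
    lat_cool = 1.0 + 0.5 * np.abs(lat) / 90.0  # glacial cooling grows poleward

    present = BioclimStack(spec)
    lgm = BioclimStack(spec)
    fields: dict[str, np.ndarray] = {}
    ordered = [v for v in config.variables if v != "bio7"]
    for var in ordered:
        base, amp = _BASE_AMP[var]
        f = base + amp * smooth_field(rng, spec.shape, config.autocorr_cells)
        if var in TEMPERATURE_VARS:
            f = f - 0.15 * np.abs(lat)  # gentle poleward cooling
        else:
            f = np.maximum(f, 0.0)
        fields[var] = f
    if "bio7" in config.variables:
        if not ("bio5" in fields and "bio6" in fields):
            raise ValueError("bio7 requires bio5 and bio6 in the variable set")
        fields["bio7"] = fields["bio5"] - fields["bio6"]

    for var in config.variables:
        pres_f = fields[var]
        if var == "bio7":
            mult5 = _COOLING_MULT.get("bio5", 1.0)
            mult6 = _COOLING_MULT.get("bio6", 1.0)
            lgm_f = pres_f - (mult5 - mult6) * config.lgm_cooling_c * lat_cool
        elif var in TEMPERATURE_VARS:
            mult = _COOLING_MULT.get(var, 1.0)
            lgm_f = pres_f - mult * config.lgm_cooling_c * lat_cool
        else:
            lgm_f = pres_f * (1.0 - config.lgm_drying_frac)
        present.add(ClimateRaster(spec, np.where(land_now, pres_f, np.nan), var))
        lgm.add(ClimateRaster(spec, np.where(land_now, lgm_f, np.nan), var))

    curve = make_curve()
    return present, lgm, dem, curve
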