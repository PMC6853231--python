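"""Palaeo-coastlines: sea-level reclassification of a DEM into land masks.

For each period, the DEM/bathymetry grid is reclassified against that
period's eustatic sea-level stand: cells above the stand are LAND, cells at
or below it that are connected to the ocean are SEA, and below-level cells
*not* connected to the ocean are LANDLOCKED_MISSING — land-enclosed
depressions (the Qattara Depression is the classic case) are not flooded but
carry no meaningful climate either, so they are treated as missing data.

Ocean connectivity is a flood fill (8-connected by default, so diagonal
straits count as water) seeded from all below-level cells on the grid border
— the borders of a global grid are polar or oceanic — plus an optional
explicit seed raster for regional crops whose borders are land.

This is pure eustatic reclassification of modern topography: no glacial
isostatic adjustment, no ice sheets, no tectonics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from oscillayers.raster_core import ClimateRaster, GridSpec, require_aligned, write_ascii_grid

LAND = 1
SEA = 0
LANDLOCKED_MISSING = 2

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class LandMask:
    """Per-cell land/sea/landlocked-missing labels for one sea-level stand."""

    spec: GridSpec
    state: np.ndarray  # int8 array of LAND / SEA / LANDLOCKED_MISSING
    sea_level_m: float

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.shape != self.spec.shape:
            raise ValueError(
                f"state shape {self.state.shape} != grid shape {self.spec.shape}"
            )

    @property
    def land(self) -> np.ndarray:
        return self.state == LAND

    @property
    def sea(self) -> np.ndarray:
        return self.state == SEA

    @property
    def landlocked_missing(self) -> np.ndarray:
        return self.state == LANDLOCKED_MISSING

    def n_land(self) -> int:
        return int(self.land.sum())


def reclassify_dem(
    dem: ClimateRaster,
    sea_level_m: float,
    connectivity: int = 8,
    ocean_seeds: np.ndarray | None = None,
) -> LandMask:
    """Classify DEM cells as LAND / SEA / LANDLOCKED_MISSING at a sea stand.

    Land is elevation strictly above ``sea_level_m`` (cells exactly at the
    stand are water).  Below-level cells are SEA when flood-fill-connected
    to the ocean seed set (below-level border cells plus any True cells of
    ``ocean_seeds``); otherwise LANDLOCKED_MISSING.  Missing DEM cells are
    labelled LANDLOCKED_MISSING.  All-land and all-sea DEMs are legal.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    elev = dem.values
    finite = np.isfinite(elev)
    with np.errstate(invalid="ignore"):
        above = finite & (elev > sea_level_m)
    below = finite & ~above

    seeds = np.zeros_like(below)
    seeds[0, :] = True
    seeds[-1, :] = True
    seeds[:, 0] = True
    seeds[:, -1] = True
    if ocean_seeds is not None:
        seeds |= np.asarray(ocean_seeds, dtype=bool)
    seeds &= below

    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n_comp = ndimage.label(below, structure=structure)
    if n_comp:
        ocean_ids = np.unique(labels[seeds])
        ocean_ids = ocean_ids[ocean_ids > 0]
        is_sea = np.isin(labels, ocean_ids) & below
    else:
        is_sea = np.zeros_like(below)

    state = np.full(dem.spec.shape, LANDLOCKED_MISSING, dtype=np.int8)
    state[above] = LAND
    state[is_sea] = SEA
    return LandMask(dem.spec, state, sea_level_m)


def clip(raster: ClimateRaster, mask: LandMask) -> ClimateRaster:
    """Keep values on LAND cells; SEA and LANDLOCKED_MISSING become missing.

    Surviving values are passed through exactly.
    """
    require_aligned(raster.spec, mask.spec, "raster vs land mask")
    out = np.where(mask.land, raster.values, np.nan)
    return raster.with_values(out)


def exclude_latitudes(mask: LandMask, south_cut_deg: float = -60.0) -> LandMask:
    """Mask out LAND cells south of a latitude cut (default 60°S, i.e.
    Antarctica and the Southern Ocean islands are dropped from the land set).
    """
    lat = mask.spec.y_centers()[:, None]  # north-first column vector
    cut = (lat < south_cut_deg) & mask.land
    state = mask.state.copy()
    state[np.broadcast_to(cut, state.shape)] = LANDLOCKED_MISSING
    return LandMask(mask.spec, state, mask.sea_level_m)


def write_mask(mask: LandMask, path: str | Path) -> None:
    """Write as ESRI ASCII: LAND=1, SEA=0, LANDLOCKED_MISSING=nodata."""
    vals = np.where(
        mask.landlocked_missing, np.nan, mask.state.astype(float)
    )
    raster = ClimateRaster(mask.spec, vals, variable="landmask")
    write_ascii_grid(raster, path, decimals=0)
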