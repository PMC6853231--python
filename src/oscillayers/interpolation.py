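"""Shelf gap-filling: extend climate surfaces over now-submerged cells.

Present-day climate grids only cover today's land.  During glacials, sea
level drops expose continental shelf, so the anomaly pipeline needs climate
estimates there for both the present and the LGM baseline.  Under the
assumption that off-coast climate is spatially correlated with coastal
climate, any exact local interpolator can extend the surfaces a short
distance offshore.  Two are provided:

* inverse-distance weighting (IDW, the default) with a configurable power
  and neighbour count, and
* ordinary kriging with an exponential or spherical variogram fitted to the
  source cells by method-of-moments + least squares.

Both are *exact*: originally valid cells are never altered.  Cells farther
than ``search_radius_cells`` from any source stay missing, so mid-ocean
cells never receive long-range extrapolations.

Distances are Euclidean in degree space on cell centers — adequate for the
shelf-local use this module serves, increasingly distorted toward the poles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from oscillayers.raster_core import ClimateRaster, require_aligned

logger = logging.getLogger(__name__)

#: Extra KD-tree candidates queried beyond max_neighbors so that equidistant
#: candidates can be re-sorted deterministically by (distance, row, col).
_TIE_SLACK = 8


@dataclass(frozen=True)
class FillConfig:
    """Parameters of the shelf gap-fill.

    method:
        'idw' or 'ordinary_kriging'.
    idw_power:
        IDW distance exponent (2 = inverse-square).
    max_neighbors:
        Number of nearest source cells feeding each filled cell.
    search_radius_cells:
        Maximum source distance in cell widths; farther targets stay missing.
    variogram_model:
        'exponential' or 'spherical' (kriging only).
    """

    method: str = "idw"
    idw_power: float = 2.0
    max_neighbors: int = 12
    search_radius_cells: int = 25
    variogram_model: str = "exponential"

    def __post_init__(self) -> None:
        if self.method not in ("idw", "ordinary_kriging"):
            raise ValueError(f"unknown fill method {self.method!r}")
        if self.variogram_model not in ("exponential", "spherical"):
            raise ValueError(f"unknown variogram model {self.variogram_model!r}")
        if self.idw_power <= 0 or self.max_neighbors <= 0 or self.search_radius_cells <= 0:
            raise ValueError("FillConfig parameters must be positive")


def shelf_target_mask(dem: ClimateRaster, lowest_sea_level_m: float) -> np.ndarray:
    """Cells that become land at some point in the timeline.

    True exactly where elevation is <= 0 (submerged today) and strictly above
    the lowest sea-level stand (exposed at the glacial maximum coastline).
    """
    elev = dem.values
    with np.errstate(invalid="ignore"):
        return (elev <= 0) & (elev > lowest_sea_level_m) & np.isfinite(elev)


def _cell_points(raster: ClimateRaster, mask: np.ndarray) -> np.ndarray:
    """(n, 2) array of (x, y) degree coordinates of cell centers under mask."""
    rows, cols = np.nonzero(mask)
    xc = raster.spec.x_centers()
    yc = raster.spec.y_centers()
    return np.column_stack([xc[cols], yc[rows]])


def _neighbor_lists(
    raster: ClimateRaster,
    src_mask: np.ndarray,
    tgt_mask: np.ndarray,
    config: FillConfig,
):
    """For each target cell, its nearest source cells within the radius.

    Returns (tgt_rows, tgt_cols, list of (distances, values) per target).
    Ties at equal distance are broken by (row, col) ascending within the
    candidate slack so outputs are reproducible.
    """
    src_rows, src_cols = np.nonzero(src_mask)
    src_pts = _cell_points(raster, src_mask)
    src_vals = raster.values[src_rows, src_cols]
    tree = cKDTree(src_pts)

    tgt_rows, tgt_cols = np.nonzero(tgt_mask)
    tgt_pts = _cell_points(raster, tgt_mask)
    radius = config.search_radius_cells * raster.spec.cellsize
    k = min(config.max_neighbors + _TIE_SLACK, len(src_pts))
    dists, idxs = tree.query(tgt_pts, k=k, distance_upper_bound=radius * (1 + 1e-12))
    if k == 1:
        dists = dists[:, None]
        idxs = idxs[:, None]

    neighbors = []
    n_src = len(src_pts)
    for d_row, i_row in zip(dists, idxs):
        ok = i_row < n_src
        d, i = d_row[ok], i_row[ok]
        if d.size == 0:
            neighbors.append(None)
            continue
        order = np.lexsort((src_cols[i], src_rows[i], np.round(d, 12)))
        d, i = d[order][: config.max_neighbors], i[order][: config.max_neighbors]
        neighbors.append((d, src_vals[i], src_pts[i]))
    return tgt_rows, tgt_cols, neighbors


# ---------------------------------------------------------------------------
# Variogram fitting for ordinary kriging


def _variogram_func(model: str):
    if model == "exponential":
        def gamma(h, sill, rng):
            return sill * (1.0 - np.exp(-3.0 * h / rng))
    else:  # spherical
        def gamma(h, sill, rng):
            h = np.asarray(h, dtype=float)
            out = np.where(
                h < rng,
                sill * (1.5 * h / rng - 0.5 * (h / rng) ** 3),
                sill,
            )
            return out
    return gamma


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    model: str = "exponential",
    n_bins: int = 12,
    max_pairs: int = 20000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Fit (sill, range) of a variogram model to scattered data.

    Empirical semivariances are computed on a subsample of point pairs
    (method of moments), binned by separation, and fitted by least squares.
    Falls back to (variance, half max separation) when fitting fails.
    """
    n = len(points)
    rng = np.random.default_rng(rng_seed)
    if n * (n - 1) // 2 > max_pairs:
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        keep = i != j
        i, j = i[keep], j[keep]
    else:
        i, j = np.triu_indices(n, k=1)
    h = np.hypot(*(points[i] - points[j]).T)
    sv = 0.5 * (values[i] - values[j]) ** 2

    hmax = h.max() if h.size else 1.0
    fallback = (max(float(np.var(values)), 1e-12), max(hmax / 2.0, 1e-9))
    if h.size < n_bins:
        return fallback
    edges = np.linspace(0, hmax, n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    bh, bg = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() >= 3:
            bh.append(h[sel].mean())
            bg.append(sv[sel].mean())
    if len(bh) < 3:
        return fallback
    gamma = _variogram_func(model)
    try:
        (sill, rng_), _ = curve_fit(
            gamma, np.array(bh), np.array(bg),
            p0=fallback, bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=2000,
        )
        return float(sill), float(rng_)
    except RuntimeError:
        logger.warning("variogram fit failed; using moment fallback")
        return fallback


def kriging_weights(
    neighbor_pts: np.ndarray,
    target_pt: np.ndarray,
    gamma,
    sill: float,
    rng: float,
) -> np.ndarray:
    """Solve the ordinary-kriging system for one target cell."""
    m = len(neighbor_pts)
    d_nn = np.hypot(
        *(neighbor_pts[:, None, :] - neighbor_pts[None, :, :]).transpose(2, 0, 1)
    )
    a = np.empty((m + 1, m + 1))
    a[:m, :m] = gamma(d_nn, sill, rng)
    a[m, :] = 1.0
    a[:, m] = 1.0
    a[m, m] = 0.0
    d_t = np.hypot(*(neighbor_pts - target_pt).T)
    b = np.empty(m + 1)
    b[:m] = gamma(d_t, sill, rng)
    b[m] = 1.0
    try:
        w = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(a, b, rcond=None)[0]
    return w[:m]


def fill_surface(
    raster: ClimateRaster,
    target_mask: np.ndarray,
    config: FillConfig | None = None,
) -> ClimateRaster:
    """Fill missing target cells from nearby valid cells.

    Originally valid cells are returned unchanged (exact interpolator
    contract).  Target cells (True in ``target_mask`` and missing in the
    input) within ``search_radius_cells`` of a source cell receive an
    interpolated value from their ``max_neighbors`` nearest sources;
    unreachable targets stay missing and are counted in the log.
    """
    config = config or FillConfig()
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.shape != raster.spec.shape:
        raise ValueError(
            f"target mask shape {target_mask.shape} != grid shape {raster.spec.shape}"
        )
    src_mask = raster.valid
    if not src_mask.any():
        raise ValueError("fill_surface requires at least one valid source cell")
    todo = target_mask & ~src_mask
    out = raster.values.copy()
    if not todo.any():
        return raster.with_values(out)

    tgt_rows, tgt_cols, neighbors = _neighbor_lists(raster, src_mask, todo, config)

    if config.method == "ordinary_kriging":
        src_pts = _cell_points(raster, src_mask)
        src_vals = raster.values[src_mask]
        sill, rng_ = fit_variogram(src_pts, src_vals, model=config.variogram_model)
        gamma = _variogram_func(config.variogram_model)
        logger.info("kriging variogram %s: sill=%.4g range=%.4g",
                    config.variogram_model, sill, rng_)

    xc = raster.spec.x_centers()
    yc = raster.spec.y_centers()
    n_unreachable = 0
    for r, c, nb in zip(tgt_rows, tgt_cols, neighbors):
        if nb is None:
            n_unreachable += 1
            continue
        d, v, pts = nb
        if config.method == "idw":
            w = 1.0 / np.maximum(d, 1e-300) ** config.idw_power
            out[r, c] = np.dot(w, v) / w.sum()
        else:
            w = kriging_weights(pts, np.array([xc[c], yc[r]]), gamma, sill, rng_)
            out[r, c] = np.dot(w, v)
    if n_unreachable:
        logger.info(
            "fill_surface(%s): %d target cells beyond search radius left missing",
            raster.variable, n_unreachable,
        )
    return raster.with_values(out)
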