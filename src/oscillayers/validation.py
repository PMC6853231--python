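"""Raster validation statistics: pattern correlation, difference quantiles,
and Delta-method downscaling of coarse model snapshots.

Two layers are compared over their *jointly valid* cells only (pairwise-
complete masking; the cell count is always reported so the masking choice is
auditable).  The skill metric is Pearson's pattern correlation r; agreement
in absolute terms is summarised by the 2.5% and 97.5% quantiles of the
cellwise absolute difference, using the linear-interpolation quantile
definition.

``delta_downscale`` implements the classic Delta method for bringing a
coarse model snapshot onto a fine observational grid: the coarse anomaly
(palaeo minus baseline) is interpolated (bilinear by default) to the fine
cell centers and added to the fine baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import pearsonr

from oscillayers.raster_core import BioclimStack, ClimateRaster, require_aligned


@dataclass(frozen=True)
class ComparisonResult:
    """Pattern agreement between two layers of one variable."""

    variable: str
    pearson_r: float
    q_low: float
    q_high: float
    n_cells: int


def _joint_values(a: ClimateRaster, b: ClimateRaster) -> tuple[np.ndarray, np.ndarray]:
    require_aligned(a.spec, b.spec, "comparison rasters")
    joint = a.valid & b.valid
    return a.values[joint], b.values[joint]


def pattern_correlation(a: ClimateRaster, b: ClimateRaster) -> float:
    """Pearson r over the jointly valid cells of two aligned rasters."""
    va, vb = _joint_values(a, b)
    if va.size < 3:
        raise ValueError(f"need >= 3 jointly valid cells, have {va.size}")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("undefined correlation: zero variance in an input")
    return float(pearsonr(va, vb).statistic)


def abs_diff_quantiles(
    a: ClimateRaster,
    b: ClimateRaster,
    probs: tuple[float, float] = (0.025, 0.975),
) -> tuple[float, float]:
    """Quantiles of |a - b| over jointly valid cells (linear interpolation)."""
    va, vb = _joint_values(a, b)
    if va.size == 0:
        raise ValueError("no jointly valid cells")
    lo, hi = np.quantile(np.abs(va - vb), probs, method="linear")
    return float(lo), float(hi)


def delta_downscale(
    coarse_paleo: ClimateRaster,
    coarse_baseline: ClimateRaster,
    fine_baseline: ClimateRaster,
    method: str = "bilinear",
) -> ClimateRaster:
    """Delta-method downscaling of a coarse palaeo snapshot to a fine grid.

    The coarse anomaly (palaeo - baseline) is interpolated to the fine cell
    centers (bilinear by default, 'nearest' available) and added to the fine
    baseline; output is missing exactly where the fine baseline is missing.
    """
    require_aligned(coarse_paleo.spec, coarse_baseline.spec, "coarse grids")
    cw, cs, ce, cn = coarse_baseline.spec.extent()
    fw, fs, fe, fn = fine_baseline.spec.extent()
    if fe <= cw or fw >= ce or fn <= cs or fs >= cn:
        raise ValueError("fine grid does not overlap the coarse extent")

    anomaly = coarse_paleo.values - coarse_baseline.values
    # RegularGridInterpolator needs ascending axes; internal rows are
    # north-first so the y axis is flipped.
    cy = coarse_baseline.spec.y_centers()[::-1]
    cx = coarse_baseline.spec.x_centers()
    interp = RegularGridInterpolator(
        (cy, cx), anomaly[::-1, :],
        method=("linear" if method == "bilinear" else method),
        bounds_error=False, fill_value=None,  # extrapolate past edge centers
    )
    fy = fine_baseline.spec.y_centers()
    fx = fine_baseline.spec.x_centers()
    yy, xx = np.meshgrid(fy, fx, indexing="ij")
    fine_anom = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(yy.shape)
    out = fine_baseline.values + fine_anom
    out = np.where(fine_baseline.valid, out, np.nan)
    return fine_baseline.with_values(out, coarse_paleo.variable)


def compare_stacks(
    a: BioclimStack,
    b: BioclimStack,
    report_path: str | Path | None = None,
    probs: tuple[float, float] = (0.025, 0.975),
) -> list[ComparisonResult]:
    """Per-variable pattern correlation and difference quantiles.

    Optionally writes a CSV report with columns
    variable, pearson_r, q025, q975, n_cells.
    """
    shared = [v for v in a.variables if v in b]
    if not shared:
        raise ValueError("stacks share no variable ids")
    results = []
    for var in shared:
        ra, rb = a[var], b[var]
        joint = ra.valid & rb.valid
        r = pattern_correlation(ra, rb)
        lo, hi = abs_diff_quantiles(ra, rb, probs)
        results.append(ComparisonResult(var, r, lo, hi, int(joint.sum())))
    if report_path is not None:
        df = pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    "pearson_r": c.pearson_r,
                    "q025": c.q_low,
                    "q975": c.q_high,
                    "n_cells": c.n_cells,
                }
                for c in results
            ]
        )
        Path(report_path).parent.mkdir(parents=True, exist_ok=True)
        with open(report_path, "w") as fh:
            fh.write("# quantiles: linear interpolation between order statistics; "
                     "cells: pairwise-complete\n")
            df.to_csv(fh, index=False)
    return results
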