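# Methods

## Model

The package treats palaeoclimate reconstruction as a scaled-anomaly
problem.  Two anchor states of each bioclim variable are taken as known on
a common grid: the present and the Last Glacial Maximum (LGM, fixed at the
20 kyr BP bin).  Their difference after shelf gap-filling,
`Δ = ISP − ISL`, is assumed to be the *shape* of glacial–interglacial
climate change at every cell; only its *amplitude* varies through time,
driven by the global mean surface temperature curve:

```
Bio_T = ISL + f(T) · Δ,      f(T) = (Ts_T − Ts_LGM) / (Ts_present − Ts_LGM)
```

The assumptions this encodes, and their consequences:

* **Pattern stationarity.** Every period's climate is a linear mixture of
  the two anchors.  Periods whose circulation differed qualitatively from
  both anchors (e.g. warmer-than-present Pliocene states, f > 1, obtained
  by extrapolation) are reconstructed less faithfully, and uncertainty
  grows with age.
* **One global scalar.** All 19 variables at all cells share the same
  factor f(T); there is no regional or seasonal modulation beyond what Δ
  itself carries.
* **Modern geography.** Coastlines respond only to eustatic sea level via
  reclassified modern topography; no isostasy, ice sheets or tectonics.
* **Additive anomalies for all variables**, precipitation included.  A
  ratio-based precipitation anomaly is a deliberate non-goal; instead,
  negative precipitation produced by large negative scaled anomalies is
  clamped to zero, with the clamp count logged per layer and a switch to
  disable it.  Temperature variables are never clamped.
* **No cross-variable repair.** Each variable is scaled independently;
  internal consistency such as bio7 = bio5 − bio6 is not enforced on
  outputs (the synthetic generator builds it into its inputs, and
  violations in real data pass through unrepaired).

The calibration baseline is ISL (the gap-filled LGM surface) rather than
the raw LGM grid: offshore shelf cells exist only in ISL, and at f = 1 the
algebra `ISL + (ISP − ISL) = ISP` still recovers the present surface
exactly, so nothing is lost on land.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `ts_present_c`, `ts_lgm_c` | 13.90, 9.46 | °C | anchor span 4.44 °C; curve metadata, overridable per run |
| timeline | 20–5400 step 10 | kyr BP | 539 periods; LGM bin at 20 kyr |
| `FillConfig.method` | `idw` | — | `ordinary_kriging` optional |
| `idw_power` | 2 | — | inverse-square weighting |
| `max_neighbors` | 12 | cells | nearest sources per filled cell |
| `search_radius_cells` | 25 | cells | beyond it, cells stay missing (no long-range extrapolation into mid-ocean) |
| `variogram_model` | exponential | — | spherical optional; sill/range fitted by binned method-of-moments + least squares |
| connectivity | 8 | — | ocean flood fill; 4 available (diagonal straits then block) |
| land rule | elev > sea level | m | cells exactly at the stand are water |
| south cut | −60 | °lat | `exclude_latitudes` masks Antarctic land |
| output decimals | 4 | digits | exposed because distributed ASCII precision is a user choice |

## Shelf gap-filling

The original workflow used a proprietary empirical Bayesian kriging tool
with unpublished settings.  Since the step's only job is to extend coastal
values a short distance offshore under an assumption of spatial
correlation, this package provides two documented exact interpolators
instead — IDW (default) and ordinary kriging — and the validation module
measures the consequences.  Both operate on cell centers as points in
degree space (no great-circle distances): adequate for shelf-local
interpolation, increasingly distorted poleward, a documented limitation.
Neighbour ties at equal distance are broken by (row, col) ascending within
an 8-candidate slack beyond `max_neighbors`, making outputs reproducible;
exact equidistance past that slack is not re-sorted (vanishingly rare off
a perfectly regular integer lattice).

## Coastlines

A period's mask is `reclassify_dem(dem, sea_level)`: LAND strictly above
the stand; below-stand cells flood-filled from the ocean seed set (all
below-stand border cells, since a global grid's borders are polar or
oceanic, plus an optional explicit seed raster for regional crops whose
borders are land); unreachable below-stand cells are LANDLOCKED_MISSING —
never flooded, but carrying no meaningful climate, so masked.  With the
strict inequality, the land set is non-decreasing as sea level falls
(verified across the full sawtooth series).  Masks are cached per distinct
sea-level stand, so a 539-period run reclassifies only as many times as
there are distinct stands.

## Validation statistics

Pearson r and the 2.5/97.5 % absolute-difference quantiles are computed on
exactly the jointly valid (pairwise-complete) cell set, with `n_cells`
always reported to keep the masking auditable.  Quantiles use linear
interpolation between order statistics (stated in the report header).  The
Delta-method downscaler transfers the coarse anomaly by bilinear
interpolation on cell centers (nearest-neighbour available); fine cells
within half a coarse cell of the edge receive linear extrapolation, which
keeps affine anomaly fields exact everywhere.  No significance testing is
attached to r.

## The synthetic world

`make_world` emulates exactly the statistical structure the method
assumes, at desk scale: a 60×40-cell, 1° grid spanning 30°S–10°N (the
size used throughout the test suite and the acceptance run), spatially
autocorrelated surfaces (unit-variance white noise smoothed with a
Gaussian kernel of 3 cells), a radial continent with a 4-cell shelf in
(−120, 0] m, deep ocean, and a 2×2 walled depression at −30 m; an LGM
stack that is the present minus a mean cooling of 4.44 °C — the global
present−LGM anchor span, amplified 1.5× at 90° latitude and modulated per
variable so the derived annual range keeps a nonzero anomaly — and minus
25 % precipitation, a typical glacial-drying magnitude; and a sawtooth
curve of 5 glacial cycles whose temperature attains both anchors exactly
on the 539-age lattice, with sea level a linear map of temperature onto
[−120, 0] m.  One seeded generator instance produces everything; no global
RNG state.

What the world does **not** emulate — and hence what green tests do not
show about real data: orographic and maritime controls on climate, the
true covariance structure among the 19 variables (all temperature
variables share one cooling field, so their anomalies are identical up to
multipliers), realistic coastline geometry, and measurement noise in the
anchor grids.  Tests on this world verify the *machinery* (algebra,
masking, I/O, determinism, oracle equivalence), not climatological skill;
skill against independent GCMs requires the real input grids.

## Numerical choices

* Missing data are NaN internally and the grid's nodata sentinel (−9999
  default) on disk; header registration is normalised to corner form on
  read (center-registered headers shifted by half a cell).
* Grid alignment tolerance 1e-9 degrees — absorbs decimal-printing jitter
  without masking real misalignment.
* Header coordinates are written with full `repr` precision; data cells
  with a fixed number of decimals, so `read(write(r, d))` agrees with `r`
  to 0.5·10⁻ᵈ per cell and reproduces the missing pattern exactly, and
  identically configured runs are byte-identical.
* Units pass through untouched (e.g. °C×10 conventions in some
  distributions): the anomaly algebra is unit-agnostic.
* The curve table is interpolated onto the 10-kyr lattice linearly by
  default (nearest-neighbour available, logged); anchors are curve
  metadata, not read off the period list, so a curve need not contain an
  exact 20-kyr row.
* Degenerate inputs: all-land and all-sea DEMs are legal masks; zero
  valid source cells is an error for gap-filling; correlation requires
  ≥ 3 joint cells and nonzero variance on both sides.

## Problem sizes

The default test and acceptance configuration runs the complete
539-period × 19-variable pipeline on the 60×40 synthetic grid (about half
a minute, dominated by ASCII output); determinism is checked bytewise on a
51-period subset run twice.  Real global 2.5′ runs are supported by the
same code paths via region subsetting (`crop`/`--bbox`) and period
subsetting, which is also how the layers are meant to be consumed.

## Known limitations

Planar degree-space distances in the interpolators; no glacial isostatic
adjustment or ice-sheet masking; no reprojection (everything is geographic
lat/lon); no recomputation of bioclim variables from monthly
climatologies; the kriging variogram fit is a pragmatic moment estimator,
not a simulation-based ensemble.
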