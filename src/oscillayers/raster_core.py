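"""Raster data model and ESRI ASCII grid I/O.

Everything downstream (interpolation, anomaly algebra, coastline masks,
validation statistics) operates on :class:`ClimateRaster` objects sharing a
:class:`GridSpec`.  The on-disk contract of record is the ESRI ASCII grid
(``.asc``): a short whitespace-separated header followed by rows of values
running north to south.  Internal row order matches file order (row 0 is the
northernmost row) so I/O never flips arrays.

Missing data are carried as NaN internally and as the grid's nodata sentinel
on disk.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

#: Alignment tolerance in degrees: absorbs decimal-printing jitter in headers
#: without masking genuine misalignment.
ALIGNMENT_TOL = 1e-9

#: Kilometres per degree of arc used for nominal cell areas.  111.6 reproduces
#: the conventional 4.65 km side of a 2.5 arc-minute cell at the equator.
KM_PER_DEGREE = 111.6

TEMPERATURE_VARS = tuple(f"bio{i}" for i in range(1, 12))
PRECIPITATION_VARS = tuple(f"bio{i}" for i in range(12, 20))
ALL_VARS = TEMPERATURE_VARS + PRECIPITATION_VARS


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a geographic raster: dims, lower-left corner, cell size.

    ``xllcorner``/``yllcorner`` are the coordinates of the outer corner of the
    lower-left (south-west) cell, in decimal degrees, matching the ESRI ASCII
    corner-registered convention.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError(f"grid dims must be >= 1, got {self.ncols}x{self.nrows}")
        if not self.cellsize > 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def aligned_with(self, other: "GridSpec", tol: float = ALIGNMENT_TOL) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
            and abs(self.nodata_value - other.nodata_value) <= tol
        )

    def x_centers(self) -> np.ndarray:
        """Longitudes of cell centers, west to east (length ncols)."""
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Latitudes of cell centers in internal row order, north to south."""
        return self.yllcorner + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds in degrees."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )


def require_aligned(a: GridSpec, b: GridSpec, what: str = "rasters") -> None:
    if not a.aligned_with(b):
        raise ValueError(f"misaligned {what}: {a} vs {b}")


@dataclass
class ClimateRaster:
    """One gridded variable with missing data.

    ``values`` is a float array of shape (nrows, ncols) with NaN at missing
    cells; row 0 is the northernmost row.  ``variable`` is a bioclim id
    (``bio1`` .. ``bio19``) or any other identifier (``dem``, ``mask`` ...).
    """

    spec: GridSpec
    values: np.ndarray
    variable: str = "bio1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask, True where the cell holds a finite value."""
        return np.isfinite(self.values)

    @property
    def n_missing(self) -> int:
        return int((~self.valid).sum())

    def copy(self) -> "ClimateRaster":
        return ClimateRaster(self.spec, self.values.copy(), self.variable)

    def with_values(self, values: np.ndarray, variable: str | None = None) -> "ClimateRaster":
        return ClimateRaster(self.spec, values, variable or self.variable)


@dataclass
class BioclimStack:
    """A set of aligned ClimateRasters keyed by variable id."""

    spec: GridSpec
    layers: dict[str, ClimateRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, r in self.layers.items():
            require_aligned(self.spec, r.spec, f"stack layer {var}")

    def add(self, raster: ClimateRaster) -> None:
        require_aligned(self.spec, raster.spec, f"stack layer {raster.variable}")
        if raster.variable in self.layers:
            raise ValueError(f"duplicate variable id {raster.variable!r}")
        self.layers[raster.variable] = raster

    def __getitem__(self, var: str) -> ClimateRaster:
        return self.layers[var]

    def __contains__(self, var: str) -> bool:
        return var in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def variables(self) -> list[str]:
        return list(self.layers)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = {
    "ncols", "nrows", "xllcorner", "xllcenter", "yllcorner", "yllcenter",
    "cellsize", "nodata_value",
}


class AsciiGridError(ValueError):
    """Malformed ESRI ASCII grid."""


def _parse_header(lines: list[str], path: str) -> tuple[dict[str, float], int]:
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise AsciiGridError(
                    f"{path}: cannot parse header line {i + 1}: {line.strip()!r}"
                ) from exc
        else:
            break
    else:
        i += 1
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise AsciiGridError(f"{path}: header missing {required!r}")
    if "xllcorner" not in header and "xllcenter" not in header:
        raise AsciiGridError(f"{path}: header missing xllcorner/xllcenter")
    if "yllcorner" not in header and "yllcenter" not in header:
        raise AsciiGridError(f"{path}: header missing yllcorner/yllcenter")
    return header, i


def read_ascii_grid(path: str | Path, variable: str | None = None) -> ClimateRaster:
    """Read an ESRI ASCII grid into a :class:`ClimateRaster`.

    Header keywords are case-insensitive; center-registered headers
    (``xllcenter``/``yllcenter``) are converted to corner registration by
    subtracting half a cell.  A missing ``NODATA_value`` defaults to -9999.
    The first data row is the northernmost.

    Parameters
    ----------
    path:
        File to read.
    variable:
        Variable id to attach; defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    header, n_header = _parse_header(lines, str(path))

    cellsize = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2.0)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2.0)
    spec = GridSpec(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=xll,
        yllcorner=yll,
        cellsize=cellsize,
        nodata_value=header.get("nodata_value", -9999.0),
    )

    data_str = "\n".join(lines[n_header:])
    try:
        flat = np.array(data_str.split(), dtype=float)
    except ValueError as exc:
        raise AsciiGridError(f"{path}: non-numeric data token") from exc
    expected = spec.ncols * spec.nrows
    if flat.size != expected:
        raise AsciiGridError(
            f"{path}: expected {expected} data cells ({spec.nrows}x{spec.ncols}), found {flat.size}"
        )
    values = flat.reshape(spec.nrows, spec.ncols)
    values[np.isclose(values, spec.nodata_value, rtol=0, atol=1e-9)] = np.nan
    return ClimateRaster(spec, values, variable or path.stem)


def _format_nodata(nodata: float) -> str:
    if float(nodata).is_integer():
        return str(int(nodata))
    return repr(float(nodata))


def write_ascii_grid(raster: ClimateRaster, path: str | Path, decimals: int = 4) -> None:
    """Write a raster as a corner-registered ESRI ASCII grid.

    Values are printed with ``decimals`` fractional digits; missing cells are
    printed as the nodata sentinel verbatim.  Rows run north to south.
    """
    path = Path(path)
    spec = raster.spec
    nodata_tok = _format_nodata(spec.nodata_value)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {float(spec.xllcorner)!r}\n"
        f"yllcorner {float(spec.yllcorner)!r}\n"
        f"cellsize {float(spec.cellsize)!r}\n"
        f"NODATA_value {nodata_tok}\n"
    )
    vals = raster.values
    valid = np.isfinite(vals)
    fmt = f"%.{decimals}f"
    tokens = np.where(valid, np.char.mod(fmt, np.where(valid, vals, 0.0)), nodata_tok)
    body = "\n".join(" ".join(row) for row in tokens)
    path.write_text(header + body + "\n")


def crop(raster: ClimateRaster, bbox: tuple[float, float, float, float]) -> ClimateRaster:
    """Extract the sub-grid of whole cells whose centers fall inside ``bbox``.

    ``bbox`` is (west, south, east, north) in degrees.  The output grid origin
    stays on the input cell lattice; no resampling occurs.
    """
    west, south, east, north = bbox
    spec = raster.spec
    xc = spec.x_centers()
    yc = spec.y_centers()  # north to south
    cols = np.nonzero((xc >= west) & (xc <= east))[0]
    rows = np.nonzero((yc >= south) & (yc <= north))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError(f"bbox {bbox} does not cover any cell center of {spec}")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    new_spec = GridSpec(
        ncols=c1 - c0,
        nrows=r1 - r0,
        xllcorner=spec.xllcorner + c0 * spec.cellsize,
        yllcorner=spec.yllcorner + (spec.nrows - r1) * spec.cellsize,
        cellsize=spec.cellsize,
        nodata_value=spec.nodata_value,
    )
    return ClimateRaster(new_spec, raster.values[r0:r1, c0:c1].copy(), raster.variable)


def cell_area_km2(
    spec: GridSpec | float,
    latitude: float,
    km_per_degree: float = KM_PER_DEGREE,
) -> float:
    """Nominal area of one grid cell at a given latitude, in km².

    Uses the cylindrical approximation side_x = cellsize * K * cos(lat),
    side_y = cellsize * K with K km per degree (default 111.6, which gives
    the conventional 2.5-arc-minute cell side of 4.65 km at the equator).
    """
    if abs(latitude) >= 90:
        raise ValueError(f"|latitude| must be < 90, got {latitude}")
    cellsize = spec.cellsize if isinstance(spec, GridSpec) else float(spec)
    side = cellsize * km_per_degree
    return side * side * math.cos(math.radians(latitude))


def read_stack(directory: str | Path, variables: list[str] | None = None) -> BioclimStack:
    """Read every ``bio*.asc`` file in a directory into a stack."""
    directory = Path(directory)
    paths = sorted(
        directory.glob("bio*.asc"),
        key=lambda p: int(re.sub(r"\D", "", p.stem) or 0),
    )
    if variables is not None:
        wanted = set(variables)
        paths = [p for p in paths if p.stem in wanted]
    if not paths:
        raise FileNotFoundError(f"no bio*.asc layers found in {directory}")
    first = read_ascii_grid(paths[0])
    stack = BioclimStack(first.spec, {first.variable: first})
    for p in paths[1:]:
        stack.add(read_ascii_grid(p))
    return stack


def write_stack(stack: BioclimStack, directory: str | Path, decimals: int = 4) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for var, raster in stack.layers.items():
        write_ascii_grid(raster, directory / f"{var}.asc", decimals=decimals)
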