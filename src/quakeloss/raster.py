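"""Georeferenced raster grids and ESRI ASCII grid I/O.

All grids are geographic (WGS84 lon/lat), cell-center registered, row 0 of
the value array being the northernmost row (the on-disk ESRI ASCII order).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "Raster",
    "IntensityGrid",
    "PopulationGrid",
    "PGVGrid",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of a geographic raster.

    Parameters
    ----------
    origin_lon, origin_lat : float
        Longitude/latitude of the *center* of the lower-left cell, degrees.
    cell_size : float
        Cell edge length in degrees (square cells).
    nrows, ncols : int
        Grid dimensions.
    crs : str
        Coordinate reference system tag; only ``"WGS84"`` is supported.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    nrows: int
    ncols: int
    crs: str = "WGS84"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) 2-D arrays of cell-center coordinates.

        Row 0 is the northernmost row, matching the value-array layout.
        """
        lon = self.origin_lon + np.arange(self.ncols) * self.cell_size
        lat_south_up = self.origin_lat + np.arange(self.nrows) * self.cell_size
        lat = lat_south_up[::-1]  # row 0 = north
        return np.meshgrid(lon, lat)

    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the cell-center bounding box."""
        return (
            self.origin_lon,
            self.origin_lon + (self.ncols - 1) * self.cell_size,
            self.origin_lat,
            self.origin_lat + (self.nrows - 1) * self.cell_size,
        )


@dataclasses.dataclass
class Raster:
    """A GridSpec plus a 2-D value array (row 0 = north)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"grid spec shape {self.spec.shape}"
            )


class IntensityGrid(Raster):
    """Continuous macroseismic intensity per cell (typically 1-12)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")


class PGVGrid(Raster):
    """Peak ground velocity per cell, m/s, non-negative."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PGV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("PGV values must be non-negative")


class PopulationGrid(Raster):
    """Persons per cell. NODATA cells are treated as zero persons.

    The count of nodata cells replaced by zero is kept in ``nodata_count``
    so downstream diagnostics can report it rather than silently dropping it.
    """

    nodata_count: int = 0

    def __init__(self, spec: GridSpec, values: np.ndarray, nodata: float | None = None):
        values = np.asarray(values, dtype=float)
        if nodata is not None:
            mask = values == nodata
        else:
            mask = ~np.isfinite(values)
        self.nodata_count = int(mask.sum())
        values = np.where(mask, 0.0, values)
        if np.any(values < 0):
            raise ValueError("population counts must be non-negative")
        super().__init__(spec, values)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def read_ascii_grid(path: str | Path, cls: type[Raster] = Raster, **kwargs) -> Raster:
    """Read an ESRI ASCII grid (.asc).

    Supports both ``xllcorner`` and ``xllcenter`` registration keywords;
    corners are converted to the cell-center origin used internally.
    """
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"missing required ESRI ASCII header field {key!r} in {path}")
    cell = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:
        x0 = header["xllcorner"] + cell / 2
        y0 = header["yllcorner"] + cell / 2
    values = np.loadtxt(path, skiprows=n_header, dtype=float, ndmin=2)
    spec = GridSpec(x0, y0, cell, int(header["nrows"]), int(header["ncols"]))
    if cls is PopulationGrid:
        kwargs.setdefault("nodata", header.get("nodata_value"))
    return cls(spec, values, **kwargs)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.17g") -> None:
    """Write a raster as an ESRI ASCII grid with cell-center registration."""
    spec = raster.spec
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcenter {spec.origin_lon!r}\n"
        f"yllcenter {spec.origin_lat!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)
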