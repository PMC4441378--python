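"""Raster grid geometry, plain-text raster I/O and great-circle distances.

Grids are WGS84 latitude/longitude rasters with cell-center registration.
Arrays are stored row-major with row 0 at the northern edge, matching the
Esri ASCII grid convention used for on-disk storage. Invalid (masked) cells
are NaN in memory and NODATA_value on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lat/lon raster (cell-center registered).

    Parameters
    ----------
    lon_min, lat_min : float
        Coordinates of the lower-left *corner* of the grid, in degrees.
    cell_size : float
        Cell edge length in degrees (square cells).
    nrows, ncols : int
        Grid dimensions. Row 0 is the northernmost row.
    """

    lon_min: float
    lat_min: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 northernmost."""
        return self.lat_max - (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell center."""
        lon = self.lon_centers()
        lat = self.lat_centers()
        return np.meshgrid(lon, lat)

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column index of the cell containing each point.

        Points on the extreme east/north edge are assigned to the last
        cell. Raises ValueError for points outside the extent.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.argwhere(~inside).ravel().tolist()
            raise ValueError(f"points outside grid extent at indices {bad}")
        col = np.clip(
            np.floor((lon - self.lon_min) / self.cell_size).astype(int), 0, self.ncols - 1
        )
        row_from_bottom = np.clip(
            np.floor((lat - self.lat_min) / self.cell_size).astype(int), 0, self.nrows - 1
        )
        row = self.nrows - 1 - row_from_bottom
        return row, col


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km).

    Inputs broadcast against each other; angles in decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def write_ascii_grid(path: str | Path, values: np.ndarray, geom: GridGeometry) -> None:
    """Write a 2-D array as an Esri ASCII grid; NaN cells become NODATA."""
    values = np.asarray(values, dtype=float)
    if values.shape != geom.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {geom.shape}")
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {geom.ncols}\n"
        f"nrows {geom.nrows}\n"
        f"xllcorner {geom.lon_min!r}\n"
        f"yllcorner {geom.lat_min!r}\n"
        f"cellsize {geom.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an Esri ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field '{key}'")
    values = np.loadtxt(lines[n_header:], ndmin=2)
    geom = GridGeometry(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        cell_size=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    if values.shape != geom.shape:
        raise ValueError(f"{path}: data shape {values.shape} disagrees with header {geom.shape}")
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, geom
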