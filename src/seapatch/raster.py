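"""Gridded density fields and ESRI ASCII grid I/O.

A :class:`DensityRaster` holds a rectangular grid of sea-floor density
(individuals per square metre) together with its cell geometry.  Missing
cells are represented internally as NaN.  The pixel *area* is an explicit
parameter rather than being silently derived from the linear cell size,
because survey products are sometimes published with a nominal pixel area
that differs from ``cellsize**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DensityRaster", "read_asc", "write_asc"]


@dataclass
class DensityRaster:
    """A rectangular grid of density values (individuals m^-2).

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.  NaN marks missing cells.
    cell_size
        Linear grid spacing in metres.
    cell_area
        Area of one pixel in m^2.  Defaults to ``cell_size ** 2``.
    xllcorner, yllcorner
        Coordinates of the lower-left corner (m).
    nodata
        Marker value used on disk for missing cells.
    """

    values: np.ndarray
    cell_size: float
    cell_area: float | None = None
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.cell_area is None:
            self.cell_area = float(self.cell_size) ** 2
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("density values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return np.isfinite(self.values)

    def total_abundance(self) -> float:
        """Sum of density x pixel area over all non-missing cells."""
        return float(np.nansum(self.values) * self.cell_area)


def read_asc(path: str | Path, cell_area: float | None = None) -> DensityRaster:
    """Read an ESRI ASCII grid (.asc).

    ``cell_area`` overrides the default ``cellsize**2`` pixel area.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                   "nodata_value", "xllcenter", "yllcenter"}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in header_keys and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: missing ncols/nrows header")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.concatenate(rows) if rows else np.empty(0)
    if data.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {data.size}")
    values = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    cellsize = header.get("cellsize", 1.0)
    # center-registered grids: shift to the equivalent corner registration
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2
                     if "xllcenter" in header else 0.0)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2
                     if "yllcenter" in header else 0.0)
    return DensityRaster(values=values, cell_size=cellsize, cell_area=cell_area,
                         xllcorner=xll, yllcorner=yll, nodata=nodata)


def write_asc(raster: DensityRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid."""
    nrows, ncols = raster.shape
    out = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.6f}\n")
        fh.write(f"yllcorner {raster.yllcorner:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
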