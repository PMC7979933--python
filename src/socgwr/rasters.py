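"""Plain-text raster I/O in the ESRI ASCII grid format.

Every gridded surface (predictor layers, region labels, coefficient and
stock maps) serializes as one ``.asc`` file: a six-line header (ncols,
nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by the rows
top-first.  In-memory arrays are row-major from the lower-left origin, so
rows are flipped on the way in and out.  Values are written with 10
significant digits, comfortably lossless at the 6 the pipeline guarantees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .grids import LandscapeGrid

NODATA = -9999.0


def write_ascii_grid(path, values, grid: LandscapeGrid, fmt: str = "%.10g") -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise InvalidArgumentError(
            f"values shape {values.shape} != grid shape {grid.shape}"
        )
    out = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.origin_x - grid.cell_size / 2:.10g}\n"
        f"yllcorner {grid.origin_y - grid.cell_size / 2:.10g}\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"NODATA_value {NODATA:g}"
    )
    np.savetxt(path, np.flipud(out), fmt=fmt, header=header, comments="")


def read_ascii_grid(path):
    """Read an ASCII grid; returns ``(values, geometry)`` with NaN for
    nodata and geometry as a label-free :class:`LandscapeGrid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_head = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_head += 1
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise InvalidArgumentError(
            f"{path}: missing header keys {sorted(required - set(header))}"
        )
    nx, ny = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    vals = np.loadtxt(lines[n_head:]).reshape(ny, nx)
    vals = np.flipud(vals)
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    geom = LandscapeGrid(
        nx=nx,
        ny=ny,
        cell_size=cs,
        origin_x=header["xllcorner"] + cs / 2,
        origin_y=header["yllcorner"] + cs / 2,
    )
    return vals, geom
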