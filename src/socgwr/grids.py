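"""Planar grid containers: landscape geometry, predictor stacks, stock maps.

All rasters in one analysis share a single planar grid: ``(ny, nx)`` arrays,
row 0 at the *bottom* (row-major from the lower-left origin), cell centers at
``origin + index * cell_size``.  Geographic (lon/lat) coordinates are accepted
by the regression layer, which then switches to great-circle distances; the
synthetic machinery is purely planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CoRegistrationError, InvalidArgumentError, MissingLayerError


@dataclass
class LandscapeGrid:
    """Regular planar grid with an integer ecoregion label per cell.

    Parameters
    ----------
    nx, ny : int
        Cell counts along x and y (each >= 2).
    cell_size : float
        Cell edge length in meters.
    origin_x, origin_y : float
        Planar coordinates of the lower-left cell *center*.
    region_labels : ndarray of int, shape (ny, nx)
        Ecoregion label of every cell; labels form contiguous patches.
    """

    nx: int
    ny: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    region_labels: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise InvalidArgumentError("grid needs nx, ny >= 2")
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be positive")
        if self.region_labels is None:
            self.region_labels = np.zeros((self.ny, self.nx), dtype=int)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.region_labels.shape != (self.ny, self.nx):
            raise InvalidArgumentError(
                f"region_labels shape {self.region_labels.shape} != {(self.ny, self.nx)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (1 ha = 10^4 m^2)."""
        return self.cell_size**2 / 1e4

    @property
    def diagonal(self) -> float:
        """Length of the grid's bounding-box diagonal in meters."""
        return float(np.hypot(self.nx * self.cell_size, self.ny * self.cell_size))

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) cell centers in row-major order
        (y varies slowest, starting at the bottom row)."""
        xs = self.origin_x + np.arange(self.nx) * self.cell_size
        ys = self.origin_y + np.arange(self.ny) * self.cell_size
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def cell_center(self, iy: int, ix: int) -> tuple[float, float]:
        return (
            self.origin_x + ix * self.cell_size,
            self.origin_y + iy * self.cell_size,
        )

    def cell_index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map planar coordinates to (iy, ix) of the containing cell."""
        ix = np.rint((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        iy = np.rint((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return iy, ix

    def same_geometry(self, other: "LandscapeGrid") -> bool:
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )


def regions_are_contiguous(grid: LandscapeGrid) -> bool:
    """True when every region label forms a single 4-connected patch."""
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for lab in np.unique(grid.region_labels):
        _, n_comp = ndimage.label(grid.region_labels == lab, structure=four)
        if n_comp != 1:
            return False
    return True


@dataclass
class PredictorStack:
    """Named, co-registered predictor layers on a common grid.

    ``layers`` maps layer name -> (ny, nx) float array.  ``indicator_names``
    records which layers are 0/1 one-hot indicators (they are exempt from
    Pearson pruning and are not standardized).
    """

    grid: LandscapeGrid
    layers: dict[str, np.ndarray]
    indicator_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for name, arr in self.layers.items():
            if name in seen:
                raise InvalidArgumentError(f"duplicate layer name {name!r}")
            seen.add(name)
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise CoRegistrationError(
                    f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}"
                )
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise MissingLayerError(name) from None

    def values_at_cells(self, flat_idx: np.ndarray, names=None) -> np.ndarray:
        """Matrix of layer values at row-major flat cell indices."""
        names = self.names if names is None else list(names)
        return np.column_stack([self[n].ravel()[flat_idx] for n in names])

    def design_matrix(self, names, overrides: dict[str, np.ndarray] | None = None):
        """(n_cells, p) matrix for ``names``; the name ``intercept`` yields a
        column of ones; ``overrides`` substitutes replacement layers."""
        overrides = overrides or {}
        cols = []
        for n in names:
            if n == "intercept":
                cols.append(np.ones(self.grid.n_cells))
                continue
            arr = overrides.get(n)
            if arr is None:
                arr = self[n]
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise CoRegistrationError(
                    f"override for {n!r} has shape {arr.shape}, grid is {self.grid.shape}"
                )
            cols.append(arr.ravel())
        return np.column_stack(cols)
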