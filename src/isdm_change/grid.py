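"""Equal-area analysis grid.

The modelling unit is a square cell (default 100x100 km) in a Lambert
azimuthal equal-area plane. The grid carries, per cell, the centroid,
area, environmental covariates, the observation-effort (thinning)
covariates, the country index, and the distance to the expert range map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .projection import DEFAULT_CENTER, laea_forward


@dataclass
class EqualAreaGrid:
    """A rectangular lattice of equal-area square cells.

    Attributes
    ----------
    nx, ny : int
        Number of cells along x and y.
    cell_size_km : float
        Side length of each square cell.
    x0, y0 : float
        Lower-left corner of the lattice in projected kilometres.
    cells : pandas.DataFrame
        One row per cell, indexed by ``cell_id`` (row-major from the
        lower-left), with at least columns ``cx, cy, area_km2``.
        Covariates and ancillary variables are added as extra columns.
    center : tuple
        (lat, lon) of the projection centre, recorded for provenance.
    """

    nx: int
    ny: int
    cell_size_km: float
    x0: float
    y0: float
    cells: pd.DataFrame
    center: tuple[float, float] = DEFAULT_CENTER
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of centroid coordinates in km."""
        return self.cells[["cx", "cy"]].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.cells["area_km2"].to_numpy()

    def polygons(self) -> np.ndarray:
        """Shapely box per cell, row-major order."""
        half = self.cell_size_km / 2.0
        cx = self.cells["cx"].to_numpy()
        cy = self.cells["cy"].to_numpy()
        return shapely.box(cx - half, cy - half, cx + half, cy + half)

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.covariate_names
        missing = [n for n in names if n not in self.cells.columns]
        if missing:
            raise ValueError(f"covariates not attached to grid: {missing}")
        return self.cells[list(names)].to_numpy(dtype=float)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major cell id for projected points; −1 when off-grid."""
        ix = np.floor((np.asarray(x) - self.x0) / self.cell_size_km).astype(int)
        iy = np.floor((np.asarray(y) - self.y0) / self.cell_size_km).astype(int)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        return np.where(inside, iy * self.nx + ix, -1)

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Cell id for geographic points (degrees); −1 when off-grid."""
        x, y = laea_forward(lon, lat, center=self.center)
        return self.cell_index(x, y)


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size_km: float = 100.0,
    center: tuple[float, float] = DEFAULT_CENTER,
) -> EqualAreaGrid:
    """Build an equal-area grid of square cells covering a projected extent.

    Parameters
    ----------
    extent : (xmin, ymin, xmax, ymax)
        Bounding box in projected kilometres. The grid snaps outward so
        whole cells cover the box.
    cell_size_km : float
        Cell side; 100 km gives the 10,000 km² macroecological grain.
    center : (lat, lon)
        Projection centre in degrees.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is degenerate: require xmax > xmin and ymax > ymin")
    if cell_size_km <= 0:
        raise ValueError("cell_size_km must be positive")
    if not (-90 <= center[0] <= 90) or not (-180 <= center[1] <= 180):
        raise ValueError(f"invalid projection centre {center}")

    nx = int(np.ceil((xmax - xmin) / cell_size_km - 1e-9))
    ny = int(np.ceil((ymax - ymin) / cell_size_km - 1e-9))
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))  # jj = row (y), ii = col (x)
    cx = xmin + (ii.ravel() + 0.5) * cell_size_km
    cy = ymin + (jj.ravel() + 0.5) * cell_size_km
    cells = pd.DataFrame(
        {
            "cx": cx,
            "cy": cy,
            "area_km2": np.full(nx * ny, cell_size_km**2),
        },
        index=pd.RangeIndex(nx * ny, name="cell_id"),
    )
    return EqualAreaGrid(nx=nx, ny=ny, cell_size_km=cell_size_km, x0=xmin, y0=ymin, cells=cells, center=center)


def regular_grid(nx: int, ny: int, cell_size_km: float = 100.0, center=DEFAULT_CENTER) -> EqualAreaGrid:
    """Convenience constructor: an nx x ny grid with lower-left at the origin."""
    return build_grid((0.0, 0.0, nx * cell_size_km, ny * cell_size_km), cell_size_km, center)
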