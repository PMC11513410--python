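"""Environmental and effort covariates for cells and blobs.

Covariate layers are planar rasters (ESRI ASCII grid on disk). They are
attached to analysis units — grid cells or survey blobs — by area-weighted
zonal means, the distance to an expert range polygon is computed from cell
centroids, and a tree-ensemble pre-screen reduces the candidate set to a
small, weakly collinear subset used in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.utils.validation import check_is_fitted

from .grid import EqualAreaGrid


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """A single planar raster layer.

    ``values`` is (nrows, ncols) with row 0 at the TOP (north), matching
    the ESRI ASCII grid convention; ``x0, y0`` is the lower-left corner
    and ``cell`` the square pixel size, all in projected km. NaN marks
    missing data.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float
    units: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_polygons(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened pixel boxes and their values (row-major, top row first)."""
        nr, nc = self.values.shape
        cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
        x_lo = self.x0 + cols.ravel() * self.cell
        y_hi = self.y0 + (nr - rows.ravel()) * self.cell
        boxes = shapely.box(x_lo, y_hi - self.cell, x_lo + self.cell, y_hi)
        return boxes, self.values.ravel()

    def write_ascii(self, path) -> None:
        nr, nc = self.values.shape
        with open(path, "w") as fh:
            fh.write(
                f"ncols {nc}\nnrows {nr}\nxllcorner {self.x0}\nyllcorner {self.y0}\n"
                f"cellsize {self.cell}\nNODATA_value -9999\n"
            )
            vals = np.where(np.isnan(self.values), -9999.0, self.values)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path, units: str = "") -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        vals[vals == header.get("nodata_value", -9999.0)] = np.nan
        return cls(values=vals, x0=header["xllcorner"], y0=header["yllcorner"], cell=header["cellsize"], units=units)


@dataclass
class CovariateStack:
    """Named raster layers sharing one extent and resolution."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def add(self, name: str, raster: Raster) -> None:
        if self.layers:
            ref = next(iter(self.layers.values()))
            same = (
                raster.shape == ref.shape
                and np.isclose(raster.x0, ref.x0)
                and np.isclose(raster.y0, ref.y0)
                and np.isclose(raster.cell, ref.cell)
            )
            if not same:
                raise ValueError(f"layer {name!r} is not aligned with the stack")
        self.layers[name] = raster

    @property
    def names(self) -> list[str]:
        return list(self.layers)


def zonal_average(stack: CovariateStack, units: list[shapely.Geometry]) -> pd.DataFrame:
    """Area-weighted mean of each layer over each unit polygon.

    Pixels are weighted by their overlap area with the unit; pixels with
    missing data contribute neither value nor weight. The returned frame
    has one row per unit, one column per layer, plus ``missing_frac_*``
    columns with the missing-area fraction. A unit whose overlap is
    entirely missing gets NaN (flagged via missing_frac = 1).
    """
    if not stack.layers:
        raise ValueError("empty covariate stack")
    ref = next(iter(stack.layers.values()))
    boxes, _ = ref.pixel_polygons()
    tree = shapely.STRtree(boxes)

    out: dict[str, np.ndarray] = {}
    overlaps = []
    for unit in units:
        idx = tree.query(unit)
        areas = np.array([unit.intersection(boxes[i]).area for i in idx])
        keep = areas > 0
        overlaps.append((np.asarray(idx)[keep], areas[keep]))

    for name, layer in stack.layers.items():
        flat = layer.values.ravel()
        means = np.full(len(units), np.nan)
        missing = np.zeros(len(units))
        for u, (idx, areas) in enumerate(overlaps):
            if len(idx) == 0:
                missing[u] = 1.0
                continue
            vals = flat[idx]
            ok = ~np.isnan(vals)
            missing[u] = areas[~ok].sum() / areas.sum()
            if ok.any():
                means[u] = np.average(vals[ok], weights=areas[ok])
        out[name] = means
        out[f"missing_frac_{name}"] = missing
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# distance to the expert range
# ---------------------------------------------------------------------------

def distance_to_range(grid: EqualAreaGrid, range_polygon: shapely.Geometry) -> np.ndarray:
    """Distance (km) from each cell centroid to the expert range map.

    Zero for centroids inside or on the polygon — expert maps are trusted
    inside the range and only penalise predictions beyond it — otherwise
    the Euclidean distance in the projected plane to the polygon edge.
    """
    if range_polygon is None or range_polygon.is_empty:
        raise ValueError("empty range polygon")
    pts = [Point(xy) for xy in grid.centroids]
    d = np.array(
        [0.0 if range_polygon.covers(p) else p.distance(range_polygon) for p in pts]
    )
    return d


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

class CovariateScreener(BaseEstimator, TransformerMixin):
    """Tree-ensemble covariate pre-screen with a collinearity cap.

    Candidates are ranked by permutation importance of a random forest
    fitted to the raw presence/absence response (both periods pooled),
    then accepted greedily in rank order, skipping any candidate whose
    absolute Pearson correlation with an already accepted one exceeds
    ``r_max``, until ``n_select`` are kept. Ties in importance break by
    rank order, then by column name.

    Parameters
    ----------
    n_select : int, default 4
        Covariates to keep.
    r_max : float, default 0.6
        Maximum |Pearson r| allowed within the selected set.
    n_estimators : int, default 200
        Forest size; small by design — this is a screen, not a model.
    n_repeats : int, default 10
        Permutation-importance repeats.
    random_state : int, default 0

    Attributes
    ----------
    feature_names_in_ : ndarray of candidate names
    importances_ : pandas.Series, permutation importance per candidate
    ranking_ : list of names, most important first
    selected_ : list of names, the accepted subset (length n_select)
    corr_ : pandas.DataFrame, candidate Pearson correlation matrix
    """

    def __init__(self, n_select: int = 4, r_max: float = 0.6, n_estimators: int = 200,
                 n_repeats: int = 10, random_state: int = 0):
        self.n_select = n_select
        self.r_max = r_max
        self.n_estimators = n_estimators
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if X.shape[1] < self.n_select:
            raise ValueError(f"need at least {self.n_select} candidates, got {X.shape[1]}")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("response must be binary presence/absence")

        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        ).fit(X.to_numpy(), y)
        imp = permutation_importance(
            forest, X.to_numpy(), y, n_repeats=self.n_repeats, random_state=self.random_state
        )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.importances_ = pd.Series(imp.importances_mean, index=X.columns)
        order = sorted(
            range(X.shape[1]),
            key=lambda j: (-self.importances_.iloc[j], j, str(X.columns[j])),
        )
        self.ranking_ = [X.columns[j] for j in order]
        self.corr_ = X.corr(method="pearson")

        selected: list[str] = []
        skipped: list[tuple[str, str, float]] = []
        for name in self.ranking_:
            if len(selected) == self.n_select:
                break
            conflict = None
            for acc in selected:
                r = self.corr_.loc[name, acc]
                if abs(r) > self.r_max:
                    conflict = (name, acc, float(r))
                    break
            if conflict is None:
                selected.append(name)
            else:
                skipped.append(conflict)
        if len(selected) < self.n_select:
            edges = ", ".join(f"{a}~{b} (r={r:.2f})" for a, b, r in skipped)
            raise ValueError(
                f"only {len(selected)} of {self.n_select} candidates satisfy "
                f"|r| <= {self.r_max}; conflicting pairs: {edges}"
            )
        self.selected_ = selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        return pd.DataFrame(X)[self.selected_]

    def report(self) -> str:
        check_is_fitted(self, "selected_")
        lines = ["covariate screening", "===================", "importance ranking:"]
        for name in self.ranking_:
            mark = "*" if name in self.selected_ else " "
            lines.append(f"  {mark} {name}: {self.importances_[name]:.5f}")
        lines.append(f"selected (|r| <= {self.r_max}): {', '.join(self.selected_)}")
        return "\n".join(lines)


def screen_covariates(
    pa_table: pd.DataFrame,
    candidates: list[str],
    response: str = "y",
    k: int = 4,
    r_max: float = 0.6,
    random_state: int = 0,
) -> CovariateScreener:
    """Functional wrapper: fit a CovariateScreener on a presence/absence table."""
    scr = CovariateScreener(n_select=k, r_max=r_max, random_state=random_state)
    return scr.fit(pa_table[candidates], pa_table[response])
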