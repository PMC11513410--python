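"""From raw occurrence records and survey tables to model-ready inputs.

Presence-only (PO) records are filtered on coordinate precision and
coordinate uncertainty, deduplicated, and aggregated to per-cell,
per-period counts on the equal-area grid. Camera-trap surveys are
buffered to discs, overlapping discs within a time period are unioned
into "blobs" carrying summed effort, and non-detections become informed
absences. The pooled PO counts of all study species give the
effort-calibration ratio rho between the two periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from .grid import EqualAreaGrid

logger = logging.getLogger(__name__)

PO_COLUMNS = ["species", "lon", "lat", "date", "uncertainty_m"]


# ---------------------------------------------------------------------------
# presence-only records
# ---------------------------------------------------------------------------

def _decimal_places_text(value: str) -> int:
    """Number of decimal places in a textual coordinate."""
    s = str(value).strip()
    if "e" in s.lower():  # scientific notation carries no textual precision
        return -1
    if "." not in s:
        return 0
    return len(s.split(".", 1)[1])


def _passes_precision(value, min_decimals: int) -> bool:
    """Coordinate-precision rule.

    Textual input: count decimal digits. Numeric input: the value passes
    when it is not exactly representable with fewer than ``min_decimals``
    decimals (trailing textual zeros are unrecoverable from a float, so a
    numeric 10.120 is treated as 2 decimals).
    """
    if isinstance(value, str):
        nd = _decimal_places_text(value)
        if nd >= 0:
            return nd >= min_decimals
        value = float(value)
    v = float(value)
    scaled = v * 10.0**min_decimals
    coarse = 10.0 * np.round(scaled / 10.0)
    return not np.isclose(scaled, coarse, rtol=0.0, atol=1e-9)


def filter_po(
    records: pd.DataFrame,
    min_decimals: int = 3,
    max_uncertainty_m: float = 25_000.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter PO records on coordinate precision and uncertainty.

    Keeps records whose latitude AND longitude carry at least
    ``min_decimals`` decimal places and whose coordinate uncertainty is
    missing or at most ``max_uncertainty_m`` metres. Unparseable
    coordinates reject the record (logged), never raise.

    Returns the kept records (coordinates coerced to float) and a report
    of counts removed per rule.
    """
    report = {"input": len(records), "unparseable": 0, "precision": 0, "uncertainty": 0}
    keep = np.ones(len(records), dtype=bool)
    lon_num = np.empty(len(records))
    lat_num = np.empty(len(records))

    for k, (_, row) in enumerate(records.iterrows()):
        try:
            lon_f, lat_f = float(row["lon"]), float(row["lat"])
            if not (np.isfinite(lon_f) and np.isfinite(lat_f)):
                raise ValueError
            if not (-180.0 <= lon_f <= 180.0 and -90.0 <= lat_f <= 90.0):
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("record %s: unparseable coordinates (%r, %r)", k, row["lon"], row["lat"])
            report["unparseable"] += 1
            keep[k] = False
            lon_num[k] = lat_num[k] = np.nan
            continue
        lon_num[k], lat_num[k] = lon_f, lat_f
        if not (_passes_precision(row["lat"], min_decimals) and _passes_precision(row["lon"], min_decimals)):
            report["precision"] += 1
            keep[k] = False
            continue
        unc = row.get("uncertainty_m", np.nan)
        unc = pd.to_numeric(unc, errors="coerce")
        if pd.notna(unc) and unc > max_uncertainty_m:
            report["uncertainty"] += 1
            keep[k] = False

    out = records.loc[keep].copy()
    out["lon"] = lon_num[keep]
    out["lat"] = lat_num[keep]
    report["kept"] = len(out)
    return out, report


def deduplicate_po(records: pd.DataFrame) -> pd.DataFrame:
    """One record per unique (species, date, lat, lon) combination.

    Sorted on the key so the result does not depend on input order.
    """
    if records.empty:
        return records.copy()
    key = ["species", "date", "lat", "lon"]
    return (
        records.drop_duplicates(subset=key)
        .sort_values(key, kind="mergesort")
        .reset_index(drop=True)
    )


def grid_po_counts(
    records: pd.DataFrame,
    grid: EqualAreaGrid,
    period_split_year: int,
    year_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Aggregate deduplicated PO records to per-cell, per-period counts.

    Period 1 contains years up to and including ``period_split_year``;
    period 2 the later years. Records outside ``year_range`` (when given)
    or falling off the grid are excluded and counted in the report.

    Returns an (n_cells, 2) integer matrix and the report.
    """
    n = np.zeros((grid.n_cells, 2), dtype=int)
    report = {"input": len(records), "off_grid": 0, "out_of_window": 0, "counted": 0}
    if records.empty:
        return n, report

    years = pd.to_datetime(records["date"]).dt.year.to_numpy()
    in_window = np.ones(len(records), dtype=bool)
    if year_range is not None:
        in_window = (years >= year_range[0]) & (years <= year_range[1])
        report["out_of_window"] = int((~in_window).sum())
        if report["out_of_window"]:
            logger.info("%d records outside year window %s excluded", report["out_of_window"], year_range)

    cell = grid.locate(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    off = in_window & (cell < 0)
    report["off_grid"] = int(off.sum())
    ok = in_window & (cell >= 0)
    period = (years > period_split_year).astype(int)  # 0 → time1, 1 → time2
    np.add.at(n, (cell[ok], period[ok]), 1)
    report["counted"] = int(ok.sum())
    return n, report


def effort_ratio(po_counts_by_period: tuple[float, float] | np.ndarray) -> float:
    """Sampling-effort ratio rho = period-2 records / period-1 records.

    Computed from the pooled records of all study species; enters the PO
    observation process of period 2 only.
    """
    n1, n2 = float(po_counts_by_period[0]), float(po_counts_by_period[1])
    if n1 <= 0:
        raise ValueError("cannot form effort ratio: zero records in period 1")
    return n2 / n1


# ---------------------------------------------------------------------------
# camera-trap surveys → blobs
# ---------------------------------------------------------------------------

@dataclass
class SurveyBlob:
    """A merged camera-trap survey polygon within one time period.

    ``polygon`` is the union of the member surveys' buffer discs,
    ``effort_days`` the sum of member efforts, and ``detections`` maps a
    species name to its 0/1 detection flag.
    """

    blob_id: int
    period: int
    polygon: shapely.Geometry
    area_km2: float
    effort_days: float
    members: list = field(default_factory=list)
    time_span: tuple | None = None
    detections: dict[str, int] = field(default_factory=dict)


SURVEY_COLUMNS = ["survey_id", "x_km", "y_km", "area_km2", "effort_days", "start", "end"]


def survey_period(start, end, period_split_year: int) -> int:
    """Assign a survey to the period containing its temporal midpoint."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    mid = start + (end - start) / 2
    return 1 if mid.year <= period_split_year else 2


def build_blobs(surveys: pd.DataFrame, period: int) -> list[SurveyBlob]:
    """Union overlapping survey buffer discs of one period into blobs.

    Each survey becomes a disc of radius sqrt(area/pi) at its centroid
    (coordinates in projected km). Overlapping discs merge; blob area is
    the union area, blob effort the sum of member efforts, and the time
    span the envelope of member spans. Surveys without effort are dropped
    with a log message; zero or negative survey area raises.
    """
    rows = surveys.reset_index(drop=True)
    if (pd.to_numeric(rows["area_km2"], errors="coerce") <= 0).any():
        raise ValueError("survey with non-positive area: buffer disc undefined")
    missing = rows["effort_days"].isna()
    if missing.any():
        logger.warning("%d surveys missing effort dropped", int(missing.sum()))
        rows = rows.loc[~missing].reset_index(drop=True)
    if rows.empty:
        return []

    radius = np.sqrt(rows["area_km2"].to_numpy(float) / np.pi)
    discs = [Point(x, y).buffer(r, quad_segs=64) for x, y, r in zip(rows["x_km"], rows["y_km"], radius)]
    merged = unary_union(discs)
    parts = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    # Deterministic blob ordering independent of survey order.
    parts.sort(key=lambda g: (g.centroid.x, g.centroid.y))

    tree = shapely.STRtree(discs)
    blobs = []
    for bid, part in enumerate(parts):
        idx = sorted(
            i for i in tree.query(part) if discs[i].intersection(part).area > 1e-9 * discs[i].area
        )
        members = rows.iloc[idx]
        span = (pd.to_datetime(members["start"]).min(), pd.to_datetime(members["end"]).max())
        blobs.append(
            SurveyBlob(
                blob_id=bid,
                period=period,
                polygon=part,
                area_km2=part.area,
                effort_days=float(members["effort_days"].sum()),
                members=sorted(members["survey_id"].tolist()),
                time_span=span,
            )
        )
    return blobs


def generate_absences(
    blobs: list[SurveyBlob],
    detections_table: pd.DataFrame,
    species: list[str],
) -> list[SurveyBlob]:
    """Fill per-species detection flags; non-detection becomes an absence.

    ``detections_table`` lists (survey_id, species) detection events. A
    blob scores 1 for a species when any member survey detected it, 0
    otherwise. Species in the table but not in ``species`` raise.
    """
    unknown = set(detections_table["species"]) - set(species)
    if unknown:
        raise ValueError(f"detections for species outside the study list: {sorted(unknown)}")
    by_survey: dict = {}
    for _, r in detections_table.iterrows():
        by_survey.setdefault(r["survey_id"], set()).add(r["species"])
    for blob in blobs:
        seen: set = set()
        for sid in blob.members:
            seen |= by_survey.get(sid, set())
        blob.detections = {s: int(s in seen) for s in species}
    return blobs


# ---------------------------------------------------------------------------
# assembled model inputs
# ---------------------------------------------------------------------------

@dataclass
class ISDMData:
    """Aligned inputs for one species' integrated model.

    ``po_counts`` is (n_cells, 2); ``blob_weights`` holds, per blob, the
    area fraction of the blob overlapping each grid cell (rows sum to 1
    over the in-grid part) and is used to average cell intensities over
    blobs. ``blob_table`` has one row per blob with period, area, effort
    and the 0/1 response ``y`` for the focal species.
    """

    grid: EqualAreaGrid
    po_counts: np.ndarray
    blob_table: pd.DataFrame
    blob_weights: np.ndarray
    effort_ratio: float
    period_split_year: int
    species: str = "species"

    def __post_init__(self):
        if self.po_counts.shape != (self.grid.n_cells, 2):
            raise ValueError("po_counts must be (n_cells, 2)")
        if (self.po_counts < 0).any():
            raise ValueError("po_counts must be non-negative")
        if self.effort_ratio <= 0:
            raise ValueError("effort_ratio must be positive")
        if len(self.blob_table) != self.blob_weights.shape[0]:
            raise ValueError("blob_table and blob_weights disagree on blob count")


def blob_cell_weights(blobs: list[SurveyBlob], grid: EqualAreaGrid) -> np.ndarray:
    """Area-weighted overlap of each blob with each grid cell.

    Rows are normalised over the in-grid overlap, so W @ values gives the
    area-weighted mean of a per-cell quantity over the blob.
    """
    cells = grid.polygons()
    tree = shapely.STRtree(cells)
    W = np.zeros((len(blobs), grid.n_cells))
    for b, blob in enumerate(blobs):
        for ci in tree.query(blob.polygon):
            a = blob.polygon.intersection(cells[ci]).area
            if a > 0:
                W[b, ci] = a
        total = W[b].sum()
        if total <= 0:
            raise ValueError(f"blob {blob.blob_id} does not overlap the grid")
        W[b] /= total
    return W


def assemble_isdm_data(
    grid: EqualAreaGrid,
    po_counts: np.ndarray,
    blobs: list[SurveyBlob],
    species: str,
    effort_ratio_value: float,
    period_split_year: int,
) -> ISDMData:
    """Bundle gridded counts and blob records into ISDMData for one species."""
    table = pd.DataFrame(
        {
            "blob_id": [b.blob_id for b in blobs],
            "period": [b.period for b in blobs],
            "area_km2": [b.area_km2 for b in blobs],
            "effort_days": [b.effort_days for b in blobs],
            "y": [b.detections.get(species, 0) for b in blobs],
        }
    )
    W = blob_cell_weights(blobs, grid) if blobs else np.zeros((0, grid.n_cells))
    return ISDMData(
        grid=grid,
        po_counts=po_counts,
        blob_table=table,
        blob_weights=W,
        effort_ratio=effort_ratio_value,
        period_split_year=period_split_year,
        species=species,
    )
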