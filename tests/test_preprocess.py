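"""Record filtering, deduplication, gridding, blobs, and the effort ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isdm_change import (
    ISDMData,
    assemble_isdm_data,
    blob_cell_weights,
    build_blobs,
    deduplicate_po,
    effort_ratio,
    filter_po,
    generate_absences,
    grid_po_counts,
)
from isdm_change.grid import regular_grid
from isdm_change.preprocess import survey_period


def _rec(lat, lon, species="sp", date="2010-06-01", unc=np.nan):
    return {"species": species, "lon": lon, "lat": lat, "date": date, "uncertainty_m": unc}


# -- filtering --------------------------------------------------------------

def test_low_textual_precision_removed():
    kept, rep = filter_po(pd.DataFrame([_rec("10.12", "-65.123")]))
    assert kept.empty and rep["precision"] == 1


def test_high_uncertainty_removed():
    kept, rep = filter_po(pd.DataFrame([_rec("10.123", "-65.123", unc=30_000)]))
    assert kept.empty and rep["uncertainty"] == 1


def test_precise_low_uncertainty_kept():
    kept, rep = filter_po(pd.DataFrame([_rec("10.123", "-65.123", unc=1_000)]))
    assert len(kept) == 1 and rep["kept"] == 1


def test_missing_uncertainty_passes():
    kept, _ = filter_po(pd.DataFrame([_rec("10.123", "-65.123")]))
    assert len(kept) == 1


def test_numeric_two_decimal_value_removed():
    # 10.120 as a float is indistinguishable from 10.12: treated as 2 decimals
    kept, rep = filter_po(pd.DataFrame([_rec(10.120, -65.123)]))
    assert kept.empty and rep["precision"] == 1


def test_unparseable_coordinates_rejected_not_fatal():
    df = pd.DataFrame([_rec("abc", "-65.123"), _rec("91.0", "-65.123"), _rec("10.123", "-65.123")])
    kept, rep = filter_po(df)
    assert rep["unparseable"] == 2 and len(kept) == 1


def test_filter_idempotent(study):
    once, _ = filter_po(study["records"])
    twice, rep = filter_po(once)
    pd.testing.assert_frame_equal(once.reset_index(drop=True), twice.reset_index(drop=True))
    assert rep["precision"] == rep["uncertainty"] == 0


# -- deduplication ----------------------------------------------------------

def test_duplicates_collapse_and_dates_distinguish():
    a = _rec(10.123, -65.123, date="2010-06-01")
    df = pd.DataFrame([a, dict(a), {**a, "date": "2011-06-01"}])
    out = deduplicate_po(df)
    assert len(out) == 2


def test_dedup_order_independent():
    rows = [_rec(10.0 + i / 1000, -65.123, date=f"20{10+i%3}-06-01") for i in range(10)]
    rows += rows[:4]
    df = pd.DataFrame(rows)
    shuffled = df.sample(frac=1.0, random_state=5)
    pd.testing.assert_frame_equal(deduplicate_po(df), deduplicate_po(shuffled))


def test_dedup_empty():
    df = pd.DataFrame(columns=["species", "lon", "lat", "date", "uncertainty_m"])
    assert deduplicate_po(df).empty


# -- gridding ---------------------------------------------------------------

def test_counts_in_one_cell_and_period_split():
    grid = regular_grid(4, 4, 100, center=(0.0, 0.0))
    # three records near the projection origin (cell 0 is [0,100)x[0,100) km)
    recs = pd.DataFrame(
        [
            _rec(0.2, 0.2, date="2010-01-01"),
            _rec(0.3, 0.3, date="2013-12-31"),
            _rec(0.4, 0.4, date="2005-07-01"),
            _rec(0.2, 0.2, date="2014-01-01"),
        ]
    )
    n, rep = grid_po_counts(recs, grid, period_split_year=2013)
    cell = grid.locate(np.array([0.3]), np.array([0.3]))[0]
    assert n[cell, 0] == 3  # 2013 and earlier → period 1
    assert n[cell, 1] == 1  # 2014 → period 2
    assert n.sum() == rep["counted"] == 4


def test_count_conservation_and_off_grid_report(study):
    data = study["data"]
    n, rep = grid_po_counts(study["records"], data.grid, 2013)
    assert n.sum() + rep["off_grid"] == len(study["records"])
    np.testing.assert_array_equal(n, study["counts"])  # regenerates the simulated counts


def test_year_window_exclusion():
    grid = regular_grid(2, 2, 100, center=(0.0, 0.0))
    recs = pd.DataFrame([_rec(0.2, 0.2, date="1980-01-01"), _rec(0.2, 0.2, date="2010-01-01")])
    n, rep = grid_po_counts(recs, grid, 2013, year_range=(2000, 2021))
    assert rep["out_of_window"] == 1 and n.sum() == 1


# -- effort ratio -----------------------------------------------------------

@pytest.mark.parametrize("totals,expected", [((100, 127), 1.27), ((50, 50), 1.0), ((200, 150), 0.75)])
def test_effort_ratio_arithmetic(totals, expected):
    assert effort_ratio(totals) == pytest.approx(expected)


def test_effort_ratio_requires_period1_records():
    with pytest.raises(ValueError):
        effort_ratio((0, 10))


# -- blobs ------------------------------------------------------------------

def _survey(sid, x, y, area, effort, start="2010-01-01", end="2010-12-01"):
    return {"survey_id": sid, "x_km": x, "y_km": y, "area_km2": area,
            "effort_days": effort, "start": start, "end": end}


def test_disjoint_surveys_stay_separate():
    df = pd.DataFrame([_survey("a", 0, 0, 100, 10), _survey("b", 500, 500, 100, 20)])
    blobs = build_blobs(df, period=1)
    assert len(blobs) == 2


def test_overlapping_surveys_merge_summing_effort():
    df = pd.DataFrame([_survey("a", 0, 0, 314.159265, 100), _survey("b", 8, 0, 314.159265, 50)])
    blobs = build_blobs(df, period=1)
    assert len(blobs) == 1
    blob = blobs[0]
    assert blob.effort_days == 150
    assert blob.members == ["a", "b"]
    # union area strictly below the sum, above a single disc
    assert 314.0 < blob.area_km2 < 2 * 314.2


def test_buffer_radius_is_sqrt_area_over_pi():
    df = pd.DataFrame([_survey("a", 0, 0, 314.159265, 10)])
    blob = build_blobs(df, period=1)[0]
    # disc of radius 10 km (area within the polygonal-buffer tolerance)
    assert blob.area_km2 == pytest.approx(np.pi * 100, rel=1e-3)
    assert blob.polygon.bounds == pytest.approx((-10, -10, 10, 10), abs=1e-2)


def test_blob_construction_permutation_invariant():
    rows = [_survey(f"s{i}", 37 * i % 160, 61 * i % 140, 400 + 30 * i, 10 + i) for i in range(8)]
    df = pd.DataFrame(rows)
    shuffled = df.sample(frac=1.0, random_state=3)
    b1 = build_blobs(df, 1)
    b2 = build_blobs(shuffled, 1)
    assert [b.members for b in b1] == [b.members for b in b2]
    assert [b.effort_days for b in b1] == [b.effort_days for b in b2]


def test_zero_area_survey_rejected_and_missing_effort_dropped():
    with pytest.raises(ValueError, match="non-positive area"):
        build_blobs(pd.DataFrame([_survey("a", 0, 0, 0.0, 10)]), 1)
    blobs = build_blobs(
        pd.DataFrame([_survey("a", 0, 0, 100, np.nan), _survey("b", 500, 0, 100, 5)]), 1
    )
    assert len(blobs) == 1 and blobs[0].members == ["b"]


def test_survey_period_uses_midpoint():
    assert survey_period("2013-01-01", "2013-12-01", 2013) == 1
    assert survey_period("2013-10-01", "2014-12-01", 2013) == 2  # midpoint in 2014
    assert survey_period("2016-01-01", "2016-06-01", 2013) == 2


# -- absences ---------------------------------------------------------------

def test_absences_filled_from_member_detections():
    df = pd.DataFrame([_survey("a", 0, 0, 314, 10), _survey("b", 8, 0, 314, 10),
                       _survey("c", 500, 500, 314, 10)])
    blobs = build_blobs(df, 1)
    det = pd.DataFrame([{"survey_id": "b", "species": "jaguarundi"}])
    blobs = generate_absences(blobs, det, ["jaguarundi", "margay"])
    by_members = {tuple(b.members): b.detections for b in blobs}
    assert by_members[("a", "b")] == {"jaguarundi": 1, "margay": 0}
    assert by_members[("c",)] == {"jaguarundi": 0, "margay": 0}


def test_absences_unknown_species_error_and_empty_blobs():
    det = pd.DataFrame([{"survey_id": "a", "species": "ghost"}])
    with pytest.raises(ValueError, match="ghost"):
        generate_absences([], det, ["jaguarundi"])
    assert generate_absences([], det.iloc[:0], ["jaguarundi"]) == []


# -- assembled data ---------------------------------------------------------

def test_blob_weights_rows_sum_to_one(study):
    W = study["data"].blob_weights
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
    assert (W >= 0).all()


def test_isdm_data_validation(study):
    d = study["data"]
    with pytest.raises(ValueError):
        ISDMData(d.grid, d.po_counts[:-1], d.blob_table, d.blob_weights, 1.0, 2013)
    with pytest.raises(ValueError):
        ISDMData(d.grid, d.po_counts, d.blob_table, d.blob_weights, 0.0, 2013)
    with pytest.raises(ValueError):
        ISDMData(d.grid, -d.po_counts, d.blob_table, d.blob_weights, 1.0, 2013)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=1, max_size=6))
def test_blob_count_never_exceeds_survey_count(centres):
    df = pd.DataFrame([_survey(f"s{i}", x, y, 200, 10) for i, (x, y) in enumerate(centres)])
    blobs = build_blobs(df, 1)
    assert 1 <= len(blobs) <= len(centres)
    assert sum(b.effort_days for b in blobs) == pytest.approx(10 * len(centres))
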