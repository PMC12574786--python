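import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odpipeline.geospatial import (
    EARTH_RADIUS_MILES,
    MILES_PER_DEGREE,
    BufferZone,
    Gazetteer,
    GeoPoint,
    aggregate_by_region,
    buffers_to_geojson,
    classify_against_buffers,
    geocode,
    haversine_miles,
    normalize_address,
)
from odpipeline.synth import SynthConfig, generate_gazetteer_and_pharmacies

from .reference import ref_haversine_miles

import pandas as pd

lat_st = st.floats(min_value=-89.0, max_value=89.0)
lng_st = st.floats(min_value=-179.0, max_value=179.0)
point_st = st.builds(GeoPoint, lat_st, lng_st)


def test_geopoint_validation():
    with pytest.raises(ValueError):
        GeoPoint(91.0, 0.0)
    with pytest.raises(ValueError):
        GeoPoint(0.0, 181.0)
    with pytest.raises(ValueError):
        BufferZone(GeoPoint(0, 0), radius=0.0)


@pytest.mark.parametrize(
    ("a", "b", "expected"),
    [
        (GeoPoint(41.85, -87.65), GeoPoint(41.85, -87.65), 0.0),
        # antipodal along the equator: pi * R
        (GeoPoint(0, 0), GeoPoint(0, 180), math.pi * EARTH_RADIUS_MILES),
        # one degree of latitude: 2 pi R / 360
        (GeoPoint(0, 0), GeoPoint(1, 0), MILES_PER_DEGREE),
    ],
)
def test_haversine_closed_forms(a, b, expected):
    assert haversine_miles(a, b) == pytest.approx(expected, abs=1e-9)


def test_haversine_agrees_with_law_of_cosines():
    rng = random.Random(9)
    for _ in range(500):
        a = GeoPoint(rng.uniform(-80, 80), rng.uniform(-179, 179))
        b = GeoPoint(a.lat + rng.uniform(-1, 1), a.lng + rng.uniform(-1, 1))
        assert haversine_miles(a, b) == pytest.approx(
            ref_haversine_miles(a.lat, a.lng, b.lat, b.lng), abs=1e-6
        )


@settings(derandomize=True, max_examples=200)
@given(point_st, point_st, point_st)
def test_haversine_is_a_metric(a, b, c):
    dab = haversine_miles(a, b)
    assert dab == pytest.approx(haversine_miles(b, a), abs=1e-9)
    assert dab >= 0
    if a == b:
        assert dab == 0.0
    assert dab <= haversine_miles(a, c) + haversine_miles(c, b) + 1e-6


def test_gazetteer_normalization():
    gaz = Gazetteer({"123 main st": GeoPoint(41.0, -87.0)})
    assert geocode("  123  MAIN st.", gaz) == GeoPoint(41.0, -87.0)
    assert geocode("unknown address", gaz) is None
    assert geocode(None, gaz) is None
    assert normalize_address("  123  MAIN st.") == normalize_address("123 main st")


def test_gazetteer_csv_roundtrip(tmp_path):
    gaz = Gazetteer({"1 oak ave": GeoPoint(43.0, -88.0)})
    gaz.to_csv(tmp_path / "gaz.csv")
    loaded = Gazetteer.from_csv(tmp_path / "gaz.csv")
    assert loaded.lookup("1 OAK AVE") == GeoPoint(43.0, -88.0)


def test_classification_examples():
    pharmacy = GeoPoint(43.0, -88.0)
    offsets = [0.0, 0.30, 0.50]  # miles due north
    points = [GeoPoint(43.0 + d / MILES_PER_DEGREE, -88.0) for d in offsets]
    out = classify_against_buffers(points, [pharmacy], radius=1 / 3)
    assert out["inside"].tolist() == [True, True, False]
    assert out["nearest_miles"].tolist() == pytest.approx(offsets, abs=1e-6)
    with pytest.raises(ValueError, match="resources"):
        classify_against_buffers(points, [], radius=1 / 3)
    with pytest.raises(ValueError, match="radius"):
        classify_against_buffers(points, [pharmacy], radius=0)


def test_classification_matches_brute_force():
    rng = random.Random(13)
    points = [GeoPoint(43 + rng.uniform(-0.1, 0.1), -88 + rng.uniform(-0.1, 0.1)) for _ in range(60)]
    resources = [GeoPoint(43 + rng.uniform(-0.1, 0.1), -88 + rng.uniform(-0.1, 0.1)) for _ in range(7)]
    out = classify_against_buffers(points, resources, radius=1 / 3)
    for i, p in enumerate(points):
        nearest = min(haversine_miles(p, r) for r in resources)
        assert out.loc[i, "nearest_miles"] == pytest.approx(nearest, abs=1e-9)
        assert out.loc[i, "inside"] == (nearest <= 1 / 3)


def test_radius_monotonicity():
    rng = random.Random(21)
    points = [GeoPoint(43 + rng.uniform(-0.05, 0.05), -88) for _ in range(40)]
    resources = [GeoPoint(43.0, -88.0)]
    inside_small = classify_against_buffers(points, resources, radius=0.2)["inside"]
    inside_large = classify_against_buffers(points, resources, radius=1 / 3)["inside"]
    assert not (inside_small & ~inside_large).any()


def test_planted_inside_count_recovered():
    """Buffer classification recovers the generator's planted inside-count."""
    gaz, pharmacies, events = generate_gazetteer_and_pharmacies(
        SynthConfig(seed=2), n_inside=17, n_outside=31
    )
    resources = [GeoPoint(r["lat"], r["lng"]) for _, r in pharmacies.iterrows()]
    points = [GeoPoint(r["lat"], r["lng"]) for _, r in events.iterrows()]
    out = classify_against_buffers(points, resources, radius=1 / 3)
    assert int(out["inside"].sum()) == 17
    assert out["inside"].astype(int).tolist() == events["planted_inside"].tolist()
    # every planted event is geocodable through the bundled gazetteer
    for _, r in events.iterrows():
        assert gaz.lookup(r["address"]) == GeoPoint(r["lat"], r["lng"])


def test_aggregate_by_region_counts_conserve():
    records = pd.DataFrame(
        {
            "injury_zip": ["A", "A", "A", "B", "B", None],
            "residence_zip": [None] * 5 + [None],
            "lat": [None] * 6,
            "lng": [None] * 6,
            "geo_resolution": ["zip"] * 5 + ["county"],
        }
    )
    counts, unaggregable = aggregate_by_region(records, "zip")
    assert counts == {"A": 3, "B": 2}
    assert unaggregable == 1
    assert sum(counts.values()) + unaggregable == len(records)
    empty_counts, empty_un = aggregate_by_region(records.iloc[:0], "zip")
    assert empty_counts == {} and empty_un == 0


def test_point_in_polygon_assignment():
    square = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"region_id": "Z1"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[-88.1, 42.9], [-87.9, 42.9], [-87.9, 43.1], [-88.1, 43.1], [-88.1, 42.9]]],
                },
            }
        ],
    }
    records = pd.DataFrame(
        {
            "injury_zip": [None, None],
            "residence_zip": [None, None],
            "lat": [43.0, 43.5],
            "lng": [-88.0, -88.0],
            "geo_resolution": ["point", "point"],
        }
    )
    counts, unaggregable = aggregate_by_region(records, "zip", region_polygons=square)
    assert counts == {"Z1": 1}
    assert unaggregable == 1


def test_geojson_export_shapes():
    zone = BufferZone(GeoPoint(43.0, -88.0))
    out = classify_against_buffers([GeoPoint(43.0, -88.0)], [zone.center], zone.radius)
    geojson = buffers_to_geojson([zone], out)
    kinds = [f["properties"]["kind"] for f in geojson["features"]]
    assert kinds == ["buffer", "event"]
    ring = geojson["features"][0]["geometry"]["coordinates"][0]
    assert len(ring) == 65  # 64 vertices, closed
    assert ring[0] == ring[-1]
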