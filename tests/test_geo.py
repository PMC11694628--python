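"""Geodesy and per-point feature extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tripgrid.geo import (
    EarthModel,
    GpsFix,
    UndefinedBearingError,
    azimuth_to_unit_circle,
    bearing,
    build_feature_table,
    central_speed,
    featurize_frame,
    haversine_distance,
)

R = 6371.0

finite_lat = st.floats(min_value=-89.0, max_value=89.0)
finite_lon = st.floats(min_value=-179.0, max_value=179.0)


def fix(ts, lat, lon):
    return GpsFix(timestamp=ts, lat=lat, lon=lon)


def law_of_cosines_km(a, b, r=R):
    """Independent spherical-law-of-cosines distance for cross-checking."""
    p1, p2 = math.radians(a.lat), math.radians(b.lat)
    dl = math.radians(b.lon - a.lon)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return r * math.acos(min(1.0, max(-1.0, c)))


class TestHaversine:
    def test_identity(self):
        assert haversine_distance(fix(0, 12.3, 45.6), fix(1, 12.3, 45.6)) == 0.0

    def test_antipodal_half_circumference(self):
        d = haversine_distance(fix(0, 0, 0), fix(1, 0, 180))
        assert d == pytest.approx(math.pi * R, rel=1e-12)

    def test_one_degree_meridian_arc(self):
        # closed form r * dphi for a meridian step, cross-checked against the
        # spherical law of cosines
        a, b = fix(0, 0, 0), fix(1, 1, 0)
        d = haversine_distance(a, b)
        assert d == pytest.approx(R * math.pi / 180.0, rel=1e-12)
        assert d == pytest.approx(law_of_cosines_km(a, b), abs=1e-9)

    def test_custom_radius(self):
        earth = EarthModel(radius_km=1.0)
        d = haversine_distance(fix(0, 0, 0), fix(1, 0, 180), earth)
        assert d == pytest.approx(math.pi)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GpsFix(0, float("nan"), 0)
        with pytest.raises(ValueError):
            GpsFix(0, 91.0, 0)
        with pytest.raises(ValueError):
            EarthModel(radius_km=-1.0)

    @given(lat1=finite_lat, lon1=finite_lon, lat2=finite_lat, lon2=finite_lon)
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        a, b = fix(0, lat1, lon1), fix(1, lat2, lon2)
        assert haversine_distance(a, b) == pytest.approx(
            haversine_distance(b, a), abs=1e-9
        )

    @given(
        lats=st.tuples(finite_lat, finite_lat, finite_lat),
        lons=st.tuples(finite_lon, finite_lon, finite_lon),
    )
    @settings(max_examples=200, deadline=None)
    def test_triangle_inequality(self, lats, lons):
        a, b, c = (fix(i, la, lo) for i, (la, lo) in enumerate(zip(lats, lons)))
        assert haversine_distance(a, c) <= (
            haversine_distance(a, b) + haversine_distance(b, c) + 1e-9
        )


class TestCentralSpeed:
    def test_no_displacement(self):
        assert central_speed(fix(0, 10, 10), fix(2, 10, 10)) == 0.0

    def test_twenty_meters_in_two_seconds(self):
        # 0.02 km over 2 s -> 36 kph; realized as a meridian step whose arc
        # length is exactly 0.02 km
        dlat = 0.02 / (R * math.pi / 180.0)
        v = central_speed(fix(0, 0, 0), fix(2, dlat, 0))
        assert v == pytest.approx(36.0, rel=1e-12)

    def test_two_arcsecond_meridian_step(self):
        # 2 arcsec of meridian in 2 s equals the one-degree-per-hour arc
        # speed, r*pi/180 km/h ~ 111.19 kph
        v = central_speed(fix(0, 0, 0), fix(2, 2 / 3600.0, 0))
        assert v == pytest.approx(R * math.pi / 180.0, rel=1e-9)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            central_speed(fix(5, 0, 0), fix(5, 1, 0))

    @given(shift=st.floats(min_value=-1e6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_time_shift_invariance(self, shift):
        v0 = central_speed(fix(0, 0, 0), fix(2, 0.001, 0))
        v1 = central_speed(fix(0 + shift, 0, 0), fix(2 + shift, 0.001, 0))
        assert v1 == pytest.approx(v0, rel=1e-9)


class TestBearing:
    def test_cardinal_directions(self):
        origin = fix(0, 0.0, 0.0)
        assert bearing(origin, fix(1, 0.01, 0.0)) == pytest.approx(0.0, abs=1e-9)
        assert bearing(origin, fix(1, 0.0, 0.01)) == pytest.approx(90.0, abs=1e-9)
        assert bearing(origin, fix(1, -0.01, 0.0)) == pytest.approx(180.0, abs=1e-9)
        assert bearing(origin, fix(1, 0.0, -0.01)) == pytest.approx(270.0, abs=1e-9)

    def test_diagonal_matches_planar_arctangent(self):
        # at small displacement with cos-lat-scaled dlon the azimuth tends to
        # the planar 45 degrees
        lat0 = 40.0
        dlat = 1e-4
        dlon = dlat / math.cos(math.radians(lat0))
        az = bearing(fix(0, lat0, 10.0), fix(1, lat0 + dlat, 10.0 + dlon))
        assert az == pytest.approx(45.0, abs=0.01)

    def test_coincident_points_undefined(self):
        with pytest.raises(UndefinedBearingError):
            bearing(fix(0, 5, 5), fix(1, 5, 5))

    @given(lat1=finite_lat, lon1=finite_lon, lat2=finite_lat, lon2=finite_lon)
    @settings(max_examples=200, deadline=None)
    def test_range(self, lat1, lon1, lat2, lon2):
        if (lat1, lon1) == (lat2, lon2):
            return
        az = bearing(fix(0, lat1, lon1), fix(1, lat2, lon2))
        assert 0.0 <= az < 360.0


class TestAzimuthUnitCircle:
    @pytest.mark.parametrize(
        "azimuth,expected",
        [
            (0.0, (0.0, 1.0)),
            (90.0, (1.0, 0.0)),
            (180.0, (0.0, -1.0)),
            (270.0, (-1.0, 0.0)),
            (360.0, (0.0, 1.0)),
            (45.0, (math.sqrt(2) / 2, math.sqrt(2) / 2)),
        ],
    )
    def test_anchor_points(self, azimuth, expected):
        x, y = azimuth_to_unit_circle(azimuth)
        assert x == pytest.approx(expected[0], abs=1e-12)
        assert y == pytest.approx(expected[1], abs=1e-12)

    def test_north_discontinuity_removed(self):
        assert azimuth_to_unit_circle(0.0) == azimuth_to_unit_circle(360.0)

    @given(az=st.floats(min_value=0.0, max_value=360.0))
    @settings(max_examples=200, deadline=None)
    def test_unit_norm(self, az):
        x, y = azimuth_to_unit_circle(az)
        assert x * x + y * y == pytest.approx(1.0, abs=1e-12)


class TestFeatureTable:
    def make_eastward_trip(self, n=13, kph=36.0):
        # constant-velocity eastward trip at the equator
        step_deg = (kph / 3600.0) / (R * math.pi / 180.0)
        return [fix(t, 0.0, t * step_deg) for t in range(n)]

    def test_one_record_per_fix(self):
        records = build_feature_table(self.make_eastward_trip(13))
        assert len(records) == 13

    def test_eastward_trip_features(self):
        records = build_feature_table(self.make_eastward_trip(10, kph=36.0))
        for r in records[:-1]:
            assert r.azimuth_deg == pytest.approx(90.0, abs=1e-6)
            assert (r.azimuth_x, r.azimuth_y) == pytest.approx((1.0, 0.0), abs=1e-8)
            assert r.speed_kph == pytest.approx(36.0, rel=1e-6)
        # the last fix has no successor: azimuth sentinel, zero step
        last = records[-1]
        assert (last.azimuth_x, last.azimuth_y) == (0.0, 0.0)
        assert last.step_distance_km == 0.0

    def test_stationary_trip(self):
        records = build_feature_table([fix(t, 5.0, 5.0) for t in range(5)])
        for r in records:
            assert r.step_distance_km == 0.0
            assert r.speed_kph == 0.0
            assert (r.azimuth_x, r.azimuth_y) == (0.0, 0.0)

    def test_short_trip_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_feature_table(self.make_eastward_trip(2))

    def test_nonmonotonic_timestamps_rejected(self):
        trip = [fix(0, 0, 0), fix(2, 0, 0.001), fix(1, 0, 0.002)]
        with pytest.raises(ValueError, match="increasing"):
            build_feature_table(trip)

    def test_sog_passthrough_and_imputation(self):
        trip = self.make_eastward_trip(5)
        sog = [30.0, None, 31.0, 32.0, None]
        records = build_feature_table(trip, sog=sog)
        assert records[0].sog_kph == 30.0 and not records[0].sog_imputed
        assert records[1].sog_imputed
        assert records[1].sog_kph == pytest.approx(records[1].speed_kph)

    def test_frame_and_record_paths_agree(self):
        trip = self.make_eastward_trip(8)
        df = pd.DataFrame(
            {
                "timestamp": [f.timestamp for f in trip],
                "lat": [f.lat for f in trip],
                "lon": [f.lon for f in trip],
            }
        )
        frame = featurize_frame(df)
        records = build_feature_table(trip)
        np.testing.assert_allclose(
            frame["speed_kph"].to_numpy(), [r.speed_kph for r in records]
        )
        np.testing.assert_allclose(
            frame["azimuth_x"].to_numpy(), [r.azimuth_x for r in records]
        )
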