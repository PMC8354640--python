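"""Track table I/O: reading, validation, filtering, round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heartbend.track_io import (
    CANONICAL_COLUMNS,
    Dialect,
    TrackIntegrityError,
    TrackSchemaError,
    TrackSet,
    filter_min_length,
    read_tracks,
    write_tracks,
)
from conftest import make_trackset


def write_csv(path, header, rows):
    lines = [",".join(header)] + [",".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadTracks:
    def test_minimal_three_row_file(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(
            p,
            CANONICAL_COLUMNS,
            [
                ("t1", 0, 0.0, 1.0, 2.0, 3.0, "ventricle"),
                ("t1", 1, 0.2, 1.1, 2.1, 3.1, "ventricle"),
                ("t1", 2, 0.4, 1.2, 2.2, 3.2, "ventricle"),
            ],
        )
        ts = read_tracks(p)
        assert ts.n_tracks == 1
        assert len(ts.records) == 3

    def test_case_insensitive_region_normalization(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(
            p, CANONICAL_COLUMNS, [("t1", 0, 0.0, 1, 2, 3, "Ventricle")]
        )
        ts = read_tracks(p, dialect=Dialect(region_case_insensitive=True))
        assert ts.records["region"].iloc[0] == "ventricle"

    def test_region_alias_mapping(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, CANONICAL_COLUMNS, [("t1", 0, 0.0, 1, 2, 3, "AV canal")])
        d = Dialect(region_aliases={"av canal": "avcanal"})
        assert read_tracks(p, dialect=d).records["region"].iloc[0] == "avcanal"

    def test_unknown_region_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, CANONICAL_COLUMNS, [("t1", 0, 0.0, 1, 2, 3, "aorta")])
        with pytest.raises(TrackIntegrityError, match="aorta"):
            read_tracks(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, ["track_id", "t_index", "x_um", "y_um", "region"],
                  [("t1", 0, 1, 2, "atrium")])
        with pytest.raises(TrackSchemaError, match="z_um"):
            read_tracks(p)

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(
            p, CANONICAL_COLUMNS,
            [("t1", 0, 0.0, 1, 2, 3, "atrium"),
             ("t1", 1, 0.2, "oops", 2, 3, "atrium")],
        )
        with pytest.raises(TrackSchemaError, match="row 1"):
            read_tracks(p)

    def test_duplicate_timepoint_is_integrity_error(self):
        rows = [
            ("t1", 0, 0.0, 1, 2, 3, "atrium"),
            ("t1", 0, 0.0, 4, 5, 6, "atrium"),
        ]
        with pytest.raises(TrackIntegrityError, match="duplicate"):
            make_trackset(rows)

    def test_foreign_dialect_column_mapping(self, tmp_path):
        p = tmp_path / "imaris.csv"
        write_csv(
            p,
            ["TrackID", "Time", "Position X", "Position Y", "Position Z", "Label"],
            [("1000000001", 0, 10.0, 20.0, 5.0, "Atrium")],
        )
        d = Dialect(
            columns={
                "track_id": "TrackID", "t_index": "Time", "t_hours": None,
                "x_um": "Position X", "y_um": "Position Y",
                "z_um": "Position Z", "region": "Label",
            }
        )
        ts = read_tracks(p, dialect=d, frame_period_hours=13 / 60)
        assert ts.records["region"].iloc[0] == "atrium"
        # t_hours synthesized from t_index x frame period
        assert np.isclose(ts.records["t_hours"].iloc[0], 0.0)

    def test_t_hours_synthesized_when_absent(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(
            p, ["track_id", "t_index", "x_um", "y_um", "z_um", "region"],
            [("t1", 3, 1, 2, 3, "atrium")],
        )
        d = Dialect(columns={**{c: c for c in CANONICAL_COLUMNS}, "t_hours": None})
        ts = read_tracks(p, dialect=d, frame_period_hours=0.25)
        assert np.isclose(ts.records["t_hours"].iloc[0], 0.75)


class TestWriteRoundTrip:
    def test_empty_set_writes_header_only(self, tmp_path):
        ts = make_trackset([])
        out = tmp_path / "empty.csv"
        write_tracks(ts, out)
        assert out.read_text().strip() == ",".join(CANONICAL_COLUMNS)

    def test_round_trip_is_bitwise_identity(self, tmp_path, rng):
        rows = []
        for i in range(20):
            region = ["ventricle", "avcanal", "atrium"][i % 3]
            for k in range(40):
                x, y, z = rng.normal(size=3) * 50
                rows.append((f"trk{i:02d}", k, k * 13 / 60, x, y, z, region))
        ts = make_trackset(rows)
        out = tmp_path / "rt.csv"
        write_tracks(ts, out)
        ts2 = read_tracks(out)
        pd.testing.assert_frame_equal(ts.records, ts2.records)
        # coordinates survive bit-comparably
        assert (
            ts.records["x_um"].to_numpy() == ts2.records["x_um"].to_numpy()
        ).all()


class TestFilterMinLength:
    @staticmethod
    def ladder():
        """10 tracks with lengths 5, 10, ..., 50."""
        rows = []
        for i, length in enumerate(range(5, 51, 5)):
            for k in range(length):
                rows.append((f"trk{i}", k, k * 0.2, 1.0 * k, 2.0, 3.0, "atrium"))
        return make_trackset(rows)

    def test_boundary_inclusive_at_15(self):
        rows = [("t1", k, k * 0.2, 1, 2, 3, "atrium") for k in range(15)]
        ts = filter_min_length(make_trackset(rows), min_points=15)
        assert ts.n_tracks == 1

    def test_boundary_exclusive_at_14(self):
        rows = [("t1", k, k * 0.2, 1, 2, 3, "atrium") for k in range(14)]
        ts = filter_min_length(make_trackset(rows), min_points=15)
        assert ts.n_tracks == 0

    def test_ladder_matches_brute_force_count(self):
        ts = self.ladder()
        expected = sum(1 for length in range(5, 51, 5) if length >= 15)
        out = filter_min_length(ts, min_points=15)
        assert out.n_tracks == expected == 8

    def test_idempotent_and_survivors_untouched(self):
        ts = self.ladder()
        once = filter_min_length(ts, min_points=15)
        twice = filter_min_length(once, min_points=15)
        pd.testing.assert_frame_equal(once.records, twice.records)
        surv = ts.records[ts.records["track_id"].isin(once.records["track_id"])]
        pd.testing.assert_frame_equal(
            once.records, surv.reset_index(drop=True)
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(lengths=st.lists(st.integers(1, 30), min_size=1, max_size=12),
           min_points=st.integers(1, 25))
    def test_filter_count_property(self, lengths, min_points):
        rows = []
        for i, length in enumerate(lengths):
            for k in range(length):
                rows.append((f"t{i}", k, k * 0.2, 0.0, 0.0, 0.0, "ventricle"))
        out = filter_min_length(make_trackset(rows), min_points=min_points)
        assert out.n_tracks == sum(1 for n in lengths if n >= min_points)


def test_trackset_rejects_nonfinite_and_negative_time():
    with pytest.raises(TrackIntegrityError):
        make_trackset([("t1", 0, 0.0, np.nan, 2, 3, "atrium")])
    with pytest.raises(TrackIntegrityError):
        make_trackset([("t1", -1, 0.0, 1, 2, 3, "atrium")])


def test_trackset_rejects_mixed_region_track():
    rows = [
        ("t1", 0, 0.0, 1, 2, 3, "atrium"),
        ("t1", 1, 0.2, 1, 2, 3, "ventricle"),
    ]
    with pytest.raises(TrackIntegrityError, match="multiple region"):
        make_trackset(rows)


def test_dialect_from_yaml_file(tmp_path):
    cfg = tmp_path / "map.yaml"
    cfg.write_text(
        "columns:\n  track_id: ID\nregion_aliases:\n  av: avcanal\n"
    )
    d = Dialect.from_file(cfg)
    assert d.columns["track_id"] == "ID"
    assert d.normalize_region("AV") == "avcanal"
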