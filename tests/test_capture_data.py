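"""Detector/capture I/O and robust-design history construction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import opencamscr as oc
from opencamscr import capture_data as cd


def _write_detectors(path, rows):
    path.write_text(
        "detector_id,site_id,x_m,y_m\n" + "\n".join(",".join(map(str, r)) for r in rows)
    )


class TestReadDetectors:
    def test_two_cameras_one_site(self, tmp_path):
        f = tmp_path / "d.csv"
        _write_detectors(f, [("a", "s1", 0, 0), ("b", "s1", 10, 0)])
        arr = cd.read_detectors(f)
        assert arr.n_sites == 1
        assert len(arr.detectors) == 2

    def test_duplicate_id_errors_naming_it(self, tmp_path):
        f = tmp_path / "d.csv"
        _write_detectors(f, [("a", "s1", 0, 0), ("a", "s2", 10, 0)])
        with pytest.raises(ValueError, match="a"):
            cd.read_detectors(f)

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("detector_id,site_id,x_m,y_m\na,s1,0,0\nb,s2,oops,0\n")
        with pytest.raises(ValueError, match="row 3"):
            cd.read_detectors(f)

    def test_grid_round_trip(self, tmp_path, study_array):
        """55-site design survives read -> write -> read bit-identically."""
        f1, f2 = tmp_path / "d1.csv", tmp_path / "d2.csv"
        cd.write_detectors(study_array, f1)
        arr = cd.read_detectors(f1)
        assert arr.n_sites == 55
        cd.write_detectors(arr, f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestReadCaptures:
    def test_empty_file(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text("individual_id,datetime_iso,detector_id,sex,status\n")
        assert len(cd.read_captures(f)) == 0

    def test_unknown_sex_parsed(self, tmp_path):
        f = tmp_path / "c.csv"
        f.write_text(
            "individual_id,datetime_iso,detector_id,sex,status\n"
            "i1,2009-10-01T12:00:00,a,U,independent\n"
        )
        rec = cd.read_captures(f)
        assert rec.loc[0, "sex"] == "U"

    def test_out_of_period_flagged_but_kept(self, tmp_path, small_spec):
        f = tmp_path / "c.csv"
        f.write_text(
            "individual_id,datetime_iso,detector_id,sex,status\n"
            "i1,2008-01-01T12:00:00,a,F,independent\n"
        )
        with pytest.warns(UserWarning, match="outside"):
            rec = cd.read_captures(f, small_spec)
        assert len(rec) == 1 and not rec.loc[0, "in_period"]

    def test_simulated_round_trip(self, tmp_path, fixture_bundle):
        out, bundle = fixture_bundle
        rec = cd.read_captures(out / "captures.csv", bundle["spec"])
        assert len(rec) == len(bundle["captures"])
        assert rec["datetime"].notna().all()


class TestBuildRobustHistory:
    def test_multiple_same_site_same_day_collapse(self, tiny_array, small_spec):
        day = "2009-09-20T"
        rows = [
            ("i1", day + "08:00:00", "c1a", "F", "independent"),
            ("i1", day + "09:00:00", "c1a", "F", "independent"),
            ("i1", day + "10:00:00", "c1b", "F", "independent"),
        ]
        rec = pd.DataFrame(
            {
                "individual_id": [r[0] for r in rows],
                "datetime": pd.to_datetime([r[1] for r in rows]),
                "detector_id": [r[2] for r in rows],
                "sex": [r[3] for r in rows],
                "status": [r[4] for r in rows],
                "in_period": True,
            }
        )
        h = cd.build_robust_history(rec, tiny_array, small_spec)
        assert h.y.sum() == 1
        assert h.y[0, 0, 5, 0] == 1  # Sep 20 is day 5 of the Sep 15 window

    def test_empty_records(self, tiny_array, small_spec):
        rec = pd.DataFrame(
            columns=["individual_id", "datetime", "detector_id", "sex", "status",
                     "in_period"]
        )
        h = cd.build_robust_history(rec, tiny_array, small_spec)
        assert h.y.shape == (0, 2, 40, 3)
        assert h.y.sum() == 0

    def test_simulator_parser_consistency(self, fixture_bundle):
        """Records regenerated from a simulated history rebuild it exactly."""
        out, bundle = fixture_bundle
        rebuilt = cd.build_robust_history(
            bundle["captures"], bundle["array"], bundle["spec"]
        )
        orig = bundle["history"]
        order = [rebuilt.individual_ids.index(i) for i in orig.individual_ids]
        assert np.array_equal(rebuilt.y[order], orig.y)
        assert np.array_equal(rebuilt.usage, orig.usage)

    def test_idempotent_on_binned_data(self, fixture_bundle):
        out, bundle = fixture_bundle
        rec = bundle["captures"]
        h1 = cd.build_robust_history(rec, bundle["array"], bundle["spec"])
        h2 = cd.build_robust_history(rec, bundle["array"], bundle["spec"])
        assert np.array_equal(h1.y, h2.y)

    def test_binned_detections_bounded_by_raw(self, fixture_bundle):
        out, bundle = fixture_bundle
        h = cd.build_robust_history(bundle["captures"], bundle["array"], bundle["spec"])
        assert h.y.sum() <= len(bundle["captures"])


class TestCollapseOccasions:
    def test_hundred_days_to_twenty_occasions(self, study_array):
        J = study_array.n_sites
        y = np.zeros((2, J, 100, 1), dtype=np.uint8)
        y[0, 3, 57, 0] = 1
        usage = np.ones((J, 100, 1), dtype=np.uint8)
        h = cd.RobustDesignHistory(
            y=y, site_coords=study_array.site_coords(), usage=usage,
            sexes=np.array([0, 1], dtype=np.int8),
        )
        c = cd.collapse_occasions(h, 5)
        assert c.y.shape == (2, J, 20)
        assert c.y[0, 3, 11] == 1  # day 57 lands in occasion 11
        assert np.all(c.usage == 5)

    def test_all_zero_history(self, tiny_array, small_spec):
        rec = pd.DataFrame(
            columns=["individual_id", "datetime", "detector_id", "sex", "status",
                     "in_period"]
        )
        h = cd.build_robust_history(rec, tiny_array, small_spec)
        c = cd.collapse_occasions(h, 5)
        assert c.y.sum() == 0

    def test_matches_logical_or_oracle(self):
        rng = np.random.default_rng(9)
        y = (rng.random((4, 3, 40, 2)) < 0.1).astype(np.uint8)
        usage = np.ones((3, 40, 2), dtype=np.uint8)
        h = cd.RobustDesignHistory(
            y=y, site_coords=np.zeros((3, 2)), usage=usage,
            sexes=np.zeros(4, dtype=np.int8),
        )
        c = cd.collapse_occasions(h, 5, period=1)
        for i in range(4):
            for j in range(3):
                for k in range(8):
                    expect = int(y[i, j, 5 * k: 5 * k + 5, 1].any())
                    assert c.y[i, j, k] == expect

    def test_invalid_block_length(self, study_array):
        h = cd.RobustDesignHistory(
            y=np.zeros((1, 55, 10, 1), dtype=np.uint8),
            site_coords=study_array.site_coords(),
            usage=np.ones((55, 10, 1), dtype=np.uint8),
            sexes=np.zeros(1, dtype=np.int8),
        )
        with pytest.raises(ValueError):
            cd.collapse_occasions(h, 0)


class TestHistorySerialization:
    def test_round_trip(self, fixture_bundle, tmp_path):
        out, bundle = fixture_bundle
        h = bundle["history"]
        f = tmp_path / "h.txt"
        cd.write_history(h, f)
        back = cd.read_history(f)
        assert np.array_equal(back.y, h.y)
        assert np.array_equal(back.usage, h.usage)
        assert np.array_equal(back.sexes, h.sexes)
        assert back.individual_ids == h.individual_ids
        assert np.allclose(back.site_coords, h.site_coords)


def test_detection_where_usage_zero_rejected():
    y = np.zeros((1, 1, 2, 1), dtype=np.uint8)
    y[0, 0, 1, 0] = 1
    usage = np.zeros((1, 2, 1), dtype=np.uint8)
    usage[0, 0, 0] = 1
    with pytest.raises(ValueError, match="usage"):
        cd.RobustDesignHistory(
            y=y, site_coords=np.zeros((1, 2)), usage=usage,
            sexes=np.zeros(1, dtype=np.int8),
        )
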