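"""Manifest filtering, district aggregation and mappable exports."""

import json

import numpy as np
import pytest
from PIL import Image

import greenview as gv
from greenview.exceptions import InputError
from greenview.survey import read_district_csv

SQUARE = [[135.0, 35.0], [135.1, 35.0], [135.1, 35.1], [135.0, 35.1], [135.0, 35.0]]


def record(image_id, path, district="D1", heading=0):
    return gv.ImageRecord(image_id, district, 35.0, 135.75, heading, str(path))


@pytest.fixture()
def image_files(tmp_path, rng):
    """textured scene, its byte-identical duplicate, and a blank frame"""
    textured = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
    blank = np.full((64, 64, 3), 128, np.uint8)
    paths = {}
    for name, arr in [("a", textured), ("blank", blank)]:
        p = tmp_path / f"{name}.png"
        Image.fromarray(arr).save(p)
        paths[name] = p
    dup = tmp_path / "dup.png"
    dup.write_bytes(paths["a"].read_bytes())
    paths["dup"] = dup
    return paths


class TestFilterImages:
    def test_reasons_and_count_conservation(self, image_files):
        records = [
            record("a", image_files["a"]),
            record("dup", image_files["dup"]),
            record("blank", image_files["blank"]),
        ]
        kept, dropped = gv.filter_images(records)
        assert [r.image_id for r in kept] == ["a"]
        assert {d.record.image_id: d.reason for d in dropped} == {
            "dup": "duplicate",
            "blank": "blank",
        }
        assert len(kept) + len(dropped) == len(records)

    def test_first_occurrence_kept_by_manifest_order(self, image_files):
        records = [
            record("dup", image_files["dup"]),
            record("a", image_files["a"]),
        ]
        kept, dropped = gv.filter_images(records)
        assert [r.image_id for r in kept] == ["dup"]
        assert dropped[0].record.image_id == "a"

    def test_idempotent(self, image_files):
        records = [
            record("a", image_files["a"]),
            record("dup", image_files["dup"]),
            record("blank", image_files["blank"]),
        ]
        kept, _ = gv.filter_images(records)
        kept2, dropped2 = gv.filter_images(kept)
        assert kept2 == kept and dropped2 == []

    def test_manual_exclude_list(self, image_files):
        records = [record("a", image_files["a"])]
        kept, dropped = gv.filter_images(records, exclude_ids=["a"])
        assert kept == [] and dropped[0].reason == "excluded"

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(InputError, match="ghost.png"):
            gv.filter_images([record("g", tmp_path / "ghost.png")])

    def test_invalid_heading_rejected(self, image_files):
        with pytest.raises(InputError):
            record("a", image_files["a"], heading=45)


def igvi(district, value, i=[0]):
    i[0] += 1
    return gv.ImageGVI(f"img-{i[0]}", district, value)


class TestAggregateDistricts:
    def test_mean_of_two(self):
        out = gv.aggregate_districts([igvi("D1", 10), igvi("D1", 20)], min_images=2)
        assert out == [gv.DistrictGVI("D1", 2, 15.0)]

    def test_below_minimum_excluded(self):
        gvis = [igvi("D1", 5.0) for _ in range(9)]
        assert gv.aggregate_districts(gvis, min_images=10) == []
        assert len(gv.aggregate_districts(gvis, min_images=9)) == 1

    def test_identical_gvi_idempotent_mean(self):
        gvis = [igvi("D2", 12.25) for _ in range(12)]
        (out,) = gv.aggregate_districts(gvis)
        assert out.mean_gvi == pytest.approx(12.25)
        assert out.n_images == 12

    def test_mean_bounded_by_extremes_and_sorted(self, rng):
        gvis = []
        for d in ["B", "A", "C"]:
            for _ in range(10):
                gvis.append(igvi(d, float(rng.uniform(0, 100))))
        out = gv.aggregate_districts(gvis)
        assert [d.district_id for d in out] == ["A", "B", "C"]
        for d in out:
            vals = [g.gvi_percent for g in gvis if g.district_id == d.district_id]
            assert min(vals) <= d.mean_gvi <= max(vals)

    def test_empty_input_empty_output(self):
        assert gv.aggregate_districts([]) == []


class TestExport:
    def polygons(self, ids):
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"district_id": d},
                    "geometry": {"type": "Polygon", "coordinates": [SQUARE]},
                }
                for d in ids
            ],
        }

    def test_feature_per_district(self, tmp_path):
        districts = [gv.DistrictGVI("D1", 12, 16.25), gv.DistrictGVI("D2", 10, 4.75)]
        fc = gv.export_district_gvi(
            districts,
            self.polygons(["D1", "D2"]),
            tmp_path / "out.geojson",
            tmp_path / "out.csv",
        )
        assert len(fc["features"]) == 2
        props = fc["features"][0]["properties"]
        assert props == {"district_id": "D1", "n_images": 12, "mean_gvi": 16.25}
        written = json.loads((tmp_path / "out.geojson").read_text())
        assert written == fc

    def test_district_without_polygon_csv_only(self, tmp_path, caplog):
        districts = [gv.DistrictGVI("D1", 10, 8.0), gv.DistrictGVI("D9", 10, 9.0)]
        fc = gv.export_district_gvi(
            districts,
            self.polygons(["D1"]),
            tmp_path / "out.geojson",
            tmp_path / "out.csv",
        )
        assert [f["properties"]["district_id"] for f in fc["features"]] == ["D1"]
        rows = read_district_csv(tmp_path / "out.csv")
        assert [r.district_id for r in rows] == ["D1", "D9"]

    def test_roundtrip_preserves_mean_to_2_decimals(self, tmp_path):
        districts = [gv.DistrictGVI("D1", 11, 100 * 117 / 400 + 1e-9)]
        gv.export_district_gvi(
            districts, self.polygons(["D1"]),
            tmp_path / "o.geojson", tmp_path / "o.csv",
        )
        (row,) = read_district_csv(tmp_path / "o.csv")
        assert row.mean_gvi == pytest.approx(29.25, abs=0.005)

    def test_malformed_boundaries_rejected(self, tmp_path):
        with pytest.raises(InputError):
            gv.export_district_gvi(
                [], {"type": "Feature"}, tmp_path / "o.geojson", tmp_path / "o.csv"
            )


class TestManifestIO:
    def test_roundtrip(self, tmp_path):
        records = [
            gv.ImageRecord("i1", "D1", 35.0, 135.7, 0, "/tmp/i1.png"),
            gv.ImageRecord("i2", "D2", 35.1, 135.8, 270, "/tmp/i2.png"),
        ]
        path = tmp_path / "manifest.csv"
        gv.write_manifest(records, path)
        assert gv.read_manifest(path) == records
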