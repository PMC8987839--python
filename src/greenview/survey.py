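"""Survey manifest management, exclusion rules and district aggregation.

A Green View Index survey collects four cardinal-heading images per
sample point across many administrative districts.  This module applies
the collection-stage exclusion rules (byte-identical duplicates, blank
frames), averages per-image GVI within districts that reached the
minimum image count, and exports district means as GeoJSON + CSV for
mapping.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .exceptions import InputError
from .grid import ImageGVI

logger = logging.getLogger(__name__)

VALID_HEADINGS = (0, 90, 180, 270)


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    district_id: str
    latitude: float
    longitude: float
    heading: int
    path: str

    def __post_init__(self) -> None:
        if self.heading not in VALID_HEADINGS:
            raise InputError(
                f"heading must be one of {VALID_HEADINGS}, got {self.heading}"
            )


@dataclass(frozen=True)
class DroppedImage:
    record: ImageRecord
    reason: str  # "duplicate" | "blank"


@dataclass(frozen=True)
class DistrictGVI:
    district_id: str
    n_images: int
    mean_gvi: float


# ---------------------------------------------------------------------------
# manifest I/O: image_id,district_id,lat,lon,heading,path

_MANIFEST_HEADER = ["image_id", "district_id", "lat", "lon", "heading", "path"]


def read_manifest(path: str | Path) -> list[ImageRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _MANIFEST_HEADER:
            raise InputError(
                f"manifest {path} must have header {','.join(_MANIFEST_HEADER)}"
            )
        return [
            ImageRecord(
                image_id=row["image_id"],
                district_id=row["district_id"],
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                heading=int(row["heading"]),
                path=row["path"],
            )
            for row in reader
        ]


def write_manifest(records: Iterable[ImageRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_HEADER)
        for r in records:
            writer.writerow(
                [r.image_id, r.district_id, r.latitude, r.longitude, r.heading, r.path]
            )


# ---------------------------------------------------------------------------
# exclusion rules


def filter_images(
    records: Sequence[ImageRecord],
    blank_std_epsilon: float = 1.0,
    exclude_ids: Iterable[str] = (),
) -> tuple[list[ImageRecord], list[DroppedImage]]:
    """Apply the survey exclusion rules, preserving manifest order.

    Byte-identical files (content hash) are dropped after their first
    occurrence as duplicates; images whose per-channel pixel standard
    deviation all fall below ``blank_std_epsilon`` (0-255 scale) are
    dropped as blank.  ``exclude_ids`` is the manual exclude-list hook
    for images (e.g. blurred frames) a curator struck by hand; those drop
    with reason ``"excluded"``.  Every drop carries its reason code;
    ``len(kept) + len(dropped) == len(records)``.
    """
    exclude = set(exclude_ids)
    kept: list[ImageRecord] = []
    dropped: list[DroppedImage] = []
    seen_hashes: set[str] = set()
    for rec in records:
        if rec.image_id in exclude:
            dropped.append(DroppedImage(rec, "excluded"))
            continue
        p = Path(rec.path)
        if not p.exists():
            raise InputError(f"image file not found: {rec.path}")
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest in seen_hashes:
            dropped.append(DroppedImage(rec, "duplicate"))
            continue
        arr = np.asarray(Image.open(p).convert("RGB"), dtype=np.float64)
        if arr.std(axis=(0, 1)).max() < blank_std_epsilon:
            dropped.append(DroppedImage(rec, "blank"))
            continue
        seen_hashes.add(digest)
        kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# district aggregation


def aggregate_districts(
    image_gvis: Sequence[ImageGVI], min_images: int = 10
) -> list[DistrictGVI]:
    """Unweighted pooled mean of per-image GVI within each district;
    districts with fewer than ``min_images`` images are excluded.
    Output sorted by district id."""
    by_district: dict[str, list[float]] = {}
    for g in image_gvis:
        by_district.setdefault(g.district_id, []).append(g.gvi_percent)
    out = [
        DistrictGVI(district_id=d, n_images=len(vals), mean_gvi=float(np.mean(vals)))
        for d, vals in by_district.items()
        if len(vals) >= min_images
    ]
    return sorted(out, key=lambda d: d.district_id)


# ---------------------------------------------------------------------------
# export


def export_district_gvi(
    districts: Sequence[DistrictGVI],
    polygons: dict,
    geojson_path: str | Path,
    csv_path: str | Path,
) -> dict:
    """Write one polygon feature per district (properties district_id,
    n_images, mean_gvi) plus a flat CSV twin.

    ``polygons`` is a GeoJSON FeatureCollection mapping; each feature
    must carry a ``district_id`` property.  Districts without a polygon
    still appear in the CSV but not in the feature collection (warning
    logged).  Returns the written FeatureCollection.
    """
    if polygons.get("type") != "FeatureCollection":
        raise InputError("district boundaries must be a GeoJSON FeatureCollection")
    geom_by_id: dict[str, dict] = {}
    for feat in polygons.get("features", []):
        props = feat.get("properties") or {}
        did = props.get("district_id")
        if did is None or "geometry" not in feat:
            raise InputError("boundary feature lacks district_id or geometry")
        geom_by_id[str(did)] = feat["geometry"]

    features = []
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["district_id", "n_images", "mean_gvi"])
        for d in districts:
            writer.writerow([d.district_id, d.n_images, f"{d.mean_gvi:.2f}"])
            geom = geom_by_id.get(d.district_id)
            if geom is None:
                logger.warning("no polygon for district %s; CSV only", d.district_id)
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": geom,
                    "properties": {
                        "district_id": d.district_id,
                        "n_images": d.n_images,
                        "mean_gvi": round(d.mean_gvi, 2),
                    },
                }
            )
    collection = {"type": "FeatureCollection", "features": features}
    Path(geojson_path).write_text(json.dumps(collection, indent=2))
    return collection


def read_district_csv(path: str | Path) -> list[DistrictGVI]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            DistrictGVI(
                district_id=row["district_id"],
                n_images=int(row["n_images"]),
                mean_gvi=float(row["mean_gvi"]),
            )
            for row in reader
        ]
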