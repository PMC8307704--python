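"""Calibrated scar planimetry from annotated wound photographs.

Wounds were photographed on days 1, 2, 3, 4, 7, 14, 21, 28, 35, 45 and 60
with a millimetre scale in frame; a blinded annotator traced each scar's area
(up to 3 replicate polygons), length (3 replicate polylines) and width
(3 segments in each of the rostral, central and caudal thirds).  This module
turns those pixel annotations plus the scale calibration into physical
area/length/width records and per-group time-series summaries.

Coordinates are 0-based pixel units (x right, y down); polygons are
implicitly closed and must be simple (self-intersections are rejected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

OBSERVATION_DAYS = (1, 2, 3, 4, 7, 14, 21, 28, 35, 45, 60)
WIDTH_REGIONS = ("rostral", "central", "caudal")


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixels per millimetre, from the photographed 1 cm scale bar."""

    pixels_per_mm: float

    def __post_init__(self) -> None:
        if not self.pixels_per_mm > 0:
            raise ValueError("pixels_per_mm must be positive")


@dataclass
class ScarAnnotation:
    """Pixel-space annotations of one wound photograph.

    area_polygons : up to 3 replicate outlines, each an (n>=3, 2) array of
        (x, y) vertices.
    length_polylines : up to 3 replicate polylines, each (n>=2, 2).
    width_segments : per width region, a list of 2-point segments.
    """

    animal: str
    group: str
    site: str
    day: int
    calibration: ScaleCalibration
    area_polygons: list[np.ndarray] = field(default_factory=list)
    length_polylines: list[np.ndarray] = field(default_factory=list)
    width_segments: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day not in OBSERVATION_DAYS:
            raise ValueError(f"day {self.day} outside the observation schedule")
        if len(self.area_polygons) > 3 or len(self.length_polylines) > 3:
            raise ValueError("at most 3 replicate measures per quantity")
        for segs in self.width_segments.values():
            if len(segs) > 3:
                raise ValueError("at most 3 width segments per region")


@dataclass
class PlanimetryRecord:
    """Calibrated per-wound, per-day scar dimensions (mm / mm^2)."""

    animal: str
    site: str
    group: str
    day: int
    area_mm2: float
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.day not in OBSERVATION_DAYS:
            raise ValueError(f"day {self.day} outside the observation schedule")
        if min(self.area_mm2, self.length_mm, self.width_mm) < 0:
            raise ValueError("measures must be non-negative")


def polygon_area(vertices, calibration: ScaleCalibration) -> float:
    """Polygon area in mm^2 by the shoelace formula; orientation-independent."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("a polygon needs at least 3 (x, y) vertices")
    poly = _ShapelyPolygon(v)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon rejected")
    x, y = v[:, 0], v[:, 1]
    shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(shoelace / calibration.pixels_per_mm**2)


def polyline_length(points, calibration: ScaleCalibration) -> float:
    """Total Euclidean length of a polyline in mm."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
        raise ValueError("a polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum() / calibration.pixels_per_mm)


def summarize_wound(annotation: ScarAnnotation) -> PlanimetryRecord:
    """Average replicate measures of one photograph into a single record.

    Area and length are means of their (up to 3) replicates; width is the
    equal-weight mean of all width segments across the three regions (the
    per-region and pooled means coincide when each region has equal counts).
    """
    cal = annotation.calibration
    if not annotation.area_polygons and not annotation.length_polylines and not any(
        annotation.width_segments.values()
    ):
        raise ValueError("annotation holds no measurements")
    areas = [polygon_area(p, cal) for p in annotation.area_polygons]
    lengths = [polyline_length(p, cal) for p in annotation.length_polylines]
    widths = [
        polyline_length(seg, cal)
        for segs in annotation.width_segments.values()
        for seg in segs
    ]
    return PlanimetryRecord(
        animal=annotation.animal,
        site=annotation.site,
        group=annotation.group,
        day=annotation.day,
        area_mm2=float(np.mean(areas)) if areas else 0.0,
        length_mm=float(np.mean(lengths)) if lengths else 0.0,
        width_mm=float(np.mean(widths)) if widths else 0.0,
    )


def records_to_frame(records: list[PlanimetryRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no planimetry records")
    return pd.DataFrame([vars(r) for r in records])


def build_timeseries(records: list[PlanimetryRecord] | pd.DataFrame) -> pd.DataFrame:
    """Group x day mean/SD/n for area, length and mean width."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no planimetry records")
    out = (
        df.groupby(["group", "day"])[["area_mm2", "length_mm", "width_mm"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out.columns = ["_".join(c).rstrip("_") for c in out.columns]
    return out


# ---------------------------------------------------------------------------
# JSON round trip (one file per photograph)

def save_annotation(annotation: ScarAnnotation, path: str | Path) -> None:
    payload = {
        "animal": annotation.animal,
        "group": annotation.group,
        "site": annotation.site,
        "day": annotation.day,
        "pixels_per_mm": annotation.calibration.pixels_per_mm,
        "area_polygons": [np.asarray(p).tolist() for p in annotation.area_polygons],
        "length_polylines": [np.asarray(p).tolist() for p in annotation.length_polylines],
        "width_segments": {
            k: [np.asarray(s).tolist() for s in v]
            for k, v in annotation.width_segments.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_annotation(path: str | Path) -> ScarAnnotation:
    cfg = json.loads(Path(path).read_text())
    return ScarAnnotation(
        animal=cfg["animal"],
        group=cfg["group"],
        site=cfg["site"],
        day=int(cfg["day"]),
        calibration=ScaleCalibration(float(cfg["pixels_per_mm"])),
        area_polygons=[np.asarray(p, float) for p in cfg.get("area_polygons", [])],
        length_polylines=[np.asarray(p, float) for p in cfg.get("length_polylines", [])],
        width_segments={
            k: [np.asarray(s, float) for s in v]
            for k, v in cfg.get("width_segments", {}).items()
        },
    )
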