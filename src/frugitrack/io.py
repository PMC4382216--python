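"""Readers and writers for the package's plain-text data formats.

Timestamps are ISO-8601 in files and seconds relative to a study epoch in
memory.  Land cover travels either as GeoJSON polygon features carrying a
``category`` property or as an ESRI-ASCII-style grid of integer category
codes.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .habitat import CATEGORIES, GridLandCover, PolygonLandCover
from .telemetry import BearingRecord, Fix, Rejection

__all__ = [
    "ParseError",
    "EPOCH",
    "read_bearings",
    "write_bearings",
    "read_fixes",
    "write_fixes",
    "write_rejections",
    "read_roosts",
    "write_roosts",
    "read_landcover",
    "write_landcover_grid",
    "write_landcover_geojson",
]

#: study epoch: internal second 0 in ISO timestamps
EPOCH = pd.Timestamp("2011-02-01T18:00:00")


class ParseError(ValueError):
    pass


def seconds_to_iso(t: float) -> str:
    return (EPOCH + pd.Timedelta(seconds=float(t))).isoformat()


def iso_to_seconds(s: str) -> float:
    return float((pd.Timestamp(s) - EPOCH).total_seconds())


BEARING_COLUMNS = ["timestamp_iso", "bat_id", "obs1_x", "obs1_y",
                   "azimuth1_deg", "obs2_x", "obs2_y", "azimuth2_deg",
                   "activity"]


def read_bearings(path) -> list[BearingRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(BEARING_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(BearingRecord(
                    timestamp=iso_to_seconds(row["timestamp_iso"]),
                    bat_id=row["bat_id"],
                    observer_pos_1=(float(row["obs1_x"]), float(row["obs1_y"])),
                    observer_pos_2=(float(row["obs2_x"]), float(row["obs2_y"])),
                    azimuth_1=float(row["azimuth1_deg"]),
                    azimuth_2=float(row["azimuth2_deg"]),
                    activity=row["activity"] or "unknown",
                ))
            except (ValueError, TypeError, KeyError) as e:
                raise ParseError(f"{path}: malformed bearing row at line {lineno}: {e}") from e
    return records


def write_bearings(path, records: list[BearingRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(BEARING_COLUMNS)
        for r in records:
            w.writerow([
                seconds_to_iso(r.timestamp), r.bat_id,
                f"{r.observer_pos_1[0]:.3f}", f"{r.observer_pos_1[1]:.3f}",
                f"{r.azimuth_1:.3f}",
                f"{r.observer_pos_2[0]:.3f}", f"{r.observer_pos_2[1]:.3f}",
                f"{r.azimuth_2:.3f}", r.activity,
            ])


def read_fixes(path) -> list[Fix]:
    fixes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                fixes.append(Fix(
                    timestamp=iso_to_seconds(row["timestamp_iso"]),
                    bat_id=row["bat_id"],
                    session_id=int(row["session_id"]),
                    position=(float(row["x"]), float(row["y"])),
                ))
            except (ValueError, TypeError, KeyError) as e:
                raise ParseError(f"{path}: malformed fix row at line {lineno}: {e}") from e
    return fixes


def write_fixes(path, fixes: list[Fix]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp_iso", "bat_id", "session_id", "x", "y"])
        for f in fixes:
            w.writerow([seconds_to_iso(f.timestamp), f.bat_id, f.session_id,
                        f"{f.position[0]:.3f}", f"{f.position[1]:.3f}"])


def write_rejections(path, rejections: list[Rejection]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp_iso", "bat_id", "reason"])
        for r in rejections:
            w.writerow([seconds_to_iso(r.timestamp), r.bat_id, r.reason])


def read_roosts(path) -> pd.DataFrame:
    """Roost table: bat_id, x, y and an optional sex column."""
    df = pd.read_csv(path)
    required = {"bat_id", "x", "y"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: roosts file needs columns {sorted(required)}")
    return df


def write_roosts(path, roosts: dict[str, list[tuple[float, float]]],
                 sex: dict[str, str] | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bat_id", "x", "y", "sex"])
        for bat_id, pts in roosts.items():
            for x, y in pts:
                w.writerow([bat_id, f"{x:.3f}", f"{y:.3f}",
                            (sex or {}).get(bat_id, "")])


def read_landcover(path):
    """Read a land-cover map from GeoJSON polygons or an ASCII grid."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_landcover_geojson(path)
    return _read_landcover_grid(path)


def _read_landcover_geojson(path) -> PolygonLandCover:
    with open(path) as fh:
        gj = json.load(fh)
    features = []
    background = gj.get("properties", {}).get("background", "pasture")
    for i, feat in enumerate(gj.get("features", [])):
        cat = feat.get("properties", {}).get("category")
        if cat not in CATEGORIES:
            raise ParseError(f"{path}: feature {i} has unknown category {cat!r}")
        features.append((shape(feat["geometry"]), cat))
    return PolygonLandCover(features, background=background)


def write_landcover_geojson(path, landcover: PolygonLandCover) -> None:
    gj = {
        "type": "FeatureCollection",
        "properties": {"background": landcover.background},
        "features": [
            {"type": "Feature", "properties": {"category": cat},
             "geometry": mapping(poly)}
            for poly, cat in landcover.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def _read_landcover_grid(path) -> GridLandCover:
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(v) for v in parts])
    try:
        nc, nr = int(header["ncols"]), int(header["nrows"])
        codes = np.array(rows, dtype=int)
        if codes.shape != (nr, nc):
            raise ParseError(f"{path}: grid shape {codes.shape} does not match header")
        # ASCII grids store the northern row first; internal row 0 is southern
        return GridLandCover(codes[::-1], header["xllcorner"],
                             header["yllcorner"], header["cellsize"])
    except KeyError as e:
        raise ParseError(f"{path}: missing grid header field {e}") from e


def write_landcover_grid(path, landcover: GridLandCover) -> None:
    nr, nc = landcover.codes.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n")
        fh.write(f"xllcorner {landcover.xll}\nyllcorner {landcover.yll}\n")
        fh.write(f"cellsize {landcover.cellsize}\n")
        for row in landcover.codes[::-1]:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_polygons_geojson(path, polygons, properties=None) -> None:
    """Write a list of shapely polygons as a GeoJSON FeatureCollection."""
    props = properties or [{} for _ in polygons]
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": p, "geometry": mapping(poly)}
            for poly, p in zip(polygons, props)
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)
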