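"""Raster, vector and station-table I/O.

Rasters travel as single-band TIFFs: float32 for continuous grids, uint8 or
uint16 for categorical ones, with the grid's georeferencing (cell size,
top-left origin, CRS label) and nodata value stored as JSON in the TIFF
ImageDescription tag.  Vectors travel as GeoJSON FeatureCollections whose
properties carry the controlled vocabularies; stations as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape

from .grids import Grid, GridSpec, MineFeature, StationSeries

STATION_COLUMNS = ["station_id", "x", "y", "month", "rainfall", "temperature",
                   "solar_radiation", "aqi", "wind_speed"]


def write_raster(g: Grid, path: str | Path) -> None:
    """Write a grid as a single-band TIFF with embedded grid metadata."""
    if g.kind == "categorical":
        vmax = int(np.nanmax(g.values)) if g.values.size else 0
        dtype = np.uint8 if vmax < 256 else np.uint16
        data = g.values.astype(dtype)
    else:
        data = np.asarray(g.values, dtype=np.float32)
    meta = {
        "n_rows": g.spec.n_rows, "n_cols": g.spec.n_cols,
        "cell_size": g.spec.cell_size,
        "origin_x": g.spec.origin_x, "origin_y": g.spec.origin_y,
        "crs_label": g.spec.crs_label,
        "nodata": None if g.nodata is None else (
            "nan" if isinstance(g.nodata, float) and np.isnan(g.nodata)
            else g.nodata),
        "kind": g.kind,
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_raster(path: str | Path, expect_spec: GridSpec | None = None) -> Grid:
    """Read a grid written by :func:`write_raster`.

    If ``expect_spec`` is given, the stored spec must match it exactly.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        try:
            meta = json.loads(page.description)
            spec = GridSpec(meta["n_rows"], meta["n_cols"], meta["cell_size"],
                            meta["origin_x"], meta["origin_y"],
                            meta["crs_label"])
        except (json.JSONDecodeError, TypeError, KeyError) as exc:
            raise ValueError(f"{path}: missing or invalid grid metadata") from exc
    nodata = meta["nodata"]
    if nodata == "nan":
        nodata = float("nan")
    if expect_spec is not None and spec != expect_spec:
        raise ValueError(
            f"{path}: grid spec {spec} does not match the run's reference "
            f"spec {expect_spec}")
    if meta["kind"] == "categorical":
        values = data.astype(np.int64)
    else:
        values = data.astype(np.float64)
    return Grid(spec, values, nodata=nodata, kind=meta["kind"])


def write_features(features: Iterable[MineFeature], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {
                    "feature_class": f.feature_class,
                    "mineral": f.mineral,
                    "method": f.method,
                },
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_features(path: str | Path) -> list[MineFeature]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        try:
            out.append(MineFeature(
                geometry=shape(feat["geometry"]),
                feature_class=props.get("feature_class"),
                mineral=props.get("mineral", "non_metal"),
                method=props.get("method", "open_pit"),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return out


def write_generic_geojson(geoms, path: str | Path) -> None:
    """Write untagged geometries (rivers, lakes, protection areas)."""
    fc = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "geometry": mapping(g),
                        "properties": {}} for g in geoms]}
    Path(path).write_text(json.dumps(fc))


def read_generic_geojson(path: str | Path):
    fc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in fc["features"]]


def write_stations(stations: Iterable[StationSeries], path: str | Path) -> None:
    rows = []
    for s in stations:
        for i, m in enumerate(s.months):
            rows.append([s.station_id, s.x, s.y, m, s.rainfall[i],
                         s.temperature[i], s.solar_radiation[i], s.aqi[i],
                         s.wind_speed[i]])
    pd.DataFrame(rows, columns=STATION_COLUMNS).to_csv(path, index=False)


def read_stations(path: str | Path) -> list[StationSeries]:
    df = pd.read_csv(path)
    missing_cols = set(STATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    out = []
    for sid, sub in df.groupby("station_id", sort=True):
        months = sorted(sub["month"].tolist())
        if months != list(range(1, 13)):
            raise ValueError(
                f"{path}: station {sid!r} does not have exactly the 12 "
                f"calendar months (got {months})")
        sub = sub.sort_values("month")
        out.append(StationSeries(
            station_id=str(sid),
            x=float(sub["x"].iloc[0]), y=float(sub["y"].iloc[0]),
            months=sub["month"].tolist(),
            rainfall=sub["rainfall"].tolist(),
            temperature=sub["temperature"].tolist(),
            solar_radiation=sub["solar_radiation"].tolist(),
            aqi=sub["aqi"].tolist(),
            wind_speed=sub["wind_speed"].tolist(),
        ))
    return out
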