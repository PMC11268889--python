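"""Readers and writers for the pipeline's file formats.

Accelerometer and GPS data travel as plain CSV (AXY-Trek-style export:
one timestamp column plus the data columns), the habitat map as GeoJSON
with a ``perch_type`` feature property, and the ground-truth schedule as
CSV. Timestamps are epoch seconds internally; ISO-8601 is accepted on
input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .containers import (
    ACC_RATE,
    G0,
    AccelerometerTrace,
    GpsTrack,
    GroundTruthSchedule,
    HabitatFeature,
    HabitatMap,
)


def _parse_time(col: pd.Series) -> np.ndarray:
    """Epoch-seconds or ISO-8601 timestamps -> float seconds."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, format="ISO8601")
    return (parsed - parsed.iloc[0]).dt.total_seconds().to_numpy()


def read_acceleration_csv(path: str | Path, units: str = "g") -> AccelerometerTrace:
    """Load a tri-axial 50 Hz trace; ``units`` is 'g' or 'ms2'."""
    if units not in ("g", "ms2"):
        raise ValueError("units must be 'g' or 'ms2'")
    df = pd.read_csv(path)
    required = {"timestamp", "heave", "surge", "sway"}
    if set(df.columns) != required:
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {sorted(df.columns)}"
        )
    t = _parse_time(df["timestamp"])
    if len(t) > 1:
        dt = np.diff(t)
        if (dt <= 0).any():
            raise ValueError(f"{path}: non-monotone or duplicated timestamps")
        if not np.allclose(dt, 1.0 / ACC_RATE, atol=1e-6):
            raise ValueError(f"{path}: sampling is not uniform 50 Hz")
    scale = 1.0 / G0 if units == "ms2" else 1.0
    return AccelerometerTrace(
        t=t - t[0] if len(t) else t,
        heave=df["heave"].to_numpy(dtype=float) * scale,
        surge=df["surge"].to_numpy(dtype=float) * scale,
        sway=df["sway"].to_numpy(dtype=float) * scale,
    )


def write_acceleration_csv(trace: AccelerometerTrace, path: str | Path) -> None:
    df = trace.to_frame().rename(columns={"t": "timestamp"})
    df.to_csv(path, index=False)


def read_gps_csv(path: str | Path) -> GpsTrack:
    df = pd.read_csv(path)
    if not {"timestamp", "x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns timestamp,x,y")
    t = _parse_time(df["timestamp"])
    return GpsTrack(t=t - t[0] if len(t) else t,
                    x=df["x"].to_numpy(dtype=float), y=df["y"].to_numpy(dtype=float))


def write_gps_csv(track: GpsTrack, path: str | Path) -> None:
    track.to_frame().rename(columns={"t": "timestamp"}).to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> GroundTruthSchedule:
    # keep the literal "n/a" outcome/perch_type markers out of pandas NA handling
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return GroundTruthSchedule.from_frame(df)


def write_schedule_csv(schedule: GroundTruthSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_habitat_geojson(path: str | Path) -> HabitatMap:
    data = json.loads(Path(path).read_text())
    features = [
        HabitatFeature(
            geometry=shape(f["geometry"]), perch_type=f["properties"]["perch_type"]
        )
        for f in data.get("features", [])
    ]
    return HabitatMap(features=features)


def write_habitat_geojson(habitat: HabitatMap, path: str | Path) -> None:
    data = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {"perch_type": f.perch_type},
            }
            for f in habitat.features
        ],
    }
    Path(path).write_text(json.dumps(data))


def equirectangular(lon: np.ndarray, lat: np.ndarray,
                    lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Declared local projection: lon/lat degrees -> planar metres.

    Adequate over a study-area-sized extent; the inverse is linear.
    """
    r = 6_371_000.0
    x = np.radians(np.asarray(lon) - lon0) * r * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * r
    return x, y
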