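"""Perch-type assignment from GPS and a vector habitat map.

Each perching event gets the type of the nearest habitat feature within a
2 m radius of its median GPS location. Poles and trees are point
features; buildings are polygons measured to their boundary. Ties between
equidistant features resolve pole > tree > building.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .containers import GpsTrack, HabitatMap

log = logging.getLogger(__name__)

_TIE_ORDER = {"pole": 0, "tree": 1, "building": 2}


def median_location(
    track: GpsTrack, t_start: float, t_end: float
) -> tuple[float, float] | None:
    """Coordinate-wise median of fixes in [t_start, t_end]; None if no fix."""
    mask = (track.t >= t_start) & (track.t <= t_end)
    if not mask.any():
        return None
    return float(np.median(track.x[mask])), float(np.median(track.y[mask]))


def assign_perch_type(
    location: tuple[float, float] | None, habitat: HabitatMap, radius: float = 2.0
) -> str:
    """Type of the nearest feature within ``radius`` metres, else 'unknown'."""
    if location is None or not len(habitat):
        return "unknown"
    p = Point(location)
    best: tuple[float, int, str] | None = None
    tied = False
    for feat in habitat.features:
        geom = feat.geometry
        d = (geom.boundary if geom.geom_type == "Polygon" else geom).distance(p)
        if d > radius:
            continue
        key = (d, _TIE_ORDER[feat.perch_type], feat.perch_type)
        if best is None or key < best:
            tied = best is not None and abs(d - best[0]) < 1e-9
            best = key
    if best is None:
        return "unknown"
    if tied:
        log.info("equidistant habitat features at %.2f m; tie broken as %s", best[0], best[2])
    return best[2]


def perched_intervals(landings: pd.DataFrame, timeline: pd.DataFrame) -> list[tuple[float, float]]:
    """(landing, next take-off) interval per perch landing."""
    labels = timeline["label"].values
    t = timeline["t"].values
    out = []
    for row in landings.itertuples():
        sec = int(row.sec)
        end = sec
        while end + 1 < len(labels) and labels[end + 1] not in ("takeoff", "travel"):
            end += 1
        out.append((float(t[sec]), float(t[end])))
    return out


def assign_perch_types(
    landings: pd.DataFrame,
    timeline: pd.DataFrame,
    track: GpsTrack,
    habitat: HabitatMap,
    radius: float = 2.0,
) -> pd.DataFrame:
    """Append ``perch_type`` to a landing table (strikes get 'n/a')."""
    landings = landings.copy()
    types = []
    intervals = perched_intervals(landings, timeline)
    for row, (t0, t1) in zip(landings.itertuples(), intervals):
        if row.subtype != "perch":
            types.append("n/a")
            continue
        loc = median_location(track, t0, t1)
        types.append(assign_perch_type(loc, habitat, radius))
    landings["perch_type"] = types
    return landings
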