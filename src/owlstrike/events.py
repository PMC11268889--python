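"""From labelled seconds to analysis units.

Turns the classifier's output into the quantities the force and success
analyses run on: landing forces in newtons, hunting attempts with
strategy and inferred outcome, pre-hunt perching context, pre-strike
flight speed, and foraging trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EventConfig
from .containers import G0, GpsTrack, OwlMetadata


def compute_landing_force(peak_g: float, body_mass: float) -> float:
    """Peak ground-reaction force in N: peak (g) x g0 x body mass (kg)."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return peak_g * G0 * body_mass


def bodyweight_multiple(force_n: float, body_mass: float) -> float:
    """Force as a dimensionless multiple of body weight."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return force_n / (body_mass * G0)


def categorize_strategy(
    preceding_flight_duration: float, config: EventConfig | None = None
) -> str:
    """sit-and-wait (<=1 s of flight), on-the-wing (>=5 s), else excluded."""
    if config is None:
        config = EventConfig()
    if preceding_flight_duration < 0:
        raise ValueError("flight duration cannot be negative")
    if preceding_flight_duration <= config.sitandwait_max_flight:
        return "sit_and_wait"
    if preceding_flight_duration >= config.onthewing_min_flight:
        return "on_the_wing"
    return "excluded"


def preceding_flight_duration(timeline: pd.DataFrame, landing_sec: int) -> float:
    """Seconds of contiguous flight (takeoff/travel) just before a landing."""
    labels = timeline["label"].values
    dur = 0
    s = landing_sec - 1
    while s >= 0 and labels[s] in ("takeoff", "travel"):
        dur += 1
        s -= 1
    return float(dur)


def flight_speed_before_strike(
    track: GpsTrack, strike_t: float, window: float = 20.0
) -> float | None:
    """Median per-second ground speed over (strike_t - window, strike_t)."""
    speeds = track.speeds()
    mask = (track.t > strike_t - window) & (track.t <= strike_t)
    if mask.sum() < 2:
        return None
    return float(np.median(speeds[mask][1:])) if mask.sum() > 2 else float(speeds[mask][-1])


def infer_outcomes(
    events: pd.DataFrame, nest_position: tuple[float, float], config: EventConfig | None = None
) -> pd.DataFrame:
    """Infer success for each strike from the subsequent event stream.

    A strike is successful iff the next *hunting-relevant* event is a
    self-feeding bout or a nest entry ("direct return"). Relevant events
    are: another strike, a feeding bout, a nest entry, and any perching
    landing made away from the nest. A perch landing within
    ``nest_radius`` of the nest does not break the chain — owls land on
    the nest box before slipping inside, so the arrival perch is part of
    the return, not a resumption of hunting.

    ``events`` needs columns: t, kind (strike|perch|feeding|nest_enter),
    x, y (NaN allowed). Returns per-strike rows with ``success`` and the
    time of the confirming event (NaN for failures).
    """
    if config is None:
        config = EventConfig()
    ev = events.sort_values("t").reset_index(drop=True)
    nx, ny = nest_position
    dist = np.hypot(ev["x"].values - nx, ev["y"].values - ny)
    at_nest = np.where(np.isfinite(dist), dist <= config.nest_radius, False)

    out = []
    for i, row in enumerate(ev.itertuples()):
        if row.kind != "strike":
            continue
        success = False
        confirm_t = float("nan")
        for j in range(i + 1, len(ev)):
            kind = ev.loc[j, "kind"]
            if kind in ("feeding", "nest_enter"):
                success = True
                confirm_t = float(ev.loc[j, "t"])
                break
            if kind == "strike":
                break
            if kind == "perch" and not at_nest[j]:
                break
            # perch at the nest: part of the return; keep scanning
        out.append({"t": float(row.t), "success": success, "confirm_t": confirm_t})
    return pd.DataFrame(out, columns=["t", "success", "confirm_t"])


def prehunt_context(
    strike_t: float,
    perch_events: pd.DataFrame,
    max_gap: float = 90.0,
) -> tuple[float | None, float | None]:
    """Force and gap of the most recent perching event before a strike.

    Returns (force_N, gap_s); force is None when the gap is >= max_gap
    or no perch precedes the strike. The gap itself is always returned
    when a prior perch exists.
    """
    prior = perch_events[perch_events["t"] < strike_t]
    if prior.empty:
        return None, None
    last = prior.iloc[-1]
    gap = float(strike_t - last["t"])
    if gap >= max_gap:
        return None, gap
    return float(last["force_N"]), gap


def time_to_next_hunt(perch_times: np.ndarray, strike_times: np.ndarray) -> np.ndarray:
    """Seconds from each perching event to the next strike (NaN if none)."""
    perch_times = np.asarray(perch_times, dtype=float)
    strike_times = np.sort(np.asarray(strike_times, dtype=float))
    idx = np.searchsorted(strike_times, perch_times, side="left")
    out = np.full(len(perch_times), np.nan)
    has = idx < len(strike_times)
    out[has] = strike_times[idx[has]] - perch_times[has]
    return out


def flag_loaded_with_prey(
    landings: pd.DataFrame, outcomes: pd.DataFrame
) -> np.ndarray:
    """Mark perch landings made while carrying prey back to the nest.

    A perch landing is flagged when it falls between a successful strike
    and the event that confirmed its success (nest entry or feeding end).
    Flagged events are excluded from all force analyses.
    """
    flags = np.zeros(len(landings), dtype=bool)
    t = landings["t"].values
    sub = landings["subtype"].values
    for row in outcomes.itertuples():
        if row.success and np.isfinite(row.confirm_t):
            flags |= (sub == "perch") & (t > row.t) & (t < row.confirm_t)
    return flags


def segment_trips(
    track: GpsTrack,
    nest_position: tuple[float, float],
    nest_radius: float = 30.0,
    attempts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Foraging trips: maximal intervals with distance(nest) > radius.

    Durations are reported in minutes. When ``attempts`` is given, the
    number of attempts, the sit-and-wait frequency and a provisioning
    flag are attached per trip.
    """
    d = np.hypot(track.x - nest_position[0], track.y - nest_position[1])
    away = d > nest_radius
    edges = np.diff(away.astype(int))
    starts = track.t[1:][edges == 1]
    ends = track.t[1:][edges == -1]
    if away[0]:
        starts = np.concatenate([[track.t[0]], starts])
    if away[-1]:
        ends = np.concatenate([ends, [track.t[-1]]])

    rows = []
    for t0, t1 in zip(starts, ends):
        row = {
            "t_start": float(t0),
            "t_end": float(t1),
            "duration_min": (t1 - t0) / 60.0,
            "n_attempts": 0,
            "sw_frequency": np.nan,
        }
        if attempts is not None and len(attempts):
            sel = attempts[(attempts["t"] >= t0) & (attempts["t"] <= t1)]
            row["n_attempts"] = int(len(sel))
            counted = sel[sel["strategy"] != "excluded"]
            if len(counted):
                row["sw_frequency"] = float((counted["strategy"] == "sit_and_wait").mean())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["t_start", "t_end", "duration_min", "n_attempts", "sw_frequency"]
    )


def build_landing_events(
    classification: dict,
    meta: OwlMetadata,
    config: EventConfig | None = None,
) -> pd.DataFrame:
    """Landing table with forces, locations and prey-load flags."""
    if config is None:
        config = EventConfig()
    landings = classification["landings"].copy()
    timeline = classification["timeline"]
    landings["owl_id"] = meta.owl_id
    landings["sex"] = meta.sex
    landings["body_mass"] = meta.body_mass
    landings["force_N"] = [
        compute_landing_force(p, meta.body_mass) for p in landings["peak_g"]
    ]
    landings["force_per_kg"] = landings["force_N"] / meta.body_mass
    landings["bw_multiple"] = [
        bodyweight_multiple(f, meta.body_mass) for f in landings["force_N"]
    ]
    secs = landings["sec"].values.astype(int)
    landings["x"] = timeline["gps_x"].values[secs]
    landings["y"] = timeline["gps_y"].values[secs]
    return landings


def build_events_stream(
    landings: pd.DataFrame, feeding: pd.DataFrame, nest_visits: pd.DataFrame
) -> pd.DataFrame:
    """Unified time-ordered event stream for outcome inference."""
    frames = []
    if len(landings):
        frames.append(
            pd.DataFrame(
                {
                    "t": landings["t"],
                    "kind": np.where(landings["subtype"] == "strike", "strike", "perch"),
                    "x": landings["x"],
                    "y": landings["y"],
                }
            )
        )
    if len(feeding):
        frames.append(
            pd.DataFrame(
                {"t": feeding["t_start"], "kind": "feeding", "x": np.nan, "y": np.nan}
            )
        )
    if len(nest_visits):
        frames.append(
            pd.DataFrame(
                {"t": nest_visits["t_enter"], "kind": "nest_enter", "x": np.nan, "y": np.nan}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["t", "kind", "x", "y"])
    return pd.concat(frames, ignore_index=True).sort_values("t").reset_index(drop=True)


def build_attempts(
    landings: pd.DataFrame,
    classification: dict,
    track: GpsTrack,
    meta: OwlMetadata,
    config: EventConfig | None = None,
) -> pd.DataFrame:
    """Hunting-attempt table: strategy, outcome, forces, speeds, context."""
    if config is None:
        config = EventConfig()
    timeline = classification["timeline"]
    stream = build_events_stream(
        landings, classification["feeding"], classification["nest_visits"]
    )
    outcomes = infer_outcomes(stream, meta.nest_position, config)

    strikes = landings[landings["subtype"] == "strike"]
    perches = landings[(landings["subtype"] == "perch")]
    rows = []
    for strike in strikes.itertuples():
        dur = preceding_flight_duration(timeline, int(strike.sec))
        strategy = categorize_strategy(dur, config)
        force_pre, gap = prehunt_context(strike.t, perches, config.prehunt_max_gap)
        match = outcomes[outcomes["t"] == strike.t]
        success = bool(match["success"].iloc[0]) if len(match) else False
        speed = None
        if strategy == "on_the_wing":
            speed = flight_speed_before_strike(track, strike.t, config.speed_window)
        rows.append(
            {
                "owl_id": meta.owl_id,
                "sex": meta.sex,
                "t": float(strike.t),
                "strategy": strategy,
                "success": success,
                "strike_force_N": float(strike.force_N),
                "preceding_flight_duration": dur,
                "flight_speed": np.nan if speed is None else speed,
                "prehunt_perch_force_N": np.nan if force_pre is None else force_pre,
                "prehunt_gap": np.nan if gap is None else gap,
            }
        )
    attempts = pd.DataFrame(
        rows,
        columns=[
            "owl_id", "sex", "t", "strategy", "success", "strike_force_N",
            "preceding_flight_duration", "flight_speed",
            "prehunt_perch_force_N", "prehunt_gap",
        ],
    )
    return attempts


def process_events(
    classification: dict,
    track: GpsTrack,
    meta: OwlMetadata,
    config: EventConfig | None = None,
) -> dict:
    """Landings (with prey-load flags), attempts, trips for one night."""
    if config is None:
        config = EventConfig()
    landings = build_landing_events(classification, meta, config)
    stream = build_events_stream(
        landings, classification["feeding"], classification["nest_visits"]
    )
    outcomes = infer_outcomes(stream, meta.nest_position, config)
    landings["loaded_with_prey"] = flag_loaded_with_prey(landings, outcomes)
    perch_mask = landings["subtype"] == "perch"
    ttn = time_to_next_hunt(
        landings.loc[perch_mask, "t"].values,
        landings.loc[landings["subtype"] == "strike", "t"].values,
    )
    landings["time_to_next_hunt"] = np.nan
    landings.loc[perch_mask, "time_to_next_hunt"] = ttn
    attempts = build_attempts(landings, classification, track, meta, config)
    trips = segment_trips(track, meta.nest_position, config.nest_radius, attempts)
    return {"landings": landings, "attempts": attempts, "trips": trips, "outcomes": outcomes}
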