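"""Boolean behavioural classification on 1 s summary features.

Rules (defaults in :class:`~owlstrike.config.RuleThresholds`):

* take-off — pitch drop of at least 10 deg (standing -> horizontal
  posture) together with a per-second max VeDBA above 1 g;
* travelling flight — smoothed VeDBA above 0.1 g and pitch below 30 deg;
* landing — pitch rise above 10 deg with a VeDBA spike above 1 g, and a
  flight segment being terminated;
* landing subtype — a landing is a hunting strike when both the pitch
  change exceeds 6 deg and the VeDBA jump exceeds 1.3 g, otherwise a
  perching event;
* self-feeding — a regular train of at least 3 VeDBA peaks each between
  0.2 and 0.9 g during stationary behaviour;
* nest visit — entry/exit pitch + VeDBA transients, gated by GPS being
  within ``nest_radius`` of the nest.

Labels partition time with precedence
landing > takeoff > travel > feeding/nest > stationary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import RuleThresholds
from .containers import ACC_RATE, GpsTrack
from .signals import DerivedSignals, summarize_per_second


def _group_events(cands: np.ndarray, score: np.ndarray, min_sep: float) -> np.ndarray:
    """Merge candidate seconds closer than ``min_sep`` into single events.

    Within a merged run the second with the highest ``score`` wins.
    """
    if cands.size == 0:
        return cands
    out = []
    prev = best = cands[0]
    for c in cands[1:]:
        if c - prev <= min_sep:
            if score[c] > score[best]:
                best = c
            prev = c
        else:
            out.append(best)
            prev = best = c
    out.append(best)
    return np.asarray(out)


def detect_takeoffs(features: pd.DataFrame, thresholds: RuleThresholds) -> np.ndarray:
    """Seconds (indices) where a take-off begins."""
    mask = (features["dpitch"] <= thresholds.takeoff_dpitch) & (
        features["vedba_max"] > thresholds.takeoff_vedba
    )
    cands = features.index.values[mask.values]
    return _group_events(cands, -features["dpitch"].values, thresholds.min_event_separation)


def detect_travel(features: pd.DataFrame, thresholds: RuleThresholds) -> np.ndarray:
    """Boolean per-second mask of travelling flight."""
    return (
        (features["vedba_smoothed_mean"] > thresholds.travel_vedba_smoothed)
        & (features["pitch_mean"] < thresholds.travel_pitch_max)
    ).values


def detect_landings(
    features: pd.DataFrame,
    thresholds: RuleThresholds,
    flight_mask: np.ndarray,
    derived: DerivedSignals | None = None,
) -> pd.DataFrame:
    """Landings: pitch-rise + VeDBA spike seconds terminating a flight.

    Returns one row per landing with the second index, the vectorial-sum
    peak in a +-0.5 s window around the within-second spike, and the
    Δpitch / ΔVeDBA values the subtype split uses.
    """
    prev_flight = np.concatenate([[False], flight_mask[:-1]])
    mask = (
        (features["dpitch"].values > thresholds.landing_dpitch)
        & (features["vedba_max"].values > thresholds.landing_vedba)
        & prev_flight
    )
    cands = features.index.values[mask]
    secs = _group_events(cands, features["vecsum_max"].values, thresholds.min_event_separation)
    rows = []
    for s in secs:
        peak = features.loc[s, "vecsum_max"]
        if derived is not None:
            t_peak = features.loc[s, "vecsum_argmax_t"]
            lo = np.searchsorted(derived.t, t_peak - 0.5)
            hi = np.searchsorted(derived.t, t_peak + 0.5)
            peak = float(np.max(derived.vecsum_raw[lo:hi]))
        rows.append(
            {
                "sec": int(s),
                "t": float(features.loc[s, "t"]),
                "peak_g": float(peak),
                "dpitch": float(features.loc[s, "dpitch"]),
                "dvedba": float(features.loc[s, "dvedba"]),
            }
        )
    return pd.DataFrame(rows, columns=["sec", "t", "peak_g", "dpitch", "dvedba"])


def classify_landing_type(dpitch: float, dvedba: float, thresholds: RuleThresholds) -> str:
    """'strike' iff both strike conditions hold, else 'perch'."""
    if dpitch > thresholds.strike_dpitch and dvedba > thresholds.strike_dvedba:
        return "strike"
    return "perch"


def detect_self_feeding(
    derived: DerivedSignals,
    stationary_sec: np.ndarray,
    thresholds: RuleThresholds,
    rate: float = ACC_RATE,
) -> pd.DataFrame:
    """Self-feeding bouts within stationary behaviour.

    A bout is a train of >= ``feed_min_peaks`` acceleration peaks in the
    surge and heave axes (the swallowing head-bob plane), each with VeDBA
    within (feed_peak_min, feed_peak_max), regular in the sense that the
    inter-peak interval coefficient of variation is <= 0.5. Peaks above
    the upper bound break a train. Restricting peak detection to the
    heave-surge dynamic norm keeps isotropic sensor noise (which spreads
    over all three axes) below the peak floor.
    """
    hs = np.sqrt(derived.dyn_heave**2 + derived.dyn_surge**2)
    idx, props = find_peaks(hs, height=thresholds.feed_peak_min, distance=int(0.5 * rate))
    if idx.size == 0:
        return pd.DataFrame(columns=["t_start", "t_end", "n_peaks"])
    del props
    secs = (idx // int(rate)).astype(int)
    ok_sec = np.zeros(len(secs), dtype=bool)
    in_range = secs < len(stationary_sec)
    ok_sec[in_range] = stationary_sec[secs[in_range]]

    bouts = []
    current: list[float] = []

    def _flush() -> None:
        if len(current) >= thresholds.feed_min_peaks:
            ivals = np.diff(current)
            cv = ivals.std() / ivals.mean() if ivals.mean() > 0 else np.inf
            if cv <= thresholds.feed_interval_cv_max:
                bouts.append(
                    {"t_start": current[0], "t_end": current[-1], "n_peaks": len(current)}
                )
        current.clear()

    for i, ok in zip(idx, ok_sec):
        t = float(derived.t[i])
        # min bound enforced by find_peaks height; max bound on full VeDBA
        if not ok or derived.vedba[i] >= thresholds.feed_peak_max:
            _flush()
            continue
        if current and t - current[-1] > thresholds.feed_max_gap:
            _flush()
        current.append(t)
    _flush()
    return pd.DataFrame(bouts, columns=["t_start", "t_end", "n_peaks"])


def detect_nest_visits(
    features: pd.DataFrame,
    track: GpsTrack | None,
    nest_position: tuple[float, float],
    thresholds: RuleThresholds,
    excluded_sec: np.ndarray | None = None,
) -> pd.DataFrame:
    """Nest-box visit intervals from enter/exit transients + a GPS gate.

    ``excluded_sec`` marks seconds already claimed by flight or landing
    labels; transients there are ignored. An enter without a matching
    exit yields an open interval (``t_exit`` = NaN, ``open`` = True).
    """
    dpitch = features["dpitch"].values
    dvedba = features["dvedba"].values
    enter = (dpitch < thresholds.nest_enter_dpitch) & (dvedba > thresholds.nest_enter_dvedba)
    exit_ = (dpitch < thresholds.nest_exit_dpitch) & (dvedba < thresholds.nest_exit_dvedba)
    if excluded_sec is not None:
        enter &= ~excluded_sec
        exit_ &= ~excluded_sec
    if track is not None:
        near = _near_nest_per_second(features, track, nest_position, thresholds.nest_radius)
        enter &= near
        exit_ &= near

    visits = []
    enter_secs = _group_events(
        features.index.values[enter], dvedba, thresholds.min_event_separation
    )
    exit_secs = _group_events(
        features.index.values[exit_], -dvedba, thresholds.min_event_separation
    )
    for s in enter_secs:
        later = exit_secs[exit_secs > s]
        if later.size:
            visits.append({"t_enter": float(s), "t_exit": float(later[0]), "open": False})
        else:
            visits.append({"t_enter": float(s), "t_exit": float("nan"), "open": True})
    return pd.DataFrame(visits, columns=["t_enter", "t_exit", "open"])


def _near_nest_per_second(
    features: pd.DataFrame, track: GpsTrack, nest_position: tuple[float, float], radius: float
) -> np.ndarray:
    """True where the nearest GPS fix (within 1 s) is inside the nest radius."""
    sec = features.index.values.astype(float)
    # track fixes are 1 Hz starting at the same origin as the trace
    fix = np.clip(np.round(sec).astype(int), 0, len(track) - 1)
    has_fix = np.abs(track.t[fix] - sec) <= 1.0
    d = np.hypot(track.x[fix] - nest_position[0], track.y[fix] - nest_position[1])
    return has_fix & (d <= radius)


def classify_night(
    derived: DerivedSignals,
    track: GpsTrack | None = None,
    nest_position: tuple[float, float] = (0.0, 0.0),
    thresholds: RuleThresholds | None = None,
) -> dict:
    """Full per-night classification.

    Returns a dict with:

    * ``timeline`` — per-second DataFrame (sec, t, label, gps_x, gps_y);
    * ``landings`` — landing events with subtype, peak and Δ features;
    * ``takeoffs`` — take-off seconds;
    * ``feeding`` — self-feeding bouts;
    * ``nest_visits`` — visit intervals;
    * ``features`` — the per-second summary table.
    """
    if thresholds is None:
        thresholds = RuleThresholds()
    features = summarize_per_second(derived)
    travel = detect_travel(features, thresholds)
    takeoffs = detect_takeoffs(features, thresholds)
    flight = travel.copy()
    flight[takeoffs] = True
    landings = detect_landings(features, thresholds, flight, derived)
    landings["subtype"] = [
        classify_landing_type(r.dpitch, r.dvedba, thresholds) for r in landings.itertuples()
    ]

    n_sec = len(features)
    labels = np.full(n_sec, "stationary", dtype=object)
    labels[travel] = "travel"
    labels[takeoffs] = "takeoff"
    landing_secs = landings["sec"].values.astype(int)
    labels[landing_secs] = "landing"

    claimed = (labels == "travel") | (labels == "takeoff") | (labels == "landing")
    stationary = ~claimed
    feeding = detect_self_feeding(derived, stationary, thresholds)
    nest_visits = detect_nest_visits(features, track, nest_position, thresholds, claimed)

    t0 = float(derived.t[0])
    for b in feeding.itertuples():
        lo = int(b.t_start - t0)
        hi = int(b.t_end - t0) + 1
        seg = slice(max(lo, 0), min(hi, n_sec))
        labels[seg] = np.where(claimed[seg], labels[seg], "feeding")
    for v in nest_visits.itertuples():
        lo = int(v.t_enter)
        hi = int(v.t_exit) + 1 if np.isfinite(v.t_exit) else lo + 1
        seg = slice(max(lo, 0), min(hi, n_sec))
        labels[seg] = np.where(claimed[seg], labels[seg], "nest_visit")

    timeline = pd.DataFrame({"sec": features["sec"], "t": features["t"], "label": labels})
    if track is not None:
        fix = np.clip(np.round(features.index.values.astype(float)).astype(int), 0, len(track) - 1)
        has_fix = np.abs(track.t[fix] - features.index.values) <= 1.0
        timeline["gps_x"] = np.where(has_fix, track.x[fix], np.nan)
        timeline["gps_y"] = np.where(has_fix, track.y[fix], np.nan)
    else:
        timeline["gps_x"] = np.nan
        timeline["gps_y"] = np.nan

    return {
        "timeline": timeline,
        "landings": landings,
        "takeoffs": takeoffs,
        "feeding": feeding,
        "nest_visits": nest_visits,
        "features": features,
    }
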