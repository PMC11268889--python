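"""Ground-truthed synthetic owl-nights.

The generator emulates the statistical structure the downstream pipeline
assumes: a night of foraging trips, each a sequence of hunting attempts
launched either on the wing (long search flight) or sit-and-wait (short
hops between perches, then a <=1 s pounce), with sex- and strategy-
dependent success probabilities, landing spikes whose vectorial-sum peak
is calibrated in body-weight multiples (defaults: strikes ~13, perch
landings ~3), self-feeding or nest-provisioning after successful strikes,
and a 1 Hz GPS track kinematically consistent with the flights.

Signal signatures (all in g, 50 Hz):

* travelling flight — sinusoidal heave wingbeat at ``wingbeat_freq`` with
  low pitch; take-off seconds carry a stronger flapping burst;
* landing — a posture step (flight -> standing pitch) plus a 0.1 s
  half-sine spike along the gravity direction whose vectorial-sum peak
  equals the injected peak exactly (before noise);
* self-feeding — a regular train of sub-gravity VeDBA bumps;
* nest visit — an entry burst with a small pitch dip, lateral (sway)
  activity inside the box, and an abrupt return to quiet on exit.

Every injected event is recorded in a :class:`GroundTruthSchedule` so the
classifier can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from shapely.geometry import Point, Polygon

from .config import SyntheticNightConfig
from .containers import (
    G0,
    AccelerometerTrace,
    GpsTrack,
    GroundTruthSchedule,
    HabitatFeature,
    HabitatMap,
    OwlMetadata,
    ScheduledEvent,
)

ACC_RATE = 50
_MIN_REST = 5  # s of stationary padding required around each trip

#: sex-specific body-mass distributions (kg): mean, sd
BODY_MASS = {"F": (0.322, 0.0226), "M": (0.281, 0.0165)}


class SynthesisError(RuntimeError):
    """The requested schedule cannot fit in the night."""


def generate_owl(owl_id: str, sex: str, rng: np.random.Generator,
                 nest_position: tuple[float, float] = (0.0, 0.0)) -> OwlMetadata:
    """Draw one individual's metadata from the sex-specific mass distribution."""
    mu, sd = BODY_MASS[sex]
    mass = float(np.clip(rng.normal(mu, sd), 0.5 * mu, 1.5 * mu))
    return OwlMetadata(owl_id=owl_id, sex=sex, body_mass=mass, nest_position=nest_position)


@dataclass
class _Seg:
    """One homogeneous stretch of the night, in whole seconds."""

    label: str  # stationary|takeoff|travel|landing_perch|landing_strike|feeding|nest_enter|nest_inside|nest_exit
    dur: int
    x0: float = 0.0
    y0: float = 0.0
    x1: float = 0.0
    y1: float = 0.0
    peak: float = float("nan")
    outcome: str = "n/a"
    perch_type: str = "n/a"
    loaded: bool = False
    strategy: str = ""
    feed_offsets: tuple = ()  # s within segment
    feed_amps: tuple = ()


class _TripBuilder:
    """Assembles one foraging trip as a list of segments (origin = nest)."""

    def __init__(self, cfg: SyntheticNightConfig, meta: OwlMetadata, rng: np.random.Generator):
        self.cfg = cfg
        self.meta = meta
        self.rng = rng
        self.speed = float(cfg.flight_speed_mean[meta.sex])
        self.pos = np.zeros(2)
        self.heading = rng.uniform(0.0, 2.0 * math.pi)
        self.segs: list[_Seg] = []

    # -- movement ---------------------------------------------------------
    def _move_seg(self, label: str, dur: int, target: np.ndarray) -> None:
        x0, y0 = self.pos
        self.pos = np.asarray(target, dtype=float)
        self.segs.append(_Seg(label, dur, x0, y0, self.pos[0], self.pos[1]))

    def flight(self, dur: int, to: np.ndarray | None = None) -> None:
        """Take-off second plus (dur-1) s of travel at cruise speed."""
        dur = max(1, int(dur))
        if to is None:
            self.heading += self.rng.uniform(-math.pi / 3, math.pi / 3)
            step = self.speed * np.array([math.cos(self.heading), math.sin(self.heading)])
            end = self.pos + step * dur
            if np.hypot(*end) < 50.0 and np.hypot(*self.pos) > 50.0:
                self.heading += math.pi  # bounce away from the nest mid-trip
                end = self.pos + self.speed * dur * np.array(
                    [math.cos(self.heading), math.sin(self.heading)]
                )
        else:
            end = np.asarray(to, dtype=float)
        airborne = bool(self.segs) and self.segs[-1].label in ("takeoff", "travel")
        if airborne:
            # already flying: a new leg is a heading change, not a take-off
            self._move_seg("travel", dur, end)
            return
        delta = (end - self.pos) / dur
        takeoff_end = self.pos + delta
        self._move_seg("takeoff", 1, takeoff_end)
        if dur > 1:
            self._move_seg("travel", dur - 1, end)

    def flight_home(self) -> None:
        dist = float(np.hypot(*self.pos))
        dur = max(2, int(round(dist / self.speed)))
        self.flight(dur, to=np.zeros(2))

    # -- stationary events ------------------------------------------------
    def _stat_seg(self, label: str, dur: int, **kw) -> _Seg:
        x, y = self.pos
        seg = _Seg(label, int(dur), x, y, x, y, **kw)
        self.segs.append(seg)
        return seg

    def stationary(self, dur: int) -> None:
        if dur > 0:
            self._stat_seg("stationary", dur)

    def landing(self, kind: str, peak: float, outcome: str = "n/a",
                perch_type: str = "n/a", loaded: bool = False, strategy: str = "") -> _Seg:
        return self._stat_seg(
            f"landing_{kind}", 1, peak=peak, outcome=outcome,
            perch_type=perch_type, loaded=loaded, strategy=strategy,
        )

    def feeding(self) -> None:
        rng, cfg = self.rng, self.cfg
        n_peaks = int(rng.integers(cfg.feed_bout_peaks[0], cfg.feed_bout_peaks[1] + 1))
        dt = float(rng.uniform(*cfg.feed_interval))
        offsets = tuple(1.0 + k * dt for k in range(n_peaks))
        # swallowing head-bobs act in the heave-surge plane
        amps = tuple(
            (a * math.cos(phi), a * math.sin(phi))
            for a, phi in zip(
                rng.uniform(0.35, 0.95, size=n_peaks),
                rng.uniform(0.2, 0.6, size=n_peaks),
            )
        )
        dur = int(math.ceil(offsets[-1])) + 2
        self._stat_seg("feeding", dur, feed_offsets=offsets, feed_amps=amps)

    def nest_visit(self) -> None:
        self._stat_seg("nest_enter", 1)
        self._stat_seg("nest_inside", int(self.rng.integers(8, 16)))
        self._stat_seg("nest_exit", 1)


def _draw_strategy(cfg: SyntheticNightConfig, rng: np.random.Generator) -> str:
    r = rng.random()
    if r < cfg.excluded_frac:
        return "excluded"
    if r < cfg.excluded_frac + (1.0 - cfg.excluded_frac) * cfg.p_sitandwait:
        return "sit_and_wait"
    return "on_the_wing"


def _draw_perch_type(cfg: SyntheticNightConfig, rng: np.random.Generator) -> str:
    return ("pole", "tree", "building")[int(rng.choice(3, p=np.asarray(cfg.perch_type_mix)))]


def _success_prob(cfg: SyntheticNightConfig, meta: OwlMetadata, strategy: str,
                  prehunt_force_n: float | None) -> float:
    """Strategy baseline, force-modulated for sit-and-wait hunts.

    The sit-and-wait success odds decrease by ``or_per_newton`` for every
    newton of pre-hunt perching force above the sex-expected perch force;
    on-the-wing success is force-independent.
    """
    key = "sit_and_wait" if strategy == "sit_and_wait" else "on_the_wing"
    p0 = float(cfg.success_prob[meta.sex][key])
    if strategy != "sit_and_wait" or prehunt_force_n is None:
        return p0
    ref = cfg.peak_bw("perch", meta.sex) * meta.body_mass * G0
    return float(expit(logit(p0) + math.log(cfg.or_per_newton) * (prehunt_force_n - ref)))


def _build_trip(cfg: SyntheticNightConfig, meta: OwlMetadata,
                rng: np.random.Generator) -> list[_Seg]:
    b = _TripBuilder(cfg, meta, rng)
    # commute out and land on an arrival perch: every attempt then starts
    # from the ground, so preceding-flight durations are unambiguous
    b.flight(int(cfg.trip_leg))
    peak = max(cfg.peak_bw("perch", meta.sex) + rng.normal(0.0, cfg.perch_peak_sd), 1.5)
    b.landing("perch", peak, perch_type=_draw_perch_type(cfg, rng))
    b.stationary(int(rng.integers(5, 21)))
    n_att = max(1, int(rng.poisson(cfg.strike_rate)))
    provisioned = False
    for _ in range(n_att):
        strategy = _draw_strategy(cfg, rng)
        prehunt_force_n = None
        if strategy == "sit_and_wait":
            n_hops = 1 + int(rng.random() < 0.4)
            peak = float("nan")
            for h in range(n_hops):
                b.flight(int(rng.integers(6, 11)))
                peak = cfg.peak_bw("perch", meta.sex) + rng.normal(0.0, cfg.perch_peak_sd)
                peak = max(peak, 1.5)
                b.landing("perch", peak, perch_type=_draw_perch_type(cfg, rng))
                b.stationary(int(round(rng.uniform(*cfg.perch_wait))))
            prehunt_force_n = peak * meta.body_mass * G0
            b.flight(1)  # the pounce: <=1 s of flight before the strike
        elif strategy == "on_the_wing":
            b.flight(int(rng.integers(int(cfg.search_flight[0]), int(cfg.search_flight[1]) + 1)))
        else:  # excluded: 2-4 s of flight
            b.flight(int(rng.integers(2, 5)))
        strike_peak = cfg.peak_bw("strike", meta.sex) + rng.normal(0.0, cfg.strike_peak_sd)
        p = _success_prob(cfg, meta, strategy, prehunt_force_n)
        success = bool(rng.random() < p)
        b.landing("strike", max(strike_peak, 2.0),
                  outcome="success" if success else "fail", strategy=strategy)
        if success and rng.random() < cfg.p_provision:
            # carry the prey straight back to the nest box
            b.stationary(3)
            b.flight_home()
            peak = (cfg.peak_bw("perch", meta.sex) + rng.normal(0.0, cfg.perch_peak_sd))
            b.landing("perch", max(peak, 1.5) * cfg.loaded_peak_factor,
                      perch_type="building", loaded=True)
            b.stationary(3)
            b.nest_visit()
            provisioned = True
            break
        if success:
            b.stationary(2)
            b.feeding()
            b.stationary(2)
        else:
            b.stationary(int(rng.integers(3, 9)))
    if not provisioned:
        b.flight_home()
        peak = cfg.peak_bw("perch", meta.sex) + rng.normal(0.0, cfg.perch_peak_sd)
        b.landing("perch", max(peak, 1.5), perch_type="building")
        b.stationary(3)
    return b.segs


# --------------------------------------------------------------------------
# rendering


_PITCH_BY_LABEL = {
    "takeoff": "flight",
    "travel": "flight",
    "nest_enter": "nest",
    "nest_inside": "nest",
    "nest_exit": "exit",  # ducking out through the box hole: brief pitch dip
}


def _render(segs: list[_Seg], cfg: SyntheticNightConfig, meta: OwlMetadata,
            rng: np.random.Generator):
    """Turn an absolute-time segment list into trace + track + schedule."""
    n_sec = sum(s.dur for s in segs)
    n = n_sec * ACC_RATE
    t = np.arange(n) / ACC_RATE

    pitch_levels = {
        "stand": cfg.pitch_stand,
        "flight": cfg.pitch_flight,
        "nest": cfg.pitch_nest,
        "exit": cfg.pitch_nest - cfg.pitch_exit_dip,
    }
    pitch_sec = np.full(n_sec, pitch_levels["stand"])
    wing_amp_sec = np.zeros(n_sec)
    sway_amp_sec = np.zeros(n_sec)
    x_sec = np.empty(n_sec)
    y_sec = np.empty(n_sec)

    spikes: list[tuple[int, float]] = []  # (start sample, amplitude in g above 1)
    bumps: list[tuple[int, float, float]] = []  # feeding bumps: (start, heave amp, surge amp)
    sway_bumps: list[tuple[int, float]] = []  # nest-entry bursts
    events: list[ScheduledEvent] = []
    landings: list[dict] = []

    sec = 0
    for seg in segs:
        sl = slice(sec, sec + seg.dur)
        pitch_sec[sl] = pitch_levels[_PITCH_BY_LABEL.get(seg.label, "stand")]
        frac = (np.arange(seg.dur) + 1.0) / seg.dur
        x_sec[sl] = seg.x0 + (seg.x1 - seg.x0) * frac
        y_sec[sl] = seg.y0 + (seg.y1 - seg.y0) * frac
        t0 = float(sec)
        if seg.label == "takeoff":
            wing_amp_sec[sl] = cfg.takeoff_amp
            events.append(ScheduledEvent(t0, t0 + 1, "takeoff"))
        elif seg.label == "travel":
            wing_amp_sec[sl] = cfg.wingbeat_amp
            events.append(ScheduledEvent(t0, t0 + seg.dur, "travel"))
        elif seg.label in ("landing_perch", "landing_strike"):
            spikes.append((sec * ACC_RATE + ACC_RATE // 10, seg.peak - 1.0))
            events.append(
                ScheduledEvent(t0, t0 + 1, seg.label, outcome=seg.outcome,
                               perch_type=seg.perch_type, injected_peak=seg.peak)
            )
            landings.append(
                {"t": t0, "label": seg.label, "injected_peak": seg.peak,
                 "perch_type": seg.perch_type, "outcome": seg.outcome,
                 "loaded": seg.loaded, "strategy": seg.strategy,
                 "x": seg.x1, "y": seg.y1}
            )
        elif seg.label == "feeding":
            for off, (ah, asu) in zip(seg.feed_offsets, seg.feed_amps):
                bumps.append((sec * ACC_RATE + int(off * ACC_RATE), float(ah), float(asu)))
            events.append(ScheduledEvent(t0, t0 + seg.dur, "feeding"))
        elif seg.label == "nest_enter":
            sway_bumps.append((sec * ACC_RATE + ACC_RATE // 5, 1.1))
            events.append(ScheduledEvent(t0, t0 + 1, "nest_enter"))
        elif seg.label == "nest_inside":
            sway_amp_sec[sl] = 1.3
            events.append(ScheduledEvent(t0, t0 + seg.dur, "stationary"))
        elif seg.label == "nest_exit":
            events.append(ScheduledEvent(t0, t0 + 1, "nest_exit"))
        else:  # stationary
            if events and events[-1].label == "stationary":
                prev = events.pop()
                events.append(replace(prev, t_end=t0 + seg.dur))
            else:
                events.append(ScheduledEvent(t0, t0 + seg.dur, "stationary"))
        sec += seg.dur

    # posture: per-second steps softened into 0.5 s ramps
    from .signals import moving_average

    pitch_samp = moving_average(np.repeat(pitch_sec, ACC_RATE), 0.5, ACC_RATE)
    sin_p = np.sin(np.radians(pitch_samp))
    cos_p = np.cos(np.radians(pitch_samp))

    heave = sin_p.copy()
    surge = cos_p.copy()
    sway = np.zeros(n)

    # wingbeat and nest activity from per-second amplitude envelopes
    wing = np.repeat(wing_amp_sec, ACC_RATE)
    if wing.any():
        heave += wing * np.sin(2.0 * math.pi * cfg.wingbeat_freq * t)
    sw_amp = np.repeat(sway_amp_sec, ACC_RATE)
    if sw_amp.any():
        sway += sw_amp * np.sin(2.0 * math.pi * 3.0 * t)

    # landing spikes: half-sine along the instantaneous gravity direction,
    # so the vectorial-sum peak equals the injected peak exactly (pre-noise)
    spike_len = max(3, int(round(cfg.spike_duration * ACC_RATE)))
    spike_kernel = np.sin(math.pi * (np.arange(spike_len) + 0.5) / spike_len)
    for start, amp in spikes:
        end = min(start + spike_len, n)
        k = spike_kernel[: end - start] * amp
        heave[start:end] += k * sin_p[start:end]
        surge[start:end] += k * cos_p[start:end]

    bump_len = ACC_RATE // 5  # 0.2 s
    bump_kernel = np.sin(math.pi * (np.arange(bump_len) + 0.5) / bump_len)
    for start, amp_h, amp_s in bumps:
        end = min(start + bump_len, n)
        heave[start:end] += bump_kernel[: end - start] * amp_h
        surge[start:end] += bump_kernel[: end - start] * amp_s
    for start, amp in sway_bumps:
        end = min(start + bump_len, n)
        sway[start:end] += bump_kernel[: end - start] * amp

    if cfg.noise_sd > 0:
        heave += rng.normal(0.0, cfg.noise_sd, n)
        surge += rng.normal(0.0, cfg.noise_sd, n)
        sway += rng.normal(0.0, cfg.noise_sd, n)

    nx, ny = meta.nest_position
    gx = x_sec + nx
    gy = y_sec + ny
    if cfg.gps_jitter_sd > 0:
        gx = gx + rng.normal(0.0, cfg.gps_jitter_sd, n_sec)
        gy = gy + rng.normal(0.0, cfg.gps_jitter_sd, n_sec)

    trace = AccelerometerTrace(t=t, heave=heave, surge=surge, sway=sway)
    track = GpsTrack(t=np.arange(n_sec, dtype=float), x=gx, y=gy)
    schedule = GroundTruthSchedule(events=events)
    landings_df = pd.DataFrame(
        landings, columns=["t", "label", "injected_peak", "perch_type",
                           "outcome", "loaded", "strategy", "x", "y"]
    )
    if len(landings_df):
        landings_df["x"] += nx
        landings_df["y"] += ny
    return trace, track, schedule, landings_df


@dataclass
class SyntheticNight:
    """Everything the generator knows about one owl-night."""

    trace: AccelerometerTrace
    track: GpsTrack
    schedule: GroundTruthSchedule
    landings: pd.DataFrame  # per-landing truth incl. position and loaded flag
    meta: OwlMetadata
    config: SyntheticNightConfig
    habitat: HabitatMap = field(default_factory=HabitatMap)


def simulate_night(config: SyntheticNightConfig, meta: OwlMetadata | None = None,
                   with_habitat: bool = True) -> SyntheticNight:
    """Generate one full synthetic night with ground truth.

    Raises :class:`SynthesisError` if the scheduled trips cannot fit in
    ``night_duration`` (no silent truncation).
    """
    rng = np.random.default_rng(config.seed)
    if meta is None:
        meta = generate_owl("owl-0", "F" if rng.random() < 0.5 else "M", rng)

    night = int(config.night_duration)
    trips = [_build_trip(config, meta, rng) for _ in range(int(config.n_trips))]
    active = sum(s.dur for trip in trips for s in trip)
    n_gaps = len(trips) + 1
    leftover = night - active
    if leftover < n_gaps * _MIN_REST:
        raise SynthesisError(
            f"scheduled trips need {active + n_gaps * _MIN_REST} s "
            f"but night_duration is {night} s"
        )
    rest = leftover // n_gaps
    segs: list[_Seg] = []
    for trip in trips:
        segs.append(_Seg("stationary", rest))
        segs.extend(trip)
    segs.append(_Seg("stationary", night - active - rest * len(trips)))

    trace, track, schedule, landings = _render(segs, config, meta, rng)
    habitat = HabitatMap()
    if with_habitat:
        perches = landings[landings["label"] == "landing_perch"] if len(landings) else None
        habitat = generate_habitat_map(config, perches, rng=rng)
    return SyntheticNight(trace=trace, track=track, schedule=schedule,
                          landings=landings, meta=meta, config=config, habitat=habitat)


def generate_night(config: SyntheticNightConfig, meta: OwlMetadata | None = None):
    """Convenience wrapper returning (trace, track, schedule) for one night."""
    night = simulate_night(config, meta, with_habitat=False)
    return night.trace, night.track, night.schedule


def generate_habitat_map(config: SyntheticNightConfig,
                         perches: pd.DataFrame | None = None,
                         rng: np.random.Generator | None = None,
                         n_decoys: int = 20) -> HabitatMap:
    """Habitat map with one typed feature at every true perch location.

    Poles and trees are points; buildings are 3 m squares centred on the
    perch point (so the perch is always within 2 m of the feature, by
    construction). Decoy features of the configured type mix are scattered
    at least 6 m from every perch.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    features: list[HabitatFeature] = []
    pts: list[tuple[float, float]] = []
    if perches is not None and len(perches):
        for row in perches.itertuples():
            features.append(_make_feature(row.x, row.y, row.perch_type))
            pts.append((row.x, row.y))
    span = 400.0
    for _ in range(n_decoys):
        for _attempt in range(50):
            x, y = rng.uniform(-span, span, size=2)
            if all((x - px) ** 2 + (y - py) ** 2 > 36.0 for px, py in pts):
                break
        ptype = _draw_perch_type(config, rng)
        features.append(_make_feature(x, y, ptype))
    return HabitatMap(features=features)


def _make_feature(x: float, y: float, ptype: str) -> HabitatFeature:
    if ptype == "building":
        h = 1.5
        geom = Polygon([(x - h, y - h), (x + h, y - h), (x + h, y + h), (x - h, y + h)])
    else:
        geom = Point(x, y)
    return HabitatFeature(geometry=geom, perch_type=ptype)


# --------------------------------------------------------------------------
# attempt-level simulator (no signal rendering)


def simulate_attempts(n: int, config: SyntheticNightConfig, meta: OwlMetadata,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw hunting attempts directly from the generative statistical model.

    Skips signal synthesis entirely: each row carries strategy, pre-hunt
    perching force (N), pre-hunt gap (s), strike force (N) and the binary
    outcome, drawn exactly as the night generator draws them. Used for
    estimator-recovery checks at sample sizes impractical for full signal
    rendering.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    strategies = np.array([_draw_strategy(config, rng) for _ in range(n)])
    perch_peak = np.maximum(
        config.peak_bw("perch", meta.sex) + rng.normal(0.0, config.perch_peak_sd, n), 1.5
    )
    prehunt_force = perch_peak * meta.body_mass * G0
    prehunt_gap = rng.uniform(10.0, 120.0, n)
    strike_peak = np.maximum(
        config.peak_bw("strike", meta.sex) + rng.normal(0.0, config.strike_peak_sd, n), 2.0
    )
    p = np.array(
        [
            _success_prob(config, meta, s, f if s == "sit_and_wait" else None)
            for s, f in zip(strategies, prehunt_force)
        ]
    )
    success = rng.random(n) < p
    speed = float(config.flight_speed_mean[meta.sex])
    flight_speed = np.where(
        strategies == "on_the_wing", speed + rng.normal(0.0, 0.3, n), np.nan
    )
    return pd.DataFrame(
        {
            "owl_id": meta.owl_id,
            "sex": meta.sex,
            "strategy": strategies,
            "success": success,
            "strike_force_N": strike_peak * meta.body_mass * G0,
            "prehunt_perch_force_N": prehunt_force,
            "prehunt_gap": prehunt_gap,
            "flight_speed": flight_speed,
        }
    )
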