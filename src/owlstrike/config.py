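"""Configuration blocks for every pipeline stage.

All thresholds of the Boolean classifier live in one place
(:class:`RuleThresholds`) so a different published rule table can be
swapped in without touching code. Configs round-trip losslessly through
dict/YAML/JSON; unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _from_dict(cls, data: dict):
    """Build a (possibly nested) dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise TypeError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        target = _NESTED.get((cls.__name__, key))
        if target is not None and isinstance(value, dict):
            value = _from_dict(target, value)
        kwargs[key] = value
        del ftype
    return cls(**kwargs)


def _to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            v = _to_dict(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


@dataclass
class RuleThresholds:
    """Thresholds of the Boolean behavioural classifier.

    Δ quantities are first differences between consecutive 1 s summary
    rows. ``takeoff_dpitch`` is a pitch DROP: a take-off requires
    Δpitch <= takeoff_dpitch (standing → horizontal posture).
    """

    takeoff_dpitch: float = -10.0  # deg; Δpitch <= this
    takeoff_vedba: float = 1.0  # g; per-second max VeDBA > this
    travel_vedba_smoothed: float = 0.1  # g; smoothed VeDBA > this
    travel_pitch_max: float = 30.0  # deg; pitch < this
    landing_dpitch: float = 10.0  # deg; Δpitch > this
    landing_vedba: float = 1.0  # g; per-second max VeDBA > this
    strike_dpitch: float = 6.0  # deg; Δpitch > this (on a detected landing)
    strike_dvedba: float = 1.3  # g; ΔVeDBA > this (on a detected landing)
    feed_peak_min: float = 0.2  # g
    feed_peak_max: float = 0.9  # g
    feed_min_peaks: int = 3
    feed_interval_cv_max: float = 0.5  # "regular" peak train
    feed_max_gap: float = 5.0  # s; peaks farther apart start a new bout
    nest_enter_dpitch: float = -1.5  # deg; Δpitch < this
    nest_enter_dvedba: float = 0.5  # g; ΔVeDBA > this
    nest_exit_dpitch: float = 0.5  # deg; Δpitch < this
    nest_exit_dvedba: float = -0.9  # g; ΔVeDBA < this
    min_event_separation: float = 1.0  # s
    nest_radius: float = 30.0  # m; GPS gate for nest visits / trips

    def __post_init__(self) -> None:
        if not self.feed_peak_min < self.feed_peak_max:
            raise ValueError("feed_peak_min must be < feed_peak_max")


@dataclass
class EventConfig:
    """Windows and bounds used when turning labels into analysis units."""

    sitandwait_max_flight: float = 1.0  # s; "flew for a maximum of 1 s"
    onthewing_min_flight: float = 5.0  # s; "flew for at least 5 s"
    speed_window: float = 20.0  # s; median ground speed pre-strike
    prehunt_max_gap: float = 90.0  # s; pre-hunt perch filter (lower tercile)
    nest_radius: float = 30.0  # m; trip segmentation + direct-return gate
    perch_radius: float = 2.0  # m; habitat search radius for perch typing


@dataclass
class SyntheticNightConfig:
    """Everything the synthetic-night generator needs.

    Signal amplitudes are calibrated so that default strikes peak near 13
    times body weight and perch landings near 3 (vectorial sum, gravity
    included), matching the force levels the classifier and the force
    analyses are built around. ``strike_peak_bw``/``perch_peak_bw`` accept
    either a float or a ``{"F": .., "M": ..}`` map.
    """

    seed: int = 0
    night_duration: float = 36000.0  # s (~10 h logging window)
    n_trips: int = 8
    strike_rate: float = 5.0  # hunting attempts per trip
    p_sitandwait: float = 0.2  # probability a strike is launched from a perch
    excluded_frac: float = 0.08  # strikes with 2-4 s preceding flight
    success_prob: dict = field(
        default_factory=lambda: {
            "F": {"sit_and_wait": 0.268, "on_the_wing": 0.191},
            "M": {"sit_and_wait": 0.345, "on_the_wing": 0.261},
        }
    )
    or_per_newton: float = 0.85  # sit-and-wait success odds ratio per +1 N pre-hunt force
    p_provision: float = 0.5  # successful strike ends in nest return (vs self-feeding)
    strike_peak_bw: object = 13.0  # body-weight multiples (vectorial-sum peak, g)
    perch_peak_bw: object = 3.0
    strike_peak_sd: float = 0.5  # g
    perch_peak_sd: float = 0.2  # g
    loaded_peak_factor: float = 1.08  # perch peak multiplier when carrying prey (~25 g prey / ~300 g owl)
    wingbeat_freq: float = 4.0  # Hz
    wingbeat_amp: float = 0.9  # g, dynamic heave amplitude in travelling flight
    takeoff_amp: float = 1.5  # g, flapping burst in the take-off second
    flight_speed_mean: dict = field(default_factory=lambda: {"F": 5.47, "M": 5.24})
    noise_sd: float = 0.05  # g per axis
    gps_jitter_sd: float = 1.0  # m, stationary GPS scatter
    perch_type_mix: tuple = (0.5, 0.3, 0.2)  # pole, tree, building
    pitch_stand: float = 64.0  # deg, perched/standing posture
    pitch_flight: float = 10.0  # deg, travelling posture
    pitch_nest: float = 55.0  # deg, inside the nest box
    pitch_exit_dip: float = 8.0  # deg dip as the owl ducks out through the hole
    spike_duration: float = 0.1  # s, landing half-sine
    feed_bout_peaks: tuple = (5, 15)  # peaks per self-feeding bout
    feed_interval: tuple = (1.0, 2.0)  # s between feeding peaks
    perch_wait: tuple = (10.0, 120.0)  # s on a perch before the next move
    search_flight: tuple = (21.0, 35.0)  # s of on-the-wing search flight
    trip_leg: float = 20.0  # s outbound/inbound commuting legs

    def __post_init__(self) -> None:
        probs = [self.p_sitandwait, self.excluded_frac, self.p_provision]
        for sex in ("F", "M"):
            probs += list(self.success_prob[sex].values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        mix = tuple(self.perch_type_mix)
        if len(mix) != 3 or any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("perch_type_mix must be a 3-simplex (pole, tree, building)")
        for sex in ("F", "M"):
            if not self.peak_bw("strike", sex) > self.peak_bw("perch", sex) > 1.0:
                raise ValueError("need strike_peak_bw > perch_peak_bw > 1")
        if self.night_duration <= 0:
            raise ValueError("night_duration must be positive")

    def peak_bw(self, kind: str, sex: str) -> float:
        """Target vectorial-sum peak (g) for a landing kind, resolving per-sex maps."""
        val = self.strike_peak_bw if kind == "strike" else self.perch_peak_bw
        if isinstance(val, dict):
            return float(val[sex])
        return float(val)


@dataclass
class StatsConfig:
    n_boot: int = 500
    trend_bandwidth: int = 9  # B-spline basis size per smooth
    trend_grid: int = 100
    glm_tol: float = 1e-8
    glm_max_iter: int = 100


@dataclass
class PipelineConfig:
    """Top-level configuration tying all stages together."""

    seed: int = 0
    acc_units: str = "g"  # "g" | "ms2" for acceleration input files
    synth: SyntheticNightConfig = field(default_factory=SyntheticNightConfig)
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    events: EventConfig = field(default_factory=EventConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.acc_units not in ("g", "ms2"):
            raise ValueError("acc_units must be 'g' or 'ms2'")

    def to_dict(self) -> dict:
        return _to_dict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def digest(self) -> str:
        """Stable hash of the full configuration, recorded in run outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# nested dataclass targets for _from_dict
_NESTED = {
    ("PipelineConfig", "synth"): SyntheticNightConfig,
    ("PipelineConfig", "thresholds"): RuleThresholds,
    ("PipelineConfig", "events"): EventConfig,
    ("PipelineConfig", "stats"): StatsConfig,
}
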