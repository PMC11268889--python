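"""Core in-memory containers shared across the pipeline.

Axis convention follows body-mounted accelerometry usage: *heave* is the
dorsoventral axis (up through the back; reads +1 g when the bird stands
upright), *surge* anteroposterior, *sway* lateral. All acceleration is in
units of standard gravity g; positions are planar metres in a local frame
centred on the study area (a declared equirectangular projection handles
real lon/lat input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: standard gravity, m s^-2 — used for every g <-> N conversion
G0 = 9.81

#: accelerometer sampling rate, Hz
ACC_RATE = 50.0

# labels the ground-truth schedule and the classifier share
EVENT_LABELS = (
    "takeoff",
    "travel",
    "landing_perch",
    "landing_strike",
    "feeding",
    "nest_enter",
    "nest_exit",
    "stationary",
)

PERCH_TYPES = ("pole", "tree", "building")


@dataclass(frozen=True)
class OwlMetadata:
    """Deployment metadata for one individual."""

    owl_id: str
    sex: str  # "F" | "M"
    body_mass: float  # kg
    nest_position: tuple[float, float] = (0.0, 0.0)  # local metres

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not self.body_mass > 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")


@dataclass
class AccelerometerTrace:
    """Uniform 50 Hz tri-axial acceleration, in g, for one deployment."""

    t: np.ndarray  # seconds, strictly increasing, constant 0.02 s step
    heave: np.ndarray
    surge: np.ndarray
    sway: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("heave", "surge", "sway"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"axis {name!r} length != time length")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / ACC_RATE, atol=1e-6):
                raise ValueError("trace is not uniformly sampled at 50 Hz")
        for name in ("heave", "surge", "sway"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def rate(self) -> float:
        return ACC_RATE

    @property
    def duration(self) -> float:
        return len(self.t) / ACC_RATE

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "heave": self.heave, "surge": self.surge, "sway": self.sway}
        )


@dataclass
class GpsTrack:
    """1 Hz planar track (metres in the local frame)."""

    t: np.ndarray  # seconds
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t/x/y length mismatch")
        if len(self.t) >= 2 and not np.allclose(np.diff(self.t), 1.0, atol=1e-6):
            raise ValueError("track is not sampled at 1 Hz")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y})

    def speeds(self) -> np.ndarray:
        """Per-fix ground speed (m/s) from consecutive fixes; first = 0."""
        if len(self.t) < 2:
            return np.zeros(len(self.t))
        d = np.hypot(np.diff(self.x), np.diff(self.y)) / np.diff(self.t)
        return np.concatenate([[0.0], d])


@dataclass(frozen=True)
class ScheduledEvent:
    """One injected event in a synthetic night (the generator's ground truth)."""

    t_start: float
    t_end: float
    label: str
    outcome: str = "n/a"  # success | fail | n/a
    perch_type: str = "n/a"  # pole | tree | building | n/a
    injected_peak: float = float("nan")  # g; vectorial-sum peak for landings

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.t_end >= self.t_start:
            raise ValueError("t_end < t_start")


@dataclass
class GroundTruthSchedule:
    """Ordered, non-overlapping event list for one synthetic owl-night."""

    events: list[ScheduledEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for ev in self.events:
            if ev.t_start < prev_end - 1e-9:
                raise ValueError("schedule events overlap")
            prev_end = ev.t_end
            if ev.label == "landing_strike" and ev.outcome not in ("success", "fail"):
                raise ValueError("strike without an outcome")
            if ev.label == "landing_perch" and ev.perch_type not in PERCH_TYPES:
                raise ValueError("perch landing without a perch_type")

    def __len__(self) -> int:
        return len(self.events)

    def select(self, *labels: str) -> list[ScheduledEvent]:
        return [e for e in self.events if e.label in labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_start": e.t_start,
                    "t_end": e.t_end,
                    "label": e.label,
                    "outcome": e.outcome,
                    "perch_type": e.perch_type,
                    "injected_peak": e.injected_peak,
                }
                for e in self.events
            ],
            columns=["t_start", "t_end", "label", "outcome", "perch_type", "injected_peak"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruthSchedule":
        events = [
            ScheduledEvent(
                t_start=float(r.t_start),
                t_end=float(r.t_end),
                label=str(r.label),
                outcome=str(r.outcome),
                perch_type=str(r.perch_type),
                injected_peak=float(r.injected_peak),
            )
            for r in df.itertuples()
        ]
        return cls(events=events)


@dataclass
class HabitatFeature:
    """A typed perchable feature: a point (pole, tree) or polygon (building)."""

    geometry: object  # shapely geometry
    perch_type: str

    def __post_init__(self) -> None:
        if self.perch_type not in PERCH_TYPES:
            raise ValueError(f"unknown perch_type {self.perch_type!r}")


@dataclass
class HabitatMap:
    features: list[HabitatFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)
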