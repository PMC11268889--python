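"""Per-sample signal derivation for behavioural classification.

The classifier consumes a handful of channels derived from the raw 50 Hz
tri-axial acceleration:

* the *static* (gravitational) component, estimated by a centred moving
  average over 0.5 s per axis, and the *dynamic* residual (raw − static);
* **VeDBA** — vectorial dynamic body acceleration, the Euclidean norm of
  the three dynamic components, plus a 0.5 s smoothed copy;
* body **pitch**, the arcsine of static heave (in g), smoothed over 1 s;
* the vectorial sum of the *raw* channels, whose event-window maximum is
  the landing-force peak.

Everything is then summarized in 1 s intervals; the Boolean rules operate
on those per-second rows and their first differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ACC_RATE, AccelerometerTrace


def moving_average(x: np.ndarray, window: float, rate: float = ACC_RATE) -> np.ndarray:
    """Centred moving mean over ``window`` seconds.

    The window is rounded to the nearest odd sample count so it can be
    centred; at the edges the window shrinks to the samples available
    (the mean is always over real samples, never padding).

    Parameters
    ----------
    x : array
        Input series.
    window : float
        Window length in seconds. ``window * rate`` must be >= 1.
    rate : float
        Sampling rate in Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    w = int(round(window * rate))
    if w < 1:
        raise ValueError(f"window of {window} s at {rate} Hz is under one sample")
    if w % 2 == 0:
        w += 1  # nearest odd, rounding up on ties
    if w == 1:
        return x.copy()
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


@dataclass
class DerivedSignals:
    """Per-sample derived channels, aligned with the input trace."""

    t: np.ndarray
    static_heave: np.ndarray
    static_surge: np.ndarray
    static_sway: np.ndarray
    dyn_heave: np.ndarray
    dyn_surge: np.ndarray
    dyn_sway: np.ndarray
    vedba: np.ndarray
    vedba_smoothed: np.ndarray
    pitch: np.ndarray  # degrees
    vecsum_raw: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "static_heave": self.static_heave,
                "static_surge": self.static_surge,
                "static_sway": self.static_sway,
                "dyn_heave": self.dyn_heave,
                "dyn_surge": self.dyn_surge,
                "dyn_sway": self.dyn_sway,
                "vedba": self.vedba,
                "vedba_smoothed": self.vedba_smoothed,
                "pitch": self.pitch,
                "vecsum_raw": self.vecsum_raw,
            }
        )


def compute_vedba(
    dyn_heave: np.ndarray, dyn_surge: np.ndarray, dyn_sway: np.ndarray
) -> np.ndarray:
    """Vectorial dynamic body acceleration: sqrt(dh² + ds² + dw²) per sample."""
    return np.sqrt(
        np.asarray(dyn_heave) ** 2
        + np.asarray(dyn_surge) ** 2
        + np.asarray(dyn_sway) ** 2
    )


def compute_pitch(
    static_heave: np.ndarray, rate: float = ACC_RATE, smooth_window: float = 1.0
) -> np.ndarray:
    """Body pitch in degrees: arcsin of static heave (g), smoothed over 1 s.

    The arcsine argument is clamped to [-1, 1] so noise pushing |static|
    above 1 g cannot produce NaNs.
    """
    clamped = np.clip(np.asarray(static_heave, dtype=float), -1.0, 1.0)
    pitch = np.degrees(np.arcsin(clamped))
    if smooth_window and len(pitch) > 0:
        pitch = moving_average(pitch, smooth_window, rate)
    return pitch


def vector_sum_raw(trace: AccelerometerTrace) -> np.ndarray:
    """Per-sample vectorial sum of the RAW channels (gravity included), g."""
    return np.sqrt(trace.heave**2 + trace.surge**2 + trace.sway**2)


def derive_signals(
    trace: AccelerometerTrace,
    static_window: float = 0.5,
    vedba_smooth_window: float = 0.5,
    pitch_smooth_window: float = 1.0,
) -> DerivedSignals:
    """Full static/dynamic decomposition and derived channels.

    ``raw = static + dynamic`` holds exactly (the dynamic component is
    defined as the residual), so the decomposition conserves the signal.
    """
    rate = trace.rate
    static = {
        ax: moving_average(getattr(trace, ax), static_window, rate)
        for ax in ("heave", "surge", "sway")
    }
    dyn = {ax: getattr(trace, ax) - static[ax] for ax in static}
    vedba = compute_vedba(dyn["heave"], dyn["surge"], dyn["sway"])
    return DerivedSignals(
        t=trace.t,
        static_heave=static["heave"],
        static_surge=static["surge"],
        static_sway=static["sway"],
        dyn_heave=dyn["heave"],
        dyn_surge=dyn["surge"],
        dyn_sway=dyn["sway"],
        vedba=vedba,
        vedba_smoothed=moving_average(vedba, vedba_smooth_window, rate),
        pitch=compute_pitch(static["heave"], rate, pitch_smooth_window),
        vecsum_raw=vector_sum_raw(trace),
    )


# alias emphasising the decomposition step by itself
def derive_static_dynamic(
    trace: AccelerometerTrace, static_window: float = 0.5
) -> DerivedSignals:
    return derive_signals(trace, static_window=static_window)


def summarize_per_second(derived: DerivedSignals, rate: float = ACC_RATE) -> pd.DataFrame:
    """One row per whole second of data.

    Columns: ``sec`` (0-based second index, interval [sec, sec+1)),
    ``pitch_mean``, ``vedba_max``, ``vedba_smoothed_mean``, ``vecsum_max``,
    ``vecsum_argmax_t`` (time of the within-second raw-vecsum peak), and
    first differences ``dpitch`` / ``dvedba`` against the previous second
    (0 for the first row).
    """
    n_sec = int(len(derived) // rate)
    if n_sec < 1:
        raise ValueError("need at least one full second of data")
    n = int(n_sec * rate)
    shape = (n_sec, int(rate))
    pitch = derived.pitch[:n].reshape(shape)
    vedba = derived.vedba[:n].reshape(shape)
    vedba_s = derived.vedba_smoothed[:n].reshape(shape)
    vecsum = derived.vecsum_raw[:n].reshape(shape)
    t = derived.t[:n].reshape(shape)

    argmax = np.argmax(vecsum, axis=1)
    rows = np.arange(n_sec)
    out = pd.DataFrame(
        {
            "sec": rows,
            "t": t[:, 0],
            "pitch_mean": pitch.mean(axis=1),
            "vedba_max": vedba.max(axis=1),
            "vedba_smoothed_mean": vedba_s.mean(axis=1),
            "vecsum_max": vecsum.max(axis=1),
            "vecsum_argmax_t": t[rows, argmax],
        }
    )
    out["dpitch"] = out["pitch_mean"].diff().fillna(0.0)
    out["dvedba"] = out["vedba_max"].diff().fillna(0.0)
    return out
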