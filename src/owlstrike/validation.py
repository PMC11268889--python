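"""Scoring detected events against a synthetic night's ground truth."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .containers import GroundTruthSchedule


def match_events(
    true_times: np.ndarray, detected_times: np.ndarray, tol: float = 1.0
) -> tuple[int, int, int]:
    """Greedy one-to-one matching within ``tol`` seconds.

    Returns (n_matched, n_missed, n_spurious).
    """
    true_times = np.sort(np.asarray(true_times, dtype=float))
    detected_times = np.sort(np.asarray(detected_times, dtype=float))
    used = np.zeros(len(detected_times), dtype=bool)
    matched = 0
    for t in true_times:
        diffs = np.abs(detected_times - t)
        diffs[used] = np.inf
        if diffs.size and diffs.min() <= tol:
            used[np.argmin(diffs)] = True
            matched += 1
    return matched, len(true_times) - matched, int((~used).sum())


def score_landings(
    schedule: GroundTruthSchedule, landings: pd.DataFrame, tol: float = 1.0
) -> dict:
    """Recall/precision for landings plus the perch/strike confusion rate."""
    true_all = [e.t_start for e in schedule.select("landing_perch", "landing_strike")]
    det_all = landings["t"].values if len(landings) else np.array([])
    m, miss, spur = match_events(np.array(true_all), det_all, tol)
    recall = m / max(len(true_all), 1)
    precision = m / max(len(det_all), 1)

    # subtype confusion among time-matched detections
    confused = 0
    matched = 0
    det_t = landings["t"].values if len(landings) else np.array([])
    det_sub = landings["subtype"].values if len(landings) else np.array([])
    for ev in schedule.select("landing_perch", "landing_strike"):
        if det_t.size == 0:
            break
        diffs = np.abs(det_t - ev.t_start)
        j = int(np.argmin(diffs))
        if diffs[j] <= tol:
            matched += 1
            want = "perch" if ev.label == "landing_perch" else "strike"
            if det_sub[j] != want:
                confused += 1
    return {
        "recall": recall,
        "precision": precision,
        "confusion_rate": confused / max(matched, 1),
        "n_true": len(true_all),
        "n_detected": int(len(det_all)),
    }


def score_takeoffs(schedule: GroundTruthSchedule, takeoff_secs: np.ndarray, tol: float = 1.0) -> dict:
    true_t = np.array([e.t_start for e in schedule.select("takeoff")])
    m, miss, spur = match_events(true_t, np.asarray(takeoff_secs, dtype=float), tol)
    return {"recall": m / max(len(true_t), 1), "n_true": len(true_t)}


def recovery_suite(
    n_nights: int = 10,
    seed: int = 0,
    night_duration: float = 4000.0,
    n_trips: int = 8,
    config=None,
) -> dict:
    """Run the full pipeline over many synthetic nights and pool results.

    Generates ``n_nights`` owl-nights (alternating sexes, per-night seeds
    derived from ``seed``), classifies each against its ground truth, and
    returns pooled detection scores plus the combined landing and attempt
    tables (with per-night ground-truth outcome agreement).

    ``night_duration``/``n_trips`` only set the per-night event yield;
    all signal-level parameters stay at the supplied (default) config.
    """
    from .config import SyntheticNightConfig
    from .pipeline import process_synthetic_night
    from .synth import generate_owl, simulate_night

    if config is None:
        config = SyntheticNightConfig()
    landings, attempts = [], []
    matched = confused = n_true = n_det = n_hit = 0
    agree = tot = 0
    for i in range(n_nights):
        night_seed = int(seed * 100003 + i) % (2**31)
        sex = "F" if i % 2 == 0 else "M"
        meta = generate_owl(
            f"owl-{i}", sex, np.random.default_rng(night_seed)
        )
        cfg = replace(
            config, seed=night_seed, night_duration=night_duration, n_trips=n_trips
        )
        night = simulate_night(cfg, meta)
        result = process_synthetic_night(night)
        s = result.scores
        n_true += s["n_true"]
        n_det += s["n_detected"]
        n_hit += round(s["recall"] * s["n_true"])
        matched += s["n_true"]
        confused += s["confusion_rate"] * s["n_true"]
        truth = night.landings[night.landings["label"] == "landing_strike"].set_index("t")
        det = result.attempts.set_index("t")
        common = truth.index.intersection(det.index)
        agree += int(
            ((truth.loc[common, "outcome"] == "success") == det.loc[common, "success"]).sum()
        )
        tot += len(common)
        landings.append(result.landings)
        attempts.append(result.attempts)
    return {
        "recall": n_hit / max(n_true, 1),
        "precision": n_hit / max(n_det, 1),
        "confusion_rate": confused / max(matched, 1),
        "outcome_agreement": agree / max(tot, 1),
        "n_true_landings": int(n_true),
        "landings": pd.concat(landings, ignore_index=True),
        "attempts": pd.concat(attempts, ignore_index=True),
    }
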