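"""Clone classification from reporter rise times.

The response threshold for each channel is calibrated from the t0 signal
of naive wells (mean + k·sd).  A clone's rise time in a channel is the
first time its total fluorescence starts a persistent run above that
threshold; presence/absence of a rise in each channel by the end of the
experiment classifies the clone as SPR, SPF, DP or DN.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CloneCall, CloneTrace, ResponseThreshold

log = logging.getLogger(__name__)

__all__ = [
    "compute_response_threshold", "compute_rise_time", "classify_clone",
    "summarize_rise_times", "division_vs_rise", "calls_frame",
]

MIN_CALIBRATION_WELLS = 10


def compute_response_threshold(t0_G: Sequence[float], t0_R: Sequence[float],
                               k: float = 3.0) -> ResponseThreshold:
    """Calibrate per-channel thresholds as mean + k·sd of naive t0 signals."""
    if k < 0:
        raise ValueError("k must be >= 0")
    t0_G = np.asarray(t0_G, dtype=float)
    t0_R = np.asarray(t0_R, dtype=float)
    if len(t0_G) < MIN_CALIBRATION_WELLS or len(t0_R) < MIN_CALIBRATION_WELLS:
        raise ValueError(
            f"threshold calibration needs >= {MIN_CALIBRATION_WELLS} t0 "
            f"measurements per channel (got {len(t0_G)}, {len(t0_R)})")
    mg, sg = float(t0_G.mean()), float(t0_G.std(ddof=1))
    mr, sr = float(t0_R.mean()), float(t0_R.std(ddof=1))
    return ResponseThreshold(threshold_G=mg + k * sg, threshold_R=mr + k * sr,
                             calibration_G=(mg, sg, k),
                             calibration_R=(mr, sr, k))


def compute_rise_time(trace: CloneTrace, threshold: ResponseThreshold,
                      channel: str, persistence_frames: int = 2) -> Optional[float]:
    """First time the channel starts >= persistence_frames frames above threshold.

    Returns None when no such run occurs by the final frame.
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    values = trace.channel(channel)
    if len(values) < persistence_frames:
        raise ValueError("trace shorter than the persistence requirement")
    above = values > threshold.channel(channel)
    if persistence_frames == 1:
        idx = np.flatnonzero(above)
    else:
        window = np.lib.stride_tricks.sliding_window_view(above, persistence_frames)
        idx = np.flatnonzero(window.all(axis=1))
    if idx.size == 0:
        return None
    return float(trace.times[idx[0]])


def classify_clone(trace: CloneTrace, threshold: ResponseThreshold,
                   persistence_frames: int = 2,
                   endpoint_frames: int = 5) -> CloneCall:
    """Classify one clone at the end of the experiment.

    Endpoint MFI per channel is the mean total fluorescence over the last
    ``endpoint_frames`` frames.
    """
    rise_G = compute_rise_time(trace, threshold, "G", persistence_frames)
    rise_R = compute_rise_time(trace, threshold, "R", persistence_frames)
    fate = {(True, True): "DP", (True, False): "SPR",
            (False, True): "SPF", (False, False): "DN"}[
        (rise_G is not None, rise_R is not None)]
    first_div = min(trace.division_times) if trace.division_times else None
    return CloneCall(
        well_id=trace.well_id, fate=fate,
        rise_time_G=rise_G, rise_time_R=rise_R,
        endpoint_MFI_G=float(trace.total_G[-endpoint_frames:].mean()),
        endpoint_MFI_R=float(trace.total_R[-endpoint_frames:].mean()),
        first_division_time=first_div, condition=trace.condition)


def calls_frame(calls: Sequence[CloneCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well_id": c.well_id, "condition": c.condition, "fate": c.fate,
        "rise_time_G": c.rise_time_G, "rise_time_R": c.rise_time_R,
        "endpoint_MFI_G": c.endpoint_MFI_G, "endpoint_MFI_R": c.endpoint_MFI_R,
        "first_division_time": c.first_division_time,
    } for c in calls])


def summarize_rise_times(groups: Mapping[str, Sequence[float]],
                         pairs: Optional[Sequence[tuple]] = None) -> dict:
    """Per-group rise-time statistics plus Welch t-tests between pairs.

    ``groups`` maps a label (e.g. "SPR/G") to its rise times in hours;
    entries that are None/NaN are dropped.  Groups with fewer than two
    defined values are excluded with a warning.
    """
    stats_out = {}
    clean = {}
    for name, values in groups.items():
        v = np.asarray([x for x in values if x is not None], dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 2:
            log.warning("group %s has < 2 defined rise times; excluded", name)
            continue
        clean[name] = v
        stats_out[name] = {
            "n": int(len(v)), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)), "sem": float(stats.sem(v)),
            "median": float(np.median(v)),
        }
    tests = []
    for a, b in (pairs or []):
        if a not in clean or b not in clean:
            continue
        t, p = stats.ttest_ind(clean[a], clean[b], equal_var=False)
        tests.append({"pair": [a, b], "t": float(t), "p": float(p)})
    return {"groups": stats_out, "tests": tests}


def division_vs_rise(calls: pd.DataFrame) -> dict:
    """Compare reporter rise times with the first-division annotation.

    For each channel, the fraction of clones (with both the rise and a
    division annotated) whose rise occurs strictly after the first
    division.  Also reports median first-division time per condition and
    a Welch t-test between the two conditions when both are present.
    Returns None values when no division annotations exist.
    """
    if "first_division_time" not in calls.columns or \
            calls["first_division_time"].dropna().empty:
        return {"fraction_rise_after_division": {"G": None, "R": None},
                "median_division": {}, "division_test": None}
    out = {"fraction_rise_after_division": {}, "median_division": {}}
    for ch in ("G", "R"):
        sub = calls.dropna(subset=[f"rise_time_{ch}", "first_division_time"])
        if sub.empty:
            out["fraction_rise_after_division"][ch] = None
            continue
        frac = float((sub[f"rise_time_{ch}"] > sub["first_division_time"]).mean())
        out["fraction_rise_after_division"][ch] = frac
    by_cond = {}
    for cond, grp in calls.dropna(subset=["first_division_time"]).groupby("condition"):
        by_cond[cond] = grp["first_division_time"].to_numpy(dtype=float)
        out["median_division"][cond] = float(np.median(by_cond[cond]))
    out["division_test"] = None
    conds = sorted(by_cond)
    if len(conds) == 2:
        t, p = stats.ttest_ind(by_cond[conds[0]], by_cond[conds[1]],
                               equal_var=False)
        out["division_test"] = {"pair": conds, "t": float(t), "p": float(p)}
    return out
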