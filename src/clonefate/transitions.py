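"""State-transition frequencies from dye-labeled co-culture flow data.

After sorting and re-culturing, events are quadrant-gated on the two
reporter channels and attributed to their origin population via the
proliferation-stable dye label; the fraction of origin-o events found in
destination state d is the o→d transition frequency.  A chi-square
homogeneity test compares a transition frequency across co-culture
mixture ratios.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ResponseThreshold

__all__ = ["gate_events", "transition_frequencies", "compare_across_ratios"]

LOW_CONFIDENCE_N = 20


def gate_events(table: pd.DataFrame, thresholds: ResponseThreshold) -> pd.Series:
    """Quadrant-gate each event into SPR / SPF / DP / DN."""
    g = table["G_intensity"].to_numpy(dtype=float)
    r = table["R_intensity"].to_numpy(dtype=float)
    if np.any(g < 0) or np.any(r < 0):
        raise ValueError("event intensities must be >= 0")
    g_pos = g > thresholds.threshold_G
    r_pos = r > thresholds.threshold_R
    fate = np.where(g_pos & r_pos, "DP",
                    np.where(g_pos, "SPR", np.where(r_pos, "SPF", "DN")))
    return pd.Series(fate, index=table.index, name="gate")


def transition_frequencies(table: pd.DataFrame,
                           gates: Optional[pd.Series] = None,
                           thresholds: Optional[ResponseThreshold] = None,
                           origin_col: str = "origin") -> pd.DataFrame:
    """Per (origin, condition, ratio): frequency of each destination gate.

    Frequency = fraction of origin-o events gated as destination d, with
    binomial standard error sqrt(p(1-p)/n).  Origin groups with fewer
    than 20 events are flagged low-confidence.
    """
    if origin_col not in table.columns:
        raise ValueError(f"event table has no origin column {origin_col!r}")
    if gates is None:
        if thresholds is None:
            raise ValueError("provide precomputed gates or thresholds")
        gates = gate_events(table, thresholds)
    df = table.assign(_gate=gates.to_numpy())
    rows = []
    group_cols = [origin_col, "condition", "mixture_ratio"]
    for (origin, cond, ratio), grp in df.groupby(group_cols, sort=True):
        n = len(grp)
        counts = grp["_gate"].value_counts()
        for dest in ("SPR", "SPF", "DP", "DN"):
            k = int(counts.get(dest, 0))
            p = k / n
            rows.append({
                "origin": origin, "condition": cond, "mixture_ratio": ratio,
                "destination": dest, "n_origin": n, "n_dest": k,
                "frequency": p, "se": float(np.sqrt(p * (1 - p) / n)),
                "low_confidence": n < LOW_CONFIDENCE_N,
            })
    return pd.DataFrame(rows)


def compare_across_ratios(frequencies: pd.DataFrame, origin: str,
                          destination: str,
                          condition: Optional[str] = None) -> dict:
    """Chi-square homogeneity of one transition frequency across ratios.

    Tests whether P(origin → destination) depends on the co-culture
    mixture ratio; reports the statistic, p-value and the maximum
    absolute frequency difference between ratio levels.
    """
    sub = frequencies[(frequencies["origin"] == origin) &
                      (frequencies["destination"] == destination)]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if sub["mixture_ratio"].nunique() < 2:
        raise ValueError("need >= 2 mixture ratios to compare")
    counts = np.array([[row["n_dest"], row["n_origin"] - row["n_dest"]]
                       for _, row in sub.iterrows()])
    freqs = sub["frequency"].to_numpy()
    max_diff = float(freqs.max() - freqs.min())
    if np.allclose(counts[:, 0], counts[0, 0]) and \
            np.allclose(counts[:, 1], counts[0, 1]):
        # identical tables: chi2 = 0 by definition
        return {"chi2": 0.0, "p": 1.0, "dof": len(freqs) - 1,
                "max_abs_difference": max_diff}
    chi2, p, dof, _ = stats.chi2_contingency(counts)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof),
            "max_abs_difference": max_diff}
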