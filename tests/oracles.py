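"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately use naive O(n·m) scans and explicit loops, written
separately from the library implementations they validate.
"""

from __future__ import annotations

import numpy as np


def brute_force_rise_time(times, values, threshold, persistence):
    """First frame time starting `persistence` consecutive frames above threshold."""
    values = list(values)
    for i in range(len(values) - persistence + 1):
        if all(values[i + j] > threshold for j in range(persistence)):
            return float(times[i])
    return None


def brute_force_peaks(smoothed, bin_centers, min_prominence_frac,
                      min_separation_deg):
    """Exhaustive local-maximum scan with prominence and separation rules.

    Rules: a peak is a sample strictly greater than both neighbours
    (boundary samples need only exceed their single neighbour); its
    prominence is height minus the higher of the two bases, where a base
    is the lowest sample walking away until a strictly higher sample,
    and a domain border traversed from a boundary peak contributes no
    base; peaks below min_prominence_frac * max(smoothed) are dropped;
    remaining peaks are pruned highest-first (ties: lower angle),
    removing any candidate within min_separation_deg of a kept peak.
    """
    y = [float(v) for v in smoothed]
    n = len(y)
    if n < 3 or max(y) <= 0:
        return []
    candidates = []
    for i in range(n):
        left_ok = i == 0 or y[i] > y[i - 1]
        right_ok = i == n - 1 or y[i] > y[i + 1]
        if i == 0 and n > 1 and not (y[0] > y[1]):
            continue
        if i == n - 1 and n > 1 and not (y[-1] > y[-2]):
            continue
        if left_ok and right_ok:
            candidates.append(i)
    peaks = []
    for i in candidates:
        bases = []
        for direction in (-1, 1):
            j = i + direction
            seen = []
            while 0 <= j < n and y[j] <= y[i]:
                seen.append(y[j])
                j += direction
            if seen:
                bases.append(min(seen))
        prominence = y[i] - max(bases) if bases else y[i]
        peaks.append((i, prominence))
    min_prom = min_prominence_frac * max(y)
    peaks = [(i, p) for i, p in peaks if p >= min_prom]
    kept = []
    for i, p in sorted(peaks, key=lambda ip: (-y[ip[0]], ip[0])):
        if all(abs(bin_centers[i] - bin_centers[j]) >= min_separation_deg
               for j, _ in kept):
            kept.append((i, p))
    kept.sort()
    return [(float(bin_centers[i]), float(p)) for i, p in kept]


def welch_t(a, b):
    """Closed-form Welch t statistic (no scipy)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / np.sqrt(va + vb)
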