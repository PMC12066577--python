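"""Pixel-angle analysis of intra-clonal heterogeneity.

Each retained pixel is placed in the two-channel plane (x = Foxp3-RFP,
y = RORγt-GFP) and reduced to its angle: 0° for pure RFP, 90° for pure
GFP, ~45° for balanced co-expression.  Pooling angles over the last five
frames of a well, smoothing the histogram with a Gaussian kernel and
counting local maxima classifies the clone as homogeneous (0–1 peak) or
heterogeneous (>= 2 peaks).  Composing pixel sets from wells of different
fates provides artificial heterogeneous clones to validate the detector.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d


from .containers import AngleDistribution, PeakReport, WellPixelFrame

log = logging.getLogger(__name__)

__all__ = [
    "pixel_angles", "angle_distribution", "detect_peaks",
    "compose_artificial_heterogeneous", "evaluate_detector",
    "DEFAULT_BIN_WIDTH_DEG", "DEFAULT_SMOOTHING_SIGMA_DEG",
    "DEFAULT_MIN_PROMINENCE_FRAC", "DEFAULT_MIN_SEPARATION_DEG",
    "DEFAULT_INTENSITY_FLOOR",
]

DEFAULT_BIN_WIDTH_DEG = 3.0
DEFAULT_SMOOTHING_SIGMA_DEG = 6.0      # = 2 histogram bins
DEFAULT_MIN_PROMINENCE_FRAC = 0.05
DEFAULT_MIN_SEPARATION_DEG = 15.0
DEFAULT_INTENSITY_FLOOR = 4.0          # combined-channel units above background
N_LAST_FRAMES = 5


def pixel_angles(frame: WellPixelFrame, intensity_floor: float,
                 background: tuple = (0.0, 0.0)) -> np.ndarray:
    """Angles (degrees) of retained pixels in the (R, G) intensity plane.

    Intensities are background-subtracted and clipped at zero; pixels with
    combined intensity G + R below ``intensity_floor`` are discarded since
    their angles are noise-dominated.  R = 0 maps to 90°, G = 0 to 0°.
    """
    if intensity_floor < 0:
        raise ValueError("intensity_floor must be >= 0")
    bg_G, bg_R = background
    g = np.clip(frame.G - bg_G, 0, None)
    r = np.clip(frame.R - bg_R, 0, None)
    keep = (g + r) >= intensity_floor
    keep &= (g > 0) | (r > 0)          # (0, 0) has no angle
    return np.degrees(np.arctan2(g[keep], r[keep]))


def _bin_grid(bin_width_deg: float) -> tuple:
    """Bin centers on multiples of the width so 0°, 45°, 90° are centers."""
    n = int(round(90.0 / bin_width_deg))
    if abs(n * bin_width_deg - 90.0) > 1e-9:
        raise ValueError("bin_width_deg must divide 90")
    centers = np.arange(n + 1) * bin_width_deg
    edges = np.concatenate([centers - bin_width_deg / 2,
                            [centers[-1] + bin_width_deg / 2]])
    return centers, edges


def angle_distribution(frames: Sequence[WellPixelFrame],
                       bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG,
                       smoothing_sigma_deg: float = DEFAULT_SMOOTHING_SIGMA_DEG,
                       intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
                       background: tuple = (0.0, 0.0),
                       n_last_frames: int = N_LAST_FRAMES) -> AngleDistribution:
    """Pooled smoothed angle histogram over the last frames of a well.

    Exactly the final ``n_last_frames`` frames are pooled (an error is
    raised when fewer are supplied).  Smoothing uses a Gaussian kernel
    with mirror boundary handling, which reflects mass about the 0° and
    90° bin centers so boundary modes are preserved.  A well whose
    retained pixel set is empty yields a flagged empty distribution.
    """
    if len(frames) < n_last_frames:
        raise ValueError(
            f"need the final {n_last_frames} frames, got {len(frames)}")
    last = sorted(frames, key=lambda f: f.frame_index)[-n_last_frames:]
    angles = np.concatenate([
        pixel_angles(fr, intensity_floor, background) for fr in last])
    centers, edges = _bin_grid(bin_width_deg)
    counts, _ = np.histogram(angles, bins=edges)
    if angles.size == 0:
        return AngleDistribution(
            well_id=last[0].well_id, bin_centers=centers,
            counts=counts.astype(float), smoothed=np.zeros_like(centers, dtype=float),
            n_pixels=0, bin_width_deg=bin_width_deg, empty=True)
    density = counts / (counts.sum() * bin_width_deg)
    smoothed = gaussian_filter1d(density, sigma=smoothing_sigma_deg / bin_width_deg,
                                 mode="mirror")
    return AngleDistribution(
        well_id=last[0].well_id, bin_centers=centers,
        counts=counts.astype(float), smoothed=smoothed,
        n_pixels=int(angles.size), bin_width_deg=bin_width_deg)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Strict local maxima including the 0° / 90° boundary samples.

    The angle domain is bounded, so a mode sitting on a boundary (pure
    RFP at 0°, pure GFP at 90°) is a genuine peak when it exceeds its
    single inner neighbour.
    """
    interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
    idx = list(interior)
    if y[0] > y[1]:
        idx.insert(0, 0)
    if y[-1] > y[-2]:
        idx.append(y.size - 1)
    return np.asarray(idx, dtype=int)


def _prominence(y: np.ndarray, i: int) -> float:
    """Topographic prominence of sample i; array borders act as valleys."""
    peak = y[i]
    bases = []
    for step in (-1, 1):
        j = i + step
        lowest = None
        while 0 <= j < y.size and y[j] <= peak:
            lowest = y[j] if lowest is None else min(lowest, y[j])
            j += step
        # a side with no samples (peak on the domain boundary) sets no base
        bases.append(-np.inf if lowest is None else lowest)
    return float(peak - max(bases))


def detect_peaks(dist: AngleDistribution,
                 min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
                 min_separation_deg: float = DEFAULT_MIN_SEPARATION_DEG) -> PeakReport:
    """Local maxima of the smoothed density, with prominence and separation rules.

    A candidate peak (boundary bins included) must have topographic
    prominence >= ``min_prominence_frac`` times the density maximum;
    candidates closer than ``min_separation_deg`` are pruned greedily,
    keeping the higher peak (ties: the lower angle).
    """
    y = np.asarray(dist.smoothed, dtype=float)
    if dist.empty or y.size < 3 or y.max() <= 0:
        return PeakReport(well_id=dist.well_id, peak_angles=(),
                          peak_heights=(), peak_prominences=())
    candidates = _local_maxima(y)
    proms = {i: _prominence(y, i) for i in candidates}
    min_prom = min_prominence_frac * y.max()
    candidates = [i for i in candidates if proms[i] >= min_prom]
    # greedy separation pruning, highest peak first
    kept = []
    for i in sorted(candidates, key=lambda i: (-y[i], i)):
        angle = dist.bin_centers[i]
        if all(abs(angle - dist.bin_centers[j]) >= min_separation_deg
               for j in kept):
            kept.append(i)
    kept.sort()
    return PeakReport(well_id=dist.well_id,
                      peak_angles=tuple(float(dist.bin_centers[i]) for i in kept),
                      peak_heights=tuple(float(y[i]) for i in kept),
                      peak_prominences=tuple(proms[i] for i in kept))


def compose_artificial_heterogeneous(well_a: Sequence[WellPixelFrame],
                                     well_b: Sequence[WellPixelFrame],
                                     fate_a: Optional[str] = None,
                                     fate_b: Optional[str] = None) -> list:
    """Framewise union of two wells' pixel sets (hypothetical mixed clone).

    Used to validate the detector: combining wells of different fates
    should produce multi-peak angle distributions.  Combining same-fate
    wells is allowed but logged, as it is not a validation pair.
    """
    if len(well_a) != len(well_b):
        raise ValueError("wells must have matching frame counts")
    if fate_a is not None and fate_a == fate_b:
        log.warning("composing two %s wells: not a heterogeneity validation pair",
                    fate_a)
    out = []
    for fa, fb in zip(well_a, well_b):
        out.append(WellPixelFrame(
            well_id=f"{fa.well_id}+{fb.well_id}", frame_index=fa.frame_index,
            time_hr=fa.time_hr,
            G=np.concatenate([fa.G, fb.G]), R=np.concatenate([fa.R, fb.R])))
    return out


def evaluate_detector(homogeneous_wells: Sequence[Sequence[WellPixelFrame]],
                      artificial_wells: Sequence[Sequence[WellPixelFrame]],
                      **kwargs) -> tuple:
    """(false-positive rate, sensitivity) of the multi-peak detector.

    False-positive rate: fraction of true-homogeneous wells called >= 2
    peaks.  Sensitivity: fraction of composed heterogeneous wells called
    >= 2 peaks.  Keyword arguments are forwarded to angle_distribution /
    detect_peaks.
    """
    dist_kw = {k: kwargs[k] for k in
               ("bin_width_deg", "smoothing_sigma_deg", "intensity_floor",
                "background", "n_last_frames") if k in kwargs}
    peak_kw = {k: kwargs[k] for k in
               ("min_prominence_frac", "min_separation_deg") if k in kwargs}

    def frac_multipeak(wells):
        if not wells:
            return float("nan")
        n_multi = 0
        for frames in wells:
            report = detect_peaks(angle_distribution(frames, **dist_kw), **peak_kw)
            n_multi += report.n_peaks >= 2
        return n_multi / len(wells)

    return frac_multipeak(homogeneous_wells), frac_multipeak(artificial_wells)
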