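"""Shared data containers for the micro-well clone-fate pipeline.

Fates are the four quadrant states defined by the two reporter channels:
``SPR`` (single-positive RORγt), ``SPF`` (single-positive Foxp3),
``DP`` (double-positive) and ``DN`` (double-negative).  Channel ``G``
is the RORγt-GFP reporter, channel ``R`` the Foxp3-RFP reporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

FATES = ("SPR", "SPF", "DP", "DN")
CHANNELS = ("G", "R")


@dataclass(frozen=True)
class CloneTrace:
    """Per-well total-fluorescence time series for both reporter channels.

    ``total_G`` / ``total_R`` are background-subtracted per-frame sums of
    pixel intensity over the well, in arbitrary fluorescence units.
    """

    well_id: str
    times: np.ndarray            # hours, starting at 0, strictly increasing
    total_G: np.ndarray
    total_R: np.ndarray
    condition: str = "Th17"
    n_cells_t0: int = 1
    n_beads_t0: int = 1
    division_times: tuple = ()   # manual annotation, hours

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.total_G, dtype=float)
        r = np.asarray(self.total_R, dtype=float)
        if not (len(t) == len(g) == len(r)):
            raise ValueError("times, total_G and total_R must share a length")
        if len(t) and t[0] != 0:
            raise ValueError("trace times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "total_G", g)
        object.__setattr__(self, "total_R", r)

    def channel(self, name: str) -> np.ndarray:
        if name == "G":
            return self.total_G
        if name == "R":
            return self.total_R
        raise ValueError(f"unknown channel {name!r}; expected 'G' or 'R'")


@dataclass(frozen=True)
class WellPixelFrame:
    """Two-channel pixel intensity set for one well at one frame.

    The pixel set is abstract (no spatial layout): every downstream
    computation uses only the (G, R) intensity pairs.
    """

    well_id: str
    frame_index: int
    time_hr: float
    G: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.G, dtype=float)
        r = np.asarray(self.R, dtype=float)
        if g.shape != r.shape:
            raise ValueError("G and R pixel arrays must have the same shape")
        object.__setattr__(self, "G", g)
        object.__setattr__(self, "R", r)

    @property
    def n_pixels(self) -> int:
        return self.G.size


@dataclass(frozen=True)
class ResponseThreshold:
    """Per-channel response threshold calibrated from naive t0 signals.

    threshold_c = mean_c + k * sd_c over the t0 signal of naive wells.
    """

    threshold_G: float
    threshold_R: float
    calibration_G: tuple = ()    # (mean, sd, k)
    calibration_R: tuple = ()

    def __post_init__(self):
        if self.calibration_G:
            m, s, k = self.calibration_G
            if k < 0:
                raise ValueError("calibration k must be >= 0")
            if self.threshold_G < m - 1e-9:
                raise ValueError("threshold_G below calibration mean")
        if self.calibration_R:
            m, s, k = self.calibration_R
            if k < 0:
                raise ValueError("calibration k must be >= 0")
            if self.threshold_R < m - 1e-9:
                raise ValueError("threshold_R below calibration mean")

    def channel(self, name: str) -> float:
        if name == "G":
            return self.threshold_G
        if name == "R":
            return self.threshold_R
        raise ValueError(f"unknown channel {name!r}; expected 'G' or 'R'")


@dataclass(frozen=True)
class CloneCall:
    """End-of-experiment classification of one clone (micro-well)."""

    well_id: str
    fate: str
    rise_time_G: Optional[float]     # hours, None if never above threshold
    rise_time_R: Optional[float]
    endpoint_MFI_G: float
    endpoint_MFI_R: float
    first_division_time: Optional[float] = None
    condition: Optional[str] = None

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        expected = {
            (True, True): "DP", (True, False): "SPR",
            (False, True): "SPF", (False, False): "DN",
        }[(self.rise_time_G is not None, self.rise_time_R is not None)]
        if self.fate != expected:
            raise ValueError(
                f"fate {self.fate!r} inconsistent with rise times "
                f"(expected {expected!r})")


@dataclass(frozen=True)
class AngleDistribution:
    """Smoothed histogram of pixel angles pooled over the last frames.

    Angles live in [0°, 90°]: 0° is pure Foxp3-RFP, 90° pure RORγt-GFP.
    ``bin_centers`` sit on multiples of the bin width so that 0°, 45° and
    90° are representable peak locations.
    """

    well_id: str
    bin_centers: np.ndarray      # degrees
    counts: np.ndarray
    smoothed: np.ndarray         # Gaussian-filtered density
    n_pixels: int
    bin_width_deg: float
    empty: bool = False

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("histogram counts must be non-negative")


@dataclass(frozen=True)
class PeakReport:
    """Peak count of a well's angle distribution.

    ``n_peaks_capped`` follows the 0 / 1 / 2 reporting convention where
    "2" means two or more peaks.  Wells with at most one peak are called
    homogeneous; multi-peak wells heterogeneous.
    """

    well_id: str
    peak_angles: tuple
    peak_heights: tuple
    peak_prominences: tuple

    @property
    def n_peaks(self) -> int:
        return len(self.peak_angles)

    @property
    def n_peaks_capped(self) -> int:
        return min(self.n_peaks, 2)

    @property
    def classification(self) -> str:
        return "heterogeneous" if self.n_peaks >= 2 else "homogeneous"


@dataclass(frozen=True)
class MedianTrace:
    """Pointwise median ± std trace of a clone population."""

    population: str
    times: np.ndarray
    median_G: np.ndarray
    std_G: np.ndarray
    median_R: np.ndarray
    std_R: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        for name in ("median_G", "std_G", "median_R", "std_R"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} does not match the time grid")
        if np.any(np.asarray(self.std_G) < 0) or np.any(np.asarray(self.std_R) < 0):
            raise ValueError("stds must be non-negative")
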