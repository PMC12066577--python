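"""Well-level quantification: total-fluorescence traces and well filtering.

Converts per-frame pixel sets (from synthetic CSVs or TIFF stacks) into
per-well total-fluorescence traces, and applies the inclusion filter for
analyzable wells: exactly one cell and at least one activation bead at
seeding, with no reporter fluorescence at t0.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CloneTrace, ResponseThreshold, WellPixelFrame

log = logging.getLogger(__name__)

__all__ = [
    "extract_well_trace", "filter_wells", "estimate_pixel_background",
    "frames_from_pixels_csv", "frames_from_tiff",
]


def extract_well_trace(frames: Sequence[WellPixelFrame],
                       background_per_channel: tuple = (0.0, 0.0),
                       condition: str = "Th17",
                       n_cells_t0: int = 1, n_beads_t0: int = 1) -> CloneTrace:
    """Sum background-subtracted pixel intensity per frame and channel.

    ``total_c = sum(max(pixel_c - background_c, 0))`` — negative residuals
    are clipped because fluorescence is non-negative.  An empty frame
    contributes zero totals with a logged warning.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    bg_G, bg_R = background_per_channel
    if bg_G < 0 or bg_R < 0:
        raise ValueError("background estimates must be >= 0")
    order = np.argsort([f.time_hr for f in frames])
    frames = [frames[i] for i in order]
    times, tg, tr = [], [], []
    for fr in frames:
        times.append(fr.time_hr)
        if fr.n_pixels == 0:
            log.warning("well %s frame %d has no pixels; totals set to 0",
                        fr.well_id, fr.frame_index)
            tg.append(0.0)
            tr.append(0.0)
            continue
        tg.append(float(np.clip(fr.G - bg_G, 0, None).sum()))
        tr.append(float(np.clip(fr.R - bg_R, 0, None).sum()))
    return CloneTrace(well_id=frames[0].well_id, times=np.asarray(times),
                      total_G=np.asarray(tg), total_R=np.asarray(tr),
                      condition=condition, n_cells_t0=n_cells_t0,
                      n_beads_t0=n_beads_t0)


def filter_wells(metadata: pd.DataFrame,
                 t0_signals: Optional[pd.DataFrame] = None,
                 threshold: Optional[ResponseThreshold] = None) -> list:
    """Select analyzable wells.

    Keeps wells seeded with exactly 1 cell and >= 1 activation bead.  If
    ``t0_signals`` (columns well_id, t0_G, t0_R) and a calibrated threshold
    are given, wells already fluorescent in either channel at t0 are also
    excluded, so only complete differentiation histories enter the analysis.
    """
    for col in ("well_id", "n_cells_t0", "n_beads_t0"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    keep = (metadata["n_cells_t0"] == 1) & (metadata["n_beads_t0"] >= 1)
    ids = set(metadata.loc[keep, "well_id"])
    if t0_signals is not None:
        if threshold is None:
            raise ValueError("t0 exclusion requires a calibrated threshold")
        hot = (t0_signals["t0_G"] > threshold.threshold_G) | \
              (t0_signals["t0_R"] > threshold.threshold_R)
        ids -= set(t0_signals.loc[hot, "well_id"])
    return [w for w in metadata["well_id"] if w in ids]


def estimate_pixel_background(frame0: WellPixelFrame) -> dict:
    """Robust per-channel background (median, MAD-based sd) from the t0 frame.

    At seeding the well holds a single naive, non-fluorescent cell, so the
    t0 frame is background-dominated in both channels.
    """
    out = {}
    for ch, arr in (("G", frame0.G), ("R", frame0.R)):
        med = float(np.median(arr))
        sd = float(1.4826 * np.median(np.abs(arr - med)))
        out[ch] = (med, sd)
    return out


def frames_from_pixels_csv(pixels: pd.DataFrame) -> dict:
    """Group a tidy pixel table into per-well lists of WellPixelFrame."""
    required = {"well_id", "frame", "time_hr", "G", "R"}
    missing = required - set(pixels.columns)
    if missing:
        raise ValueError(f"pixel table is missing columns {sorted(missing)}")
    wells = {}
    for (well_id, frame_idx), grp in pixels.groupby(["well_id", "frame"], sort=True):
        wells.setdefault(well_id, []).append(WellPixelFrame(
            well_id=str(well_id), frame_index=int(frame_idx),
            time_hr=float(grp["time_hr"].iloc[0]),
            G=grp["G"].to_numpy(), R=grp["R"].to_numpy()))
    for frames in wells.values():
        frames.sort(key=lambda f: f.frame_index)
    return wells


def frames_from_tiff(path, times: Sequence[float],
                     roi: Optional[tuple] = None,
                     well_id: str = "well") -> list:
    """Read a (T, 2, H, W) two-channel TIFF stack into pixel frames.

    ``roi`` is an optional (row0, row1, col0, col1) bounding box from the
    well metadata; the full frame is used when absent.
    """
    import tifffile
    stack = tifffile.imread(path)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("expected a (T, 2, H, W) two-channel stack")
    if len(times) != stack.shape[0]:
        raise ValueError("times must match the number of stack frames")
    frames = []
    for i, ti in enumerate(times):
        g, r = stack[i, 0], stack[i, 1]
        if roi is not None:
            r0, r1, c0, c1 = roi
            g, r = g[r0:r1, c0:c1], r[r0:r1, c0:c1]
        frames.append(WellPixelFrame(well_id=well_id, frame_index=i,
                                     time_hr=float(ti),
                                     G=g.reshape(-1), R=r.reshape(-1)))
    return frames
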