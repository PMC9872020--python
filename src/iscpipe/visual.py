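"""Average luminance difference (ALD) of a video frame stack.

Per transition, ALD is the mean over pixels of the squared grayscale
(0-255) intensity change between consecutive frames; it is max-downsampled
onto the ISC window grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corrca import WindowGrid
from .layout import ClipLayout

logger = logging.getLogger(__name__)


@dataclass
class ALDSeries:
    per_frame: np.ndarray       # ALD at transition into frame t (index 0 = NaN)
    per_window: np.ndarray      # max within each retained window
    grid: WindowGrid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start": self.grid.starts,
            "block": self.grid.blocks,
            "ald": self.per_window,
        })


def to_grayscale(frames: np.ndarray, already_gray: bool = False) -> np.ndarray:
    """Unweighted RGB mean per pixel, on the 0-255 scale."""
    frames = np.asarray(frames, dtype=float)
    if already_gray:
        if frames.ndim not in (2, 3):
            raise ValueError("gray input must be (h, w) or (n, h, w)")
        return frames
    if frames.shape[-1] != 3:
        raise ValueError(f"expected 3 color channels, got shape {frames.shape}")
    return frames.mean(axis=-1)


def frame_ald(g1: np.ndarray, g2: np.ndarray) -> float:
    """Mean over pixels of the squared intensity difference."""
    g1, g2 = np.asarray(g1, dtype=float), np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError(f"frame shape mismatch: {g1.shape} vs {g2.shape}")
    return float(((g2 - g1) ** 2).mean())


def ald_per_frame(gray_stack: np.ndarray, fps: float,
                  layout: ClipLayout | None = None,
                  exclude_clip_boundaries: bool = True) -> np.ndarray:
    """ALD at every frame transition; index t is the (t-1, t) transition.

    Index 0 is NaN (no transition).  Transitions spanning a clip boundary
    are set to NaN when ``exclude_clip_boundaries`` — they encode cuts, not
    in-scene dynamics.
    """
    n = gray_stack.shape[0]
    out = np.full(n, np.nan)
    diffs = np.diff(gray_stack.astype(float), axis=0)
    out[1:] = (diffs ** 2).mean(axis=tuple(range(1, gray_stack.ndim)))
    if layout is not None and exclude_clip_boundaries:
        for _, s, _ in layout.clips:
            f = int(round(s * fps))
            if 0 < f < n:
                out[f] = np.nan
    return out


def downsample_ald(per_frame: np.ndarray, fps: float, grid: WindowGrid,
                   frame_mask: np.ndarray | None = None) -> ALDSeries:
    """Maximum per-frame ALD within each retained window; excised and NaN
    transitions are ignored.  An empty window yields NaN and is flagged.
    """
    n = len(per_frame)
    times = np.arange(n) / fps
    masked = (np.zeros(n, dtype=bool) if frame_mask is None
              else np.asarray(frame_mask, dtype=bool))
    per_window = np.full(grid.n_windows, np.nan)
    valid = ~masked & ~np.isnan(per_frame)
    for j, t0 in enumerate(grid.starts):
        inwin = (times >= t0) & (times < t0 + grid.window_len) & valid
        if not inwin.any():
            logger.warning("ALD window at %.3f s is empty", t0)
            continue
        per_window[j] = per_frame[inwin].max()
    return ALDSeries(per_frame=per_frame, per_window=per_window, grid=grid)
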