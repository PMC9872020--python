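"""Movement annotation from pose keypoints.

A frame transition counts as limb movement when the Euclidean displacement
of any joint of that limb set between consecutive frames lies strictly
above a lower threshold (camera jitter) and at or below an upper threshold
(scene cuts).  Window categories {neither, arm, leg, both} are assigned on
the same grid as the time-resolved ISC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrca import WindowGrid

logger = logging.getLogger(__name__)

ARM_JOINTS = ("l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_wrist", "r_wrist")
LEG_JOINTS = ("l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle")


def limb_of(joint: str) -> str | None:
    if joint in ARM_JOINTS:
        return "arm"
    if joint in LEG_JOINTS:
        return "leg"
    return None


@dataclass
class KeypointTrack:
    """Per-frame person entries with named joints as (x, y, confidence)."""

    fps: float
    frames: list[list[dict[str, tuple[float, float, float]]]]
    joint_names: list[str] = field(
        default_factory=lambda: ["nose", *ARM_JOINTS, *LEG_JOINTS]
    )

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class MovementSeries:
    """Per-frame limb indicators and per-window categories on the ISC grid."""

    arm: np.ndarray                 # bool per frame (transition into frame t)
    leg: np.ndarray
    categories: np.ndarray          # str per retained window
    grid: WindowGrid
    theta_low: float
    theta_high: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start": self.grid.starts,
            "block": self.grid.blocks,
            "movement": self.categories,
        })


def limb_displacement(track: KeypointTrack) -> pd.DataFrame:
    """Per-transition Euclidean displacement of every limb joint.

    Returns a long table with columns ``frame`` (index t of the later
    frame), ``person``, ``joint``, ``limb`` and ``dist``.  Joints missing
    (confidence 0) in either frame yield no row.  Persons are matched by
    detection index; a change in person count is logged.
    """
    if track.n_frames < 2:
        raise ValueError("need >= 2 frames")
    rows = []
    prev_count = len(track.frames[0])
    for t in range(1, track.n_frames):
        prev, cur = track.frames[t - 1], track.frames[t]
        if len(cur) != prev_count:
            logger.warning("person count changed at frame %d (%d -> %d)",
                           t, prev_count, len(cur))
            prev_count = len(cur)
        for p, (pp, cp) in enumerate(zip(prev, cur)):
            for joint in track.joint_names:
                limb = limb_of(joint)
                if limb is None:
                    continue
                if joint not in pp or joint not in cp:
                    continue
                x0, y0, c0 = pp[joint]
                x1, y1, c1 = cp[joint]
                if c0 == 0 or c1 == 0:
                    continue
                d = float(np.hypot(x1 - x0, y1 - y0))
                rows.append((t, p, joint, limb, d))
    return pd.DataFrame(rows, columns=["frame", "person", "joint", "limb", "dist"])


def classify_frames(dists: pd.DataFrame, theta_low: float, theta_high: float,
                    n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean arm(t), leg(t) per frame; index t marks the (t-1, t) transition.

    A limb is positive at t iff any of its joints (any person) moved by
    ``theta_low < d <= theta_high`` pixels.  Index 0 is always False.
    """
    if not (0 <= theta_low < theta_high):
        raise ValueError("need 0 <= theta_low < theta_high")
    arm = np.zeros(n_frames, dtype=bool)
    leg = np.zeros(n_frames, dtype=bool)
    hit = dists[(dists["dist"] > theta_low) & (dists["dist"] <= theta_high)]
    for limb, out in (("arm", arm), ("leg", leg)):
        idx = hit.loc[hit["limb"] == limb, "frame"].unique()
        out[idx[idx < n_frames]] = True
    return arm, leg


def window_categories(
    arm: np.ndarray, leg: np.ndarray, fps: float, grid: WindowGrid,
    frame_mask: np.ndarray | None = None, rule_fraction: float = 0.25,
    theta_low: float = 0.0, theta_high: float = np.inf,
) -> MovementSeries:
    """Assign one category per retained window.

    A window is positive for a limb when at least ``rule_fraction`` of its
    retained frame transitions are positive; ``both`` requires both limbs.
    Frames inside excised spans (``frame_mask`` True) are ignored; a window
    with no retained frames is labeled ``neither`` and flagged.
    """
    n_frames = len(arm)
    times = np.arange(n_frames) / fps
    masked = (np.zeros(n_frames, dtype=bool) if frame_mask is None
              else np.asarray(frame_mask, dtype=bool))
    cats = np.empty(grid.n_windows, dtype=object)
    for j, t0 in enumerate(grid.starts):
        inwin = (times >= t0) & (times < t0 + grid.window_len) & ~masked
        inwin[0] = False  # index 0 carries no transition
        n_ret = int(inwin.sum())
        if n_ret == 0:
            logger.warning("window at %.3f s has no retained frames", t0)
            cats[j] = "neither"
            continue
        a = arm[inwin].mean() >= rule_fraction
        l = leg[inwin].mean() >= rule_fraction
        cats[j] = "both" if (a and l) else "arm" if a else "leg" if l else "neither"
    return MovementSeries(arm=arm, leg=leg, categories=cats.astype(str), grid=grid,
                          theta_low=theta_low, theta_high=theta_high)


def annotate(track: KeypointTrack, grid: WindowGrid, theta_low: float,
             theta_high: float, frame_mask: np.ndarray | None = None,
             rule_fraction: float = 0.25) -> MovementSeries:
    """Full path: displacements -> dual-threshold frame labels -> window labels."""
    dists = limb_displacement(track)
    arm, leg = classify_frames(dists, theta_low, theta_high, track.n_frames)
    return window_categories(arm, leg, track.fps, grid, frame_mask, rule_fraction,
                             theta_low, theta_high)


def displacement_histogram(dists: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Tuning report: displacement histogram to guide threshold choice."""
    counts, edges = np.histogram(dists["dist"], bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
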