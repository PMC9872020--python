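"""Clip/block layout of the stimulus and onset-excision masks.

All timestamps are seconds from the start of the concatenated recording,
half-open intervals ``[start, end)``.  Sample index 0 is the first EEG
sample; frame index 0 is the first video frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClipLayout:
    """Block/clip boundaries of the stimulus.

    Parameters
    ----------
    blocks
        List of ``(block_id, clips)`` where ``clips`` is a list of
        ``(start, end)`` times in seconds on the global (concatenated)
        time base.  Clips within a block must be contiguous, ordered and
        non-overlapping.
    """

    blocks: list[tuple[str, list[tuple[float, float]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for block_id, clips in self.blocks:
            for (s0, e0), (s1, e1) in zip(clips, clips[1:]):
                if not (s0 < e0 <= s1 < e1):
                    raise ValueError(
                        f"block {block_id!r}: clips must be ordered, "
                        f"non-overlapping and contiguous; got ({s0},{e0}), ({s1},{e1})"
                    )
            for s, e in clips:
                if e <= s:
                    raise ValueError(f"block {block_id!r}: empty clip ({s},{e})")

    @classmethod
    def from_clip_lengths(
        cls, clip_lengths: list[float], n_blocks: int = 1, block_prefix: str = "block"
    ) -> "ClipLayout":
        """Build a layout by tiling ``clip_lengths`` across ``n_blocks`` blocks."""
        blocks = []
        t = 0.0
        for b in range(n_blocks):
            clips = []
            for length in clip_lengths:
                clips.append((t, t + float(length)))
                t += float(length)
            blocks.append((f"{block_prefix}{b}", clips))
        return cls(blocks)

    @property
    def duration(self) -> float:
        """Total duration in seconds across all blocks."""
        if not self.blocks:
            return 0.0
        return max(e for _, clips in self.blocks for _, e in clips)

    @property
    def clips(self) -> list[tuple[str, float, float]]:
        """Flat list of ``(block_id, start, end)``."""
        return [(bid, s, e) for bid, cl in self.blocks for s, e in cl]

    def block_spans(self) -> list[tuple[str, float, float]]:
        """Per-block ``(block_id, start, end)``."""
        return [(bid, cl[0][0], cl[-1][1]) for bid, cl in self.blocks]

    def onset_mask(self, n: int, rate: float, skip: float = 5.0) -> np.ndarray:
        """Boolean mask of length ``n`` (True = excised) on a time base of
        ``rate`` samples (or frames) per second, marking the first ``skip``
        seconds of every clip.
        """
        if skip < 0:
            raise ValueError("skip must be >= 0")
        mask = np.zeros(n, dtype=bool)
        if skip == 0:
            return mask
        for bid, s, e in self.clips:
            if e - s < skip:
                logger.warning(
                    "clip [%g, %g) in %s shorter than skip=%g s; fully excised",
                    s, e, bid, skip,
                )
            i0 = int(np.floor(s * rate))
            i1 = int(np.floor(min(s + skip, e) * rate))
            mask[i0:min(i1, n)] = True
        return mask

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(bid, i, s, e) for bid, cl in self.blocks for i, (s, e) in enumerate(cl)],
            columns=["block", "clip", "start", "end"],
        )

    @classmethod
    def from_frame(cls, df) -> "ClipLayout":
        blocks = []
        for bid, sub in df.groupby("block", sort=False):
            sub = sub.sort_values("clip")
            blocks.append((str(bid), list(zip(sub["start"], sub["end"]))))
        return cls(blocks)
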