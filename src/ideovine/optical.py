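"""Optical vulnerability: embolism quantification from leaf scan sequences.

Embolism events appear as transient pixel changes between consecutive
scans of a dehydrating leaf.  The pipeline differences consecutive frames,
removes salt-and-pepper noise with a median filter, thresholds the
remainder, counts embolised pixels per frame and accumulates them into the
percentage of embolised pixels (PEP), the cumulative optical proxy for leaf
embolism.  Frames are consumed as a stream: only one previous frame is held
in memory, so stacks of thousands of scans process in bounded memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import OpticalStack


@dataclass
class OpticalConfig:
    median_size: int = 3  # salt-and-pepper outlier removal kernel
    threshold_k: float = 3.0  # global threshold at mean + k*SD of difference pixels
    threshold_abs: Optional[float] = None  # overrides the adaptive rule when set


def frame_difference_areas(
    frames: Iterable[np.ndarray],
    config: OpticalConfig | None = None,
) -> np.ndarray:
    """Embolised pixel count per frame transition (first frame yields 0).

    Consecutive frames are subtracted; unchanged pixels difference to zero.
    The absolute difference is median-filtered (outlier removal) and
    thresholded; the embolism area of the transition is the count of
    suprathreshold pixels.
    """
    cfg = config or OpticalConfig()
    counts = [0]
    it: Iterator[np.ndarray] = iter(frames)
    try:
        prev = np.asarray(next(it), dtype=np.int16)
    except StopIteration:
        raise ValueError("need at least two frames") from None
    n = 1
    for frame in it:
        cur = np.asarray(frame, dtype=np.int16)
        diff = np.abs(cur - prev).astype(np.float32)
        if cfg.median_size and cfg.median_size > 1:
            diff = ndimage.median_filter(diff, size=cfg.median_size)
        if cfg.threshold_abs is not None:
            thr = cfg.threshold_abs
        else:
            thr = float(diff.mean() + cfg.threshold_k * diff.std())
        counts.append(int(np.count_nonzero(diff > thr)))
        prev = cur
        n += 1
    if n < 2:
        raise ValueError("need at least two frames")
    return np.asarray(counts, dtype=float)


def quantify_optical_embolism(
    stack: OpticalStack,
    config: OpticalConfig | None = None,
) -> pd.DataFrame:
    """PEP time series of an optical stack.

    PEP(t) = 100 * cumulative embolised area up to t / total embolised area
    over the whole sequence; each frame carries the stem water potential
    interpolated from the concurrent psychrometer trace.

    Raises when no pixel ever changes (PEP undefined).
    """
    areas = frame_difference_areas(stack.frames, config)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all difference images are empty: PEP is undefined")
    pep = 100.0 * np.cumsum(areas) / total
    return pd.DataFrame(
        {
            "frame": np.arange(areas.size),
            "time": stack.frame_times,
            "psi_stem": stack.psi_at_frames(),
            "area_px": areas,
            "pep": pep,
        }
    )
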