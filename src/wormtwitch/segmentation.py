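"""Movie-frame segmentation and the full-body movie eligibility filter.

A single-worm contraction movie is reduced to a per-frame body-area signal in
three steps: per-frame thresholding (Otsu by default, fixed override), largest
connected-component selection to suppress debris, and pixel counting.  A movie
is eligible for contraction analysis only if the worm's entire body stays in
the field of view — operationalised as the mask touching no image border — for
a contiguous run of strictly more than ``min_seconds`` (default 3 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "FrameStack",
    "BinaryMaskStack",
    "AreaSeries",
    "QCResult",
    "segment_worm",
    "area_per_frame",
    "qc_full_body",
]

#: slack used when comparing a run duration against the eligibility cutoff, so
#: that e.g. 30 frames x 0.1 s (== 3.0 s up to float rounding) is *not* eligible
#: under the strict "more than" rule.
_DURATION_EPS_S = 1e-9


@dataclass
class FrameStack:
    """Ordered grayscale movie frames with a fixed frame interval.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; arbitrary intensity units.
    frame_interval_s
        Time between consecutive frames, seconds (the study's recordings use
        0.07 s/frame).
    """

    frames: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must have shape (T, H, W) with T >= 1")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class BinaryMaskStack:
    """Per-frame boolean body masks, aligned with a source :class:`FrameStack`."""

    masks: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3 or self.masks.shape[0] < 1:
            raise ValueError("masks must have shape (T, H, W) with T >= 1")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.masks.shape[0])

    @property
    def areas_px2(self) -> np.ndarray:
        """Foreground pixel count per frame."""
        return self.masks.sum(axis=(1, 2))


@dataclass
class AreaSeries:
    """Per-frame body area (pixels^2) plus the frame interval.

    This is the signal on which all contraction statistics are computed.
    """

    area_px2: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.area_px2 = np.asarray(self.area_px2, dtype=float)
        if self.area_px2.ndim != 1 or self.area_px2.size < 1:
            raise ValueError("area_px2 must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.area_px2)):
            raise ValueError("area_px2 contains non-finite values")
        if np.any(self.area_px2 < 0):
            raise ValueError("areas must be non-negative")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.area_px2.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class QCResult:
    """Outcome of the full-body continuity filter.

    ``run_start``/``run_stop`` delimit (half-open) the longest run of
    consecutive full-body frames, for downstream cropping.
    """

    eligible: bool
    longest_run_frames: int
    run_start: int
    run_stop: int
    min_seconds: float = 3.0


def segment_worm(
    stack: FrameStack,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_object_px: int = 20,
) -> BinaryMaskStack:
    """Threshold each frame and keep only the largest bright object.

    Per frame, pixels strictly above the threshold form candidate foreground;
    only the largest 8-connected component is retained, and only if its size is
    at least ``min_object_px`` (debris suppression).  An empty mask (area 0) is
    a valid outcome, e.g. for a blank or constant frame.

    Parameters
    ----------
    method
        ``"otsu"`` (parameter-free, per frame) or ``"fixed"``.
    fixed_threshold
        Required when ``method="fixed"``.
    min_object_px
        Smallest component size (pixels) kept as the body.
    """
    frames = stack.frames
    if not np.all(np.isfinite(frames)):
        raise ValueError("frame stack contains non-finite pixel values")
    if method not in ("otsu", "fixed"):
        raise ValueError(f"unknown threshold method: {method!r}")
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold is required with method='fixed'")
        if not np.isfinite(fixed_threshold):
            raise ValueError("fixed_threshold must be finite")

    masks = np.zeros(frames.shape, dtype=bool)
    for t in range(frames.shape[0]):
        frame = frames[t]
        if method == "fixed":
            thr = float(fixed_threshold)
        else:
            if frame.max() == frame.min():  # constant frame: nothing to segment
                continue
            thr = float(threshold_otsu(frame))
        cand = frame > thr
        if not cand.any():
            continue
        lab = label(cand, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        best = int(sizes.argmax())
        if sizes[best] >= min_object_px:
            masks[t] = lab == best
    return BinaryMaskStack(masks, stack.frame_interval_s)


def area_per_frame(
    masks: BinaryMaskStack, frame_interval_s: float | None = None
) -> AreaSeries:
    """Foreground pixel count per frame as an :class:`AreaSeries`."""
    dt = masks.frame_interval_s if frame_interval_s is None else frame_interval_s
    return AreaSeries(masks.areas_px2.astype(float), dt)


def _longest_true_run(flags: np.ndarray) -> tuple[int, int, int]:
    """Longest run of consecutive ``True``; returns (length, start, stop)."""
    best_len = best_start = 0
    cur_len = cur_start = 0
    for i, f in enumerate(flags):
        if f:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    return best_len, best_start, best_start + best_len


def qc_full_body(masks: BinaryMaskStack, min_seconds: float = 3.0) -> QCResult:
    """Apply the full-body movie eligibility filter.

    A frame is "full-body" iff its mask is non-empty and touches no image
    border (a clipped worm is the observable failure mode in a single-worm
    movie).  The movie is eligible iff the longest run of consecutive
    full-body frames lasts strictly more than ``min_seconds``, with duration
    counted as ``run_length * frame_interval_s``.
    """
    m = masks.masks
    nonempty = m.any(axis=(1, 2))
    border = (
        m[:, 0, :].any(axis=1)
        | m[:, -1, :].any(axis=1)
        | m[:, :, 0].any(axis=1)
        | m[:, :, -1].any(axis=1)
    )
    full = nonempty & ~border
    run_len, start, stop = _longest_true_run(full)
    eligible = run_len * masks.frame_interval_s > min_seconds + _DURATION_EPS_S
    return QCResult(bool(eligible), run_len, start, stop, min_seconds)
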