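"""Movement-trace area quantification (30-minute plate-track assay).

A worm left on a fresh plate for 30 minutes carves a visible track into the
bacterial lawn; the photographed track's pixel area is the locomotion
endpoint.  The measurement is a polarity-aware binarisation (tracks are dark
on a light lawn by default), small-speck removal, and a foreground pixel
count, optionally converted to mm^2 with a pixel scale.  No area-to-distance
conversion is attempted: none is defined for this assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = ["TrackImage", "MovementResult", "quantify_track_area"]

POLARITIES = ("dark_trace_on_light", "light_trace_on_dark")


@dataclass
class TrackImage:
    """Grayscale plate photograph of a worm's movement trace."""

    image: np.ndarray
    polarity: str = "dark_trace_on_light"
    pixel_scale_mm: float | None = None  # mm per pixel, optional

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("track image must be 2-D grayscale")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if self.pixel_scale_mm is not None and not self.pixel_scale_mm > 0:
            raise ValueError("pixel_scale_mm must be positive")


@dataclass
class MovementResult:
    trace_area_px2: int
    trace_area_mm2: float | None
    threshold_used: float


def quantify_track_area(
    img: TrackImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_component_px: int = 25,
) -> MovementResult:
    """Measure the pixel area covered by the movement trace.

    The image is binarised toward the trace polarity (Otsu by default, fixed
    threshold override), connected components smaller than
    ``min_component_px`` pixels are discarded as dust, and the remaining
    foreground pixel count is the trace area.  A constant (blank) image has
    area 0.
    """
    image = img.image
    if not np.all(np.isfinite(image)):
        raise ValueError("track image contains non-finite pixel values")
    if method not in ("otsu", "fixed"):
        raise ValueError(f"unknown threshold method: {method!r}")

    # work on a signal where the trace is bright
    signal = -image if img.polarity == "dark_trace_on_light" else image

    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold is required with method='fixed'")
        thr = float(fixed_threshold)
        if img.polarity == "dark_trace_on_light":
            thr = -thr  # user supplies the threshold in image units
    else:
        if signal.max() == signal.min():
            scale = img.pixel_scale_mm
            return MovementResult(0, 0.0 if scale else None, float(signal.max()))
        thr = float(threshold_otsu(signal))

    mask = signal > thr
    if min_component_px > 1 and mask.any():
        lab = label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = sizes >= min_component_px
        mask = keep[lab]
    area = int(mask.sum())
    scale = img.pixel_scale_mm
    area_mm2 = area * scale * scale if scale is not None else None
    thr_reported = -thr if img.polarity == "dark_trace_on_light" else thr
    return MovementResult(area, area_mm2, float(thr_reported))
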