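"""Nuclei counting and whole-body fluorescence intensity quantification.

Counts GFP-labelled body-wall-muscle nuclei in a (pre-cropped) bundle image by
difference-of-Gaussians bandpass filtering followed by local-maximum picking,
and quantifies background-subtracted whole-body fluorescence.  Both automate
measurements that are done by eye or with ImageJ in practice, so every
detection parameter is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians, threshold_otsu
from skimage.measure import label

__all__ = [
    "FluorescenceImage",
    "NucleiCount",
    "IntensityResult",
    "count_nuclei",
    "total_intensity",
]


@dataclass
class FluorescenceImage:
    """2-D grayscale fluorescence micrograph."""

    image: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("fluorescence image must be 2-D grayscale")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("fluorescence image contains non-finite values")


@dataclass
class NucleiCount:
    n_nuclei: int
    centers: np.ndarray  # (n, 2) array of (row, col)
    parameters: dict


@dataclass
class IntensityResult:
    integrated_intensity: float
    mean_intensity: float
    body_area_px2: int
    background_level: float


def count_nuclei(
    img: FluorescenceImage,
    blob_sigma_range: tuple[float, float] = (1.5, 4.0),
    min_peak_distance: int = 5,
    rel_threshold: float = 0.3,
) -> NucleiCount:
    """Count bright nuclear puncta.

    The image is bandpassed with a difference of Gaussians over
    ``blob_sigma_range`` and local maxima of the response are picked with a
    minimum pairwise separation of ``min_peak_distance`` pixels and a height
    of at least ``rel_threshold`` times the response maximum.  A constant
    image yields count 0 (not an error).
    """
    low, high = blob_sigma_range
    if not (0 < low < high):
        raise ValueError("blob_sigma_range must satisfy 0 < low < high")
    if min_peak_distance < 1:
        raise ValueError("min_peak_distance must be >= 1")
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")

    params = {
        "blob_sigma_range": (float(low), float(high)),
        "min_peak_distance": int(min_peak_distance),
        "rel_threshold": float(rel_threshold),
    }
    if img.image.max() == img.image.min():
        return NucleiCount(0, np.empty((0, 2), dtype=int), params)
    response = difference_of_gaussians(img.image, low, high)
    if response.max() <= 0:
        return NucleiCount(0, np.empty((0, 2), dtype=int), params)
    centers = peak_local_max(
        response,
        min_distance=min_peak_distance,
        threshold_abs=rel_threshold * float(response.max()),
        exclude_border=False,
    )
    # deterministic ordering by (row, col)
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    centers = centers[order]
    return NucleiCount(int(centers.shape[0]), centers, params)


def total_intensity(
    img: FluorescenceImage,
    body_threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    background_method: str = "mode",
    pct: float = 5.0,
    body_mask: np.ndarray | None = None,
) -> IntensityResult:
    """Background-subtracted integrated intensity over the body mask.

    The body is the largest connected component above an Otsu (or fixed)
    threshold, unless an explicit ``body_mask`` is supplied.  The background
    level is the intensity mode of the non-body pixels (suitable for
    quantized images) or, with ``background_method="percentile"``, their
    ``pct``-th percentile.  Integrated intensity sums ``pixel - background``
    over the body, clipped at zero; ``mean = integrated / area`` always holds.
    """
    image = img.image
    if background_method not in ("mode", "percentile"):
        raise ValueError(f"unknown background method: {background_method!r}")

    if body_mask is None:
        if body_threshold_method == "fixed":
            if fixed_threshold is None:
                raise ValueError("fixed_threshold required with method='fixed'")
            thr = float(fixed_threshold)
        elif body_threshold_method == "otsu":
            if image.max() == image.min():
                raise ValueError("empty body mask: image is constant")
            thr = float(threshold_otsu(image))
        else:
            raise ValueError(
                f"unknown body threshold method: {body_threshold_method!r}"
            )
        cand = image > thr
        if not cand.any():
            raise ValueError("empty body mask: no pixels above threshold")
        lab = label(cand, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        body_mask = lab == int(sizes.argmax())
    else:
        body_mask = np.asarray(body_mask, dtype=bool)
        if body_mask.shape != image.shape:
            raise ValueError("body_mask shape does not match image")
        if not body_mask.any():
            raise ValueError("empty body mask")

    outside = image[~body_mask]
    if outside.size == 0:
        background = 0.0
    elif background_method == "mode":
        values, counts = np.unique(outside, return_counts=True)
        background = float(values[np.argmax(counts)])
    else:
        background = float(np.percentile(outside, pct))

    body = image[body_mask]
    subtracted = np.clip(body - background, 0.0, None)
    integrated = float(subtracted.sum())
    area = int(body_mask.sum())
    return IntensityResult(integrated, integrated / area, area, background)
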