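"""Body-wall-muscle contraction statistics from a per-frame body-area signal.

The assay works on a mean-centred body-area signal ("deviation series"):

    dev[t] = area[t] - mean(area)                  (pixels^2)

Downward peaks (local minima) of this signal are counted as contractions.
Each contraction's amplitude is the excursion from the nearest preceding
upper peak (or, for a leading trough, from the window's first sample) down to
the trough.  Two summary statistics are reported per movie:

    rate_of_change = sum(amplitudes) / n_contractions      (mean excursion, px^2)
    frequency_hz   = n_contractions / (n_frames * dt)      (per second)

Peak detection is deliberately transparent: an optional centred moving
average, then local extrema selected by topographic prominence (default
threshold: 10 % of the deviation-series interquartile range).  All defaults
are overridable, and an ``"excursion_mean_per_contraction"`` alternative
reading of the rate-of-change formula (dividing the mean a second time by the
contraction count) is selectable for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import (
    AreaSeries,
    FrameStack,
    area_per_frame,
    qc_full_body,
    segment_worm,
)

__all__ = [
    "DeviationSeries",
    "PeakSet",
    "ContractionResult",
    "AssayConfig",
    "QCFailureError",
    "deviation_series",
    "moving_average",
    "detect_peaks",
    "contraction_metrics",
    "run_contraction_assay",
]


class QCFailureError(ValueError):
    """Raised when a movie fails the full-body continuity filter."""


@dataclass
class DeviationSeries:
    """Mean-centred body-area signal: per-frame (area - mean area)."""

    deviation_px2: np.ndarray
    mean_area_px2: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.deviation_px2 = np.asarray(self.deviation_px2, dtype=float)
        if self.deviation_px2.ndim != 1 or self.deviation_px2.size < 1:
            raise ValueError("deviation_px2 must be a non-empty 1-D array")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.deviation_px2.size)


@dataclass
class PeakSet:
    """Upper (local-maximum) and lower (local-minimum) peaks of a deviation series.

    Indices are frame numbers within the analysis window; values are read off
    the *unsmoothed* deviation signal at the smoothed-extremum index.  Merged
    by index, upper and lower peaks alternate.
    """

    upper_peak_frames: np.ndarray
    lower_peak_frames: np.ndarray
    upper_peak_values: np.ndarray
    lower_peak_values: np.ndarray

    def __post_init__(self) -> None:
        self.upper_peak_frames = np.asarray(self.upper_peak_frames, dtype=int)
        self.lower_peak_frames = np.asarray(self.lower_peak_frames, dtype=int)
        self.upper_peak_values = np.asarray(self.upper_peak_values, dtype=float)
        self.lower_peak_values = np.asarray(self.lower_peak_values, dtype=float)


@dataclass
class ContractionResult:
    """Contraction count, per-contraction amplitudes and summary statistics."""

    n_contractions: int
    amplitudes_px2: np.ndarray
    rate_of_change_px2: float
    frequency_hz: float
    n_analysis_frames: int
    rate_defined: bool = True
    provenance: dict = field(default_factory=dict)


def deviation_series(series: AreaSeries) -> DeviationSeries:
    """Subtract the window-mean body area from every frame's area."""
    mean_area = float(series.area_px2.mean())
    return DeviationSeries(
        series.area_px2 - mean_area, mean_area, series.frame_interval_s
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; windows shrink symmetrically at the ends.

    ``smooth[i]`` averages ``x[max(0, i-h) : i+h+1]`` with ``h = window // 2``,
    so the output has the same length as the input and no zero-padding bias.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > x.size:
        raise ValueError("smoothing window longer than the series")
    if window == 1:
        return x.copy()
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(x.size)
    lo = np.maximum(0, i - h)
    hi = np.minimum(x.size, i + h + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat-topped peak reports its midpoint.

    Series endpoints are never maxima (truncation artifacts).
    """
    peaks: list[int] = []
    n = x.size
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _prominences(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Topographic prominence of each peak.

    On each side, walk outward until a sample higher than the peak (or the
    series end); the side's base is the minimum over that stretch.  The
    prominence is the peak height minus the higher of the two bases.
    """
    proms = np.empty(peaks.size, dtype=float)
    n = x.size
    for idx, p in enumerate(peaks):
        h = x[p]
        left_min = h
        i = p - 1
        while i >= 0 and x[i] <= h:
            if x[i] < left_min:
                left_min = x[i]
            i -= 1
        right_min = h
        i = p + 1
        while i < n and x[i] <= h:
            if x[i] < right_min:
                right_min = x[i]
            i += 1
        proms[idx] = h - max(left_min, right_min)
    return proms


def _prominent_maxima(x: np.ndarray, min_prominence: float) -> np.ndarray:
    peaks = _local_maxima(x)
    if peaks.size == 0:
        return peaks
    return peaks[_prominences(x, peaks) >= min_prominence]


def detect_peaks(
    dev: DeviationSeries,
    smooth_window_frames: int = 3,
    min_prominence_px2: float | None = None,
) -> PeakSet:
    """Find upper and lower peaks of the (optionally smoothed) deviation signal.

    Lower peaks are local minima of the smoothed signal with topographic
    prominence at least ``min_prominence_px2`` (default: 10 % of the
    deviation-series interquartile range).  Two contractions must be
    separated by an actual relaxation: adjacent prominent minima with no
    prominent maximum between them are merged, keeping the deepest (earliest
    on ties) — this collapses equal-depth twin dips across a flat trough
    bottom into one contraction.  Upper peaks are local maxima: exactly one —
    the highest sample — between each adjacent pair of lower peaks, plus,
    where present, the highest prominent maximum flanking the first/last
    lower peak.  Peak values are reported on the unsmoothed signal at the
    smoothed-extremum index; endpoints are never peaks.
    """
    x = dev.deviation_px2
    smooth = moving_average(x, smooth_window_frames)
    if min_prominence_px2 is None:
        q75, q25 = np.percentile(x, [75, 25])
        min_prominence_px2 = 0.1 * (q75 - q25)
    if min_prominence_px2 < 0:
        raise ValueError("min_prominence_px2 must be >= 0")

    lower = _prominent_maxima(-smooth, min_prominence_px2)
    upper_candidates = _prominent_maxima(smooth, min_prominence_px2)

    if lower.size > 1:
        # merge runs of minima not separated by a prominent maximum
        keys = np.searchsorted(upper_candidates, lower)
        merged = []
        for key in dict.fromkeys(keys.tolist()):
            group = lower[keys == key]
            merged.append(int(group[np.argmin(smooth[group])]))
        lower = np.asarray(merged, dtype=int)

    if lower.size == 0:
        upper = upper_candidates
    else:
        chosen: list[int] = []
        # flanking maximum before the first trough, if any prominent one exists
        pre = upper_candidates[upper_candidates < lower[0]]
        if pre.size:
            chosen.append(int(pre[np.argmax(smooth[pre])]))
        # exactly one maximum between each adjacent pair of troughs: the
        # highest interior sample (always exists between two strict minima)
        for a, b in zip(lower[:-1], lower[1:]):
            seg = slice(a + 1, b)
            chosen.append(int(a + 1 + np.argmax(smooth[seg])))
        post = upper_candidates[upper_candidates > lower[-1]]
        if post.size:
            chosen.append(int(post[np.argmax(smooth[post])]))
        upper = np.asarray(sorted(chosen), dtype=int)

    return PeakSet(upper, lower, x[upper], x[lower])


def contraction_metrics(
    dev: DeviationSeries,
    peaks: PeakSet,
    rate_formula: str = "mean_excursion",
) -> ContractionResult:
    """Count contractions and compute amplitude and frequency statistics.

    Each lower peak is one contraction.  Its amplitude is the deviation value
    of the nearest preceding upper peak — or the window's first sample when no
    upper peak precedes it — minus the lower-peak value.  ``rate_formula``
    selects how the per-movie contraction-strength statistic is formed:

    - ``"mean_excursion"`` (default): sum(amplitudes) / n, the mean
      peak-to-trough excursion;
    - ``"mean_excursion_per_contraction"``: the mean excursion divided once
      more by n (alternative operator-precedence reading, for sensitivity
      analysis; shrinks with movie length).

    A movie with zero contractions yields frequency 0 and an undefined
    (NaN-flagged) rate of change — not an error.
    """
    if rate_formula not in ("mean_excursion", "mean_excursion_per_contraction"):
        raise ValueError(f"unknown rate_formula: {rate_formula!r}")
    x = dev.deviation_px2
    n_frames = dev.n_frames
    lower = peaks.lower_peak_frames
    upper = peaks.upper_peak_frames
    n = int(lower.size)

    if n == 0:
        return ContractionResult(
            n_contractions=0,
            amplitudes_px2=np.empty(0),
            rate_of_change_px2=float("nan"),
            frequency_hz=0.0,
            n_analysis_frames=n_frames,
            rate_defined=False,
        )

    amplitudes = np.empty(n, dtype=float)
    for i, low in enumerate(lower):
        preceding = upper[upper < low]
        ref = x[preceding[-1]] if preceding.size else x[0]
        amplitudes[i] = ref - x[low]

    rate = float(amplitudes.sum() / n)
    if rate_formula == "mean_excursion_per_contraction":
        rate /= n
    frequency = n / (n_frames * dev.frame_interval_s)
    return ContractionResult(
        n_contractions=n,
        amplitudes_px2=amplitudes,
        rate_of_change_px2=rate,
        frequency_hz=float(frequency),
        n_analysis_frames=n_frames,
        rate_defined=True,
    )


@dataclass(frozen=True)
class AssayConfig:
    """End-to-end contraction-assay parameters (all stages)."""

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_object_px: int = 20
    smooth_window_frames: int = 3
    #: explicit prominence threshold (px^2); overrides the IQR fraction
    min_prominence_px2: float | None = None
    #: prominence threshold as a fraction of the deviation-series IQR
    prominence_iqr_fraction: float = 0.1
    rate_formula: str = "mean_excursion"
    min_track_seconds: float = 3.0


def run_contraction_assay(
    stack: FrameStack, config: AssayConfig = AssayConfig()
) -> ContractionResult:
    """Segment a movie, apply the eligibility filter, and compute metrics.

    Statistics are computed on the longest eligible full-body run only ("the
    analysis window"), not the whole movie.  Raises :class:`QCFailureError`
    for ineligible movies.
    """
    masks = segment_worm(
        stack,
        method=config.threshold_method,
        fixed_threshold=config.fixed_threshold,
        min_object_px=config.min_object_px,
    )
    qc = qc_full_body(masks, config.min_track_seconds)
    if not qc.eligible:
        raise QCFailureError(
            "movie fails the full-body continuity filter: longest full-body run "
            f"is {qc.longest_run_frames} frames "
            f"({qc.longest_run_frames * stack.frame_interval_s:.3f} s), "
            f"which is not more than {config.min_track_seconds:g} s"
        )
    series = area_per_frame(masks)
    window = AreaSeries(
        series.area_px2[qc.run_start : qc.run_stop], series.frame_interval_s
    )
    dev = deviation_series(window)
    if config.min_prominence_px2 is not None:
        prominence = config.min_prominence_px2
    else:
        q75, q25 = np.percentile(dev.deviation_px2, [75, 25])
        prominence = config.prominence_iqr_fraction * (q75 - q25)
    peaks = detect_peaks(dev, config.smooth_window_frames, prominence)
    result = contraction_metrics(dev, peaks, config.rate_formula)
    result.provenance = {
        "window_start_frame": qc.run_start,
        "window_stop_frame": qc.run_stop,
        "n_analysis_frames": qc.longest_run_frames,
        "threshold_method": config.threshold_method,
        "fixed_threshold": config.fixed_threshold,
        "min_object_px": config.min_object_px,
        "smooth_window_frames": config.smooth_window_frames,
        "min_prominence_px2": float(prominence),
        "rate_formula": config.rate_formula,
        "min_track_seconds": config.min_track_seconds,
    }
    return result
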