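"""Reading and writing the package's file formats (TIFF movies/images, CSV)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segmentation import AreaSeries, FrameStack

__all__ = [
    "read_movie",
    "write_movie",
    "read_gray_image",
    "write_gray_image",
    "area_series_to_frame",
    "write_area_series_csv",
    "read_area_series_csv",
    "sha256_file",
]


def read_movie(path, frame_interval_s: float) -> FrameStack:
    """Read a (multi-page) TIFF movie as a FrameStack."""
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames, frame_interval_s)


def write_movie(stack: FrameStack, path) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32))


def read_gray_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = np.asarray(tifffile.imread(path), dtype=float)
    else:
        img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse color channels
        img = img[..., :3].mean(axis=-1)
    return img


def write_gray_image(img: np.ndarray, path) -> None:
    path = Path(path)
    img = np.asarray(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.astype(np.float32))
    else:
        lo, hi = float(img.min()), float(img.max())
        scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
        iio.imwrite(path, np.rint(scaled * 255).astype(np.uint8))


def area_series_to_frame(series: AreaSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "time_s": series.times_s,
            "area_px2": series.area_px2,
        }
    )


def write_area_series_csv(series: AreaSeries, path) -> None:
    area_series_to_frame(series).to_csv(path, index=False)


def read_area_series_csv(path, frame_interval_s: float | None = None) -> AreaSeries:
    df = pd.read_csv(path)
    if frame_interval_s is None:
        times = np.asarray(df["time_s"], dtype=float)
        if times.size < 2:
            raise ValueError(
                "cannot infer frame interval from a single-row CSV; "
                "pass frame_interval_s"
            )
        frame_interval_s = float(np.diff(times).mean())
    return AreaSeries(np.asarray(df["area_px2"], dtype=float), frame_interval_s)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
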