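"""Synthetic assay data with exact ground truth.

Every downstream stage of the package (segmentation, contraction statistics,
trace-area and fluorescence quantification, group statistics) can be verified
without laboratory data against the generators here.  Each generator is a
pure, seeded function of its specification and returns a
:class:`GroundTruth` sidecar describing exactly what was drawn.

Conventions
-----------
* Movies and fluorescence images are bright-on-dark; trace images are
  dark-on-light (a track carved into a bacterial lawn).
* The contraction waveform is a cosine with additive i.i.d. Gaussian noise —
  the simplest signal with unambiguous analytic troughs:

      area(t) = baseline - (amplitude / 2) * (1 - cos(2 pi f t)) + noise

  so the body area starts at the baseline (fully relaxed) and dips by
  ``amplitude`` px^2 at each contraction.  A trough belongs to the ground
  truth iff its analytic minimum lies inside the sampled window.
* Cohort effect presets are calibrated as standardized differences (Cohen's
  d), not raw physiological units: only the ordering and significance
  structure of the phenotypes is being emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .fluorescence import FluorescenceImage
from .locomotion import TrackImage
from .segmentation import AreaSeries, FrameStack

__all__ = [
    "WormSceneSpec",
    "ConditionSpec",
    "CohortSpec",
    "GroundTruth",
    "gen_area_series",
    "gen_worm_movie",
    "gen_track_image",
    "gen_nuclei_image",
    "gen_cohort",
    "rasterize_polyline",
    "contractility_preset",
    "two_group_contractility_preset",
    "null_cohort_preset",
    "mobility_preset",
    "aging_mobility_preset",
    "muscle_integrity_preset",
    "COUNT_ENDPOINTS",
]


@dataclass
class GroundTruth:
    """Oracle sidecar: exactly what a generator drew.

    Only the fields relevant to the generated object are populated.
    """

    true_area_per_frame: np.ndarray | None = None
    true_n_contractions: int | None = None
    true_trough_frames: np.ndarray | None = None
    true_mean_amplitude_px2: float | None = None
    true_trace_area: int | None = None
    true_nuclei_centers: np.ndarray | None = None
    true_condition_means: dict | None = None


@dataclass(frozen=True)
class WormSceneSpec:
    """Parameters of a synthetic single-worm contraction scene.

    ``pixel_noise_sd`` is additive Gaussian noise.  For rendered movies it is
    in intensity units (the worm is at 1.0 on a 0.0 background); for directly
    generated area series it is applied to the signal and therefore read in
    px^2.
    """

    image_height: int = 96
    image_width: int = 128
    n_frames: int = 143
    frame_interval_s: float = 0.07
    baseline_area: float = 600.0
    contraction_amplitude: float = 100.0  # peak-to-trough, px^2
    contraction_freq_hz: float = 1.0
    pixel_noise_sd: float = 0.0
    body_touches_border_frames: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if self.contraction_amplitude < 0:
            raise ValueError("contraction_amplitude must be >= 0")
        if not self.baseline_area > self.contraction_amplitude / 2:
            raise ValueError(
                "baseline_area must exceed contraction_amplitude/2 "
                "(amplitude > 2*baseline would yield negative areas)"
            )
        if self.contraction_freq_hz < 0:
            raise ValueError("contraction_freq_hz must be >= 0")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        object.__setattr__(
            self, "body_touches_border_frames",
            tuple(int(t) for t in self.body_touches_border_frames),
        )
        for t in self.body_touches_border_frames:
            if not 0 <= t < self.n_frames:
                raise ValueError(f"border-contact frame {t} outside the movie")


def _analytic_areas(spec: WormSceneSpec) -> np.ndarray:
    t = np.arange(spec.n_frames) * spec.frame_interval_s
    osc = 1.0 - np.cos(2.0 * math.pi * spec.contraction_freq_hz * t)
    return spec.baseline_area - 0.5 * spec.contraction_amplitude * osc


def _analytic_troughs(spec: WormSceneSpec) -> np.ndarray:
    """Frame indices nearest the analytic cosine minima inside the window."""
    if spec.contraction_amplitude <= 0 or spec.contraction_freq_hz <= 0:
        return np.empty(0, dtype=int)
    dt = spec.frame_interval_s
    t_max = (spec.n_frames - 1) * dt
    f = spec.contraction_freq_hz
    k_max = int(math.floor(f * t_max - 0.5 + 1e-12))
    if k_max < 0:
        return np.empty(0, dtype=int)
    times = (np.arange(k_max + 1) + 0.5) / f
    return np.clip(np.rint(times / dt).astype(int), 0, spec.n_frames - 1)


def gen_area_series(spec: WormSceneSpec) -> tuple[AreaSeries, GroundTruth]:
    """Generate a body-area signal directly (no rendering).

    area(t) = baseline - (amplitude/2) * (1 - cos(2 pi f t)) + noise, with the
    analytic trough frames and their in-window count as ground truth.
    """
    if spec.contraction_amplitude > spec.baseline_area:
        raise ValueError("amplitude exceeds baseline: areas would go negative")
    rng = np.random.default_rng(spec.seed)
    clean = _analytic_areas(spec)
    noisy = clean + rng.normal(0.0, spec.pixel_noise_sd, spec.n_frames) \
        if spec.pixel_noise_sd > 0 else clean.copy()
    troughs = _analytic_troughs(spec)
    truth = GroundTruth(
        true_area_per_frame=clean,
        true_n_contractions=int(troughs.size),
        true_trough_frames=troughs,
        true_mean_amplitude_px2=float(spec.contraction_amplitude),
    )
    return AreaSeries(np.clip(noisy, 0.0, None), spec.frame_interval_s), truth


def _worm_pixel_order(
    spec: WormSceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rank all canvas pixels by distance to a sinusoidal worm centerline.

    Taking the first k ranked pixels yields a connected, worm-shaped tube of
    exactly k pixels; modulating k over frames modulates the body area with
    pixel-exact ground truth.
    """
    H, W = spec.image_height, spec.image_width
    transpose = H > W  # lay the worm along the longer axis
    if transpose:
        H, W = W, H
    k_max = int(round(spec.baseline_area))
    length = int(0.62 * W)
    r_est = k_max / (2.0 * max(length, 1)) + 2.0
    margin = int(math.ceil(r_est)) + 2
    wave_amp = max(2.0, 0.10 * H)
    if length + 2 * margin > W or 2 * wave_amp + 2 * margin > H or length < 4:
        raise ValueError(
            f"worm region of {k_max} px cannot fit in a "
            f"{spec.image_height}x{spec.image_width} image"
        )
    x0 = (W - length) // 2
    y0 = H / 2.0 + rng.uniform(-0.04, 0.04) * H
    phase = rng.uniform(0.0, 2.0 * math.pi)
    cycles = rng.uniform(1.0, 1.8)

    s = np.linspace(0.0, 1.0, 4 * length)
    xs = x0 + s * length
    ys = y0 + wave_amp * np.sin(2.0 * math.pi * cycles * s + phase)
    center = np.zeros((H, W), dtype=bool)
    rr = np.clip(np.rint(ys).astype(int), 0, H - 1)
    cc = np.clip(np.rint(xs).astype(int), 0, W - 1)
    center[rr, cc] = True

    dist = ndimage.distance_transform_edt(~center)
    order = np.lexsort((np.arange(dist.size), dist.ravel()))
    rows, cols = np.unravel_index(order, (H, W))
    body_r, body_c = rows[:k_max], cols[:k_max]
    if (
        body_r.min() == 0 or body_r.max() == H - 1
        or body_c.min() == 0 or body_c.max() == W - 1
    ):
        raise ValueError(
            f"worm region of {k_max} px cannot fit in a "
            f"{spec.image_height}x{spec.image_width} image without touching "
            "the border"
        )
    if transpose:
        rows, cols = cols, rows
    return rows, cols


def gen_worm_movie(spec: WormSceneSpec) -> tuple[FrameStack, GroundTruth]:
    """Render a movie of one bright worm whose area follows the cosine signal.

    Before noise, each frame's foreground pixel count equals the ground-truth
    area exactly.  Frames listed in ``body_touches_border_frames`` have the
    worm translated so that it is clipped by the top image edge (their
    ground-truth area is the remaining, clipped pixel count).
    """
    if spec.contraction_amplitude > spec.baseline_area:
        raise ValueError("amplitude exceeds baseline: areas would go negative")
    rng = np.random.default_rng(spec.seed)
    rows, cols = _worm_pixel_order(spec, rng)
    ks = np.rint(_analytic_areas(spec)).astype(int)
    H, W, T = spec.image_height, spec.image_width, spec.n_frames
    border_frames = set(spec.body_touches_border_frames)

    frames = np.zeros((T, H, W), dtype=np.float32)
    realized = np.empty(T, dtype=int)
    for t in range(T):
        k = ks[t]
        r, c = rows[:k], cols[:k]
        if t in border_frames:
            r = r - (r.min() + 2)  # push past the top edge: clip two rows
            keep = r >= 0
            r, c = r[keep], c[keep]
        frames[t, r, c] = 1.0
        realized[t] = r.size
    if spec.pixel_noise_sd > 0:
        frames = frames + rng.normal(
            0.0, spec.pixel_noise_sd, frames.shape
        ).astype(np.float32)

    troughs = _analytic_troughs(spec)
    truth = GroundTruth(
        true_area_per_frame=realized,
        true_n_contractions=int(troughs.size),
        true_trough_frames=troughs,
        true_mean_amplitude_px2=float(spec.contraction_amplitude),
    )
    return FrameStack(frames, spec.frame_interval_s), truth


def rasterize_polyline(
    points: Sequence[tuple[float, float]],
    stroke_width_px: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize a polyline of (row, col) vertices onto a boolean canvas.

    Segments share their endpoint pixels, so the result is the *union* of the
    per-segment pixel sets.  Stroke widths > 1 are rendered by dilating the
    1-px polyline with a disk of radius ``round((w - 1) / 2)`` (odd widths are
    exact; even widths round up to the next odd width).
    """
    if stroke_width_px < 1:
        raise ValueError("stroke_width_px must be >= 1")
    mask = np.zeros(shape, dtype=bool)
    pts = [(int(round(r)), int(round(c))) for r, c in points]
    if len(pts) == 1:
        mask[pts[0]] = True
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    radius = int(round((stroke_width_px - 1) / 2))
    if radius > 0:
        mask = dilation(mask, disk(radius))
    return mask


def gen_track_image(
    n_steps: int,
    step_length_px: float = 12.0,
    stroke_width_px: int = 2,
    image_size: tuple[int, int] = (240, 240),
    seed: int = 0,
    background_level: float = 0.85,
    trace_level: float = 0.15,
) -> tuple[TrackImage, GroundTruth]:
    """Generate a plate photograph of a random-walk movement trace.

    The walk starts at the plate centre with a persistent heading perturbed by
    Gaussian turns; a step that would leave the canvas is reflected at the
    borders (documented behaviour, not an error).  The trace is dark on a
    light background and ``true_trace_area`` is the exact count of rasterized
    trace pixels (the union over self-crossings).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    H, W = image_size
    rng = np.random.default_rng(seed)
    pad = int(round((stroke_width_px - 1) / 2)) + 1
    lo_r, hi_r = float(pad), float(H - 1 - pad)
    lo_c, hi_c = float(pad), float(W - 1 - pad)

    r, c = H / 2.0, W / 2.0
    heading = rng.uniform(0.0, 2.0 * math.pi)
    points = [(r, c)]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.7)
        r += step_length_px * math.sin(heading)
        c += step_length_px * math.cos(heading)
        # reflect at the padded borders
        while not (lo_r <= r <= hi_r and lo_c <= c <= hi_c):
            if r < lo_r:
                r = 2 * lo_r - r
            elif r > hi_r:
                r = 2 * hi_r - r
            if c < lo_c:
                c = 2 * lo_c - c
            elif c > hi_c:
                c = 2 * hi_c - c
        points.append((r, c))

    if n_steps == 0:
        mask = np.zeros((H, W), dtype=bool)
    else:
        mask = rasterize_polyline(points, stroke_width_px, (H, W))
    image = np.full((H, W), background_level, dtype=float)
    image[mask] = trace_level
    truth = GroundTruth(true_trace_area=int(mask.sum()))
    return TrackImage(image, polarity="dark_trace_on_light"), truth


def gen_nuclei_image(
    n_nuclei: int,
    min_separation_px: float = 12.0,
    blob_sigma_px: float = 2.5,
    noise_sd: float = 0.0,
    image_size: tuple[int, int] = (160, 160),
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[FluorescenceImage, GroundTruth]:
    """Generate a muscle-bundle image with countable nuclear GFP puncta.

    Spots are isotropic Gaussians of width ``blob_sigma_px`` placed at
    integer pixel centres, pairwise at least ``min_separation_px`` apart, on a
    dark background with optional Gaussian noise.  Raises if the requested
    packing is infeasible.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    H, W = image_size
    rng = np.random.default_rng(seed)
    margin = int(math.ceil(3.0 * blob_sigma_px)) + 2
    if n_nuclei > 0 and (H - 2 * margin < 1 or W - 2 * margin < 1):
        raise ValueError(
            f"cannot place {n_nuclei} nuclei: margin {margin}px leaves no "
            f"interior in a {H}x{W} image"
        )

    centers: list[tuple[int, int]] = []
    tries = 0
    max_tries = 1000 * max(n_nuclei, 1) + 1000
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_nuclei} nuclei with min_separation_px="
                f"{min_separation_px} inside a {H}x{W} image (packing "
                "constraint infeasible)"
            )
        cand = (
            int(rng.integers(margin, H - margin)),
            int(rng.integers(margin, W - margin)),
        )
        if all(
            (cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_separation_px**2
            for r, c in centers
        ):
            centers.append(cand)

    image = np.zeros((H, W), dtype=float)
    rr, cc = np.mgrid[0:H, 0:W]
    for r, c in centers:
        image += amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * blob_sigma_px**2)
        )
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, image.shape)

    centers_arr = np.asarray(sorted(centers), dtype=int).reshape(-1, 2)
    truth = GroundTruth(true_nuclei_centers=centers_arr)
    return FluorescenceImage(image, channel_label="synthetic-GFP"), truth


# --------------------------------------------------------------------------
# cohort generation


#: endpoints drawn as counts (rounded to integers after truncation at 0)
COUNT_ENDPOINTS = frozenset({"nuclei_count"})


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition and its per-endpoint effect model."""

    genotype: str
    fbx_dose_ug_ml: float = 0.0
    ua_dose_mM: float = 0.0
    day: int = 4
    #: endpoint name -> (mean, sd)
    endpoints: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (mean, sd) in self.endpoints.items():
            if sd < 0:
                raise ValueError(f"dispersion for endpoint {name!r} must be >= 0")

    @property
    def label(self) -> str:
        return (
            f"{self.genotype}|fbx{self.fbx_dose_ug_ml:g}"
            f"|ua{self.ua_dose_mM:g}|d{self.day}"
        )


@dataclass(frozen=True)
class CohortSpec:
    """A set of conditions with per-animal endpoint distributions."""

    conditions: tuple[ConditionSpec, ...]
    n_animals_per_condition: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) < 1:
            raise ValueError("at least one condition is required")
        if self.n_animals_per_condition < 1:
            raise ValueError("n_animals_per_condition must be >= 1")


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a per-animal measurement table with known condition means.

    Values are normal draws truncated at 0 (areas, rates, intensities cannot
    be negative); count endpoints are additionally rounded to integers.  The
    table is long-format with one row per (animal, endpoint).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_animals_per_condition
    rows: list[dict] = []
    truth_means: dict[str, dict[str, float]] = {}
    for ci, cond in enumerate(spec.conditions):
        truth_means[cond.label] = {}
        for name, (mean, sd) in cond.endpoints.items():
            truth_means[cond.label][name] = float(mean)
            values = np.clip(rng.normal(mean, sd, n), 0.0, None)
            if name in COUNT_ENDPOINTS:
                values = np.rint(values)
            for j in range(n):
                rows.append(
                    {
                        "animal_id": f"a{ci:02d}_{j:03d}",
                        "genotype": cond.genotype,
                        "fbx_dose_ug_ml": cond.fbx_dose_ug_ml,
                        "ua_dose_mM": cond.ua_dose_mM,
                        "day": cond.day,
                        "condition": cond.label,
                        "endpoint": name,
                        "value": float(values[j]),
                    }
                )
    table = pd.DataFrame(rows)
    return table, GroundTruth(true_condition_means=truth_means)


# --------------------------------------------------------------------------
# cohort presets emulating the study's phenotype structure


def contractility_preset(
    n_animals: int = 30, seed: int = 0, days: tuple[int, ...] = (4, 7, 9, 12)
) -> CohortSpec:
    """Contraction endpoints for the twitching single vs. double mutant.

    The dystrophin-deficient double mutant has a lower contraction-amplitude
    mean than the single mutant at matched frequency means (standardized
    difference d = 5 at days 4-9, no difference by day 12); contraction
    frequency is identical between genotypes at every day.
    """
    amp_unc = {4: 2.0, 7: 1.8, 9: 1.6, 12: 1.2}
    amp_dys = {4: 1.0, 7: 0.9, 9: 0.8, 12: 1.2}
    conditions = []
    for day in days:
        for genotype, amps in (
            ("unc-22(e66)", amp_unc),
            ("dys-1(tm4402);unc-22(e66)", amp_dys),
        ):
            conditions.append(
                ConditionSpec(
                    genotype=genotype,
                    day=day,
                    endpoints={
                        "contraction_amplitude": (amps[day], 0.2),
                        "contraction_frequency": (1.0, 0.15),
                    },
                )
            )
    return CohortSpec(tuple(conditions), n_animals, seed)


def two_group_contractility_preset(
    n_animals: int = 30, seed: int = 0, d: float = 5.0, sd: float = 0.2
) -> CohortSpec:
    """Two genotypes differing in amplitude by ``d`` standard deviations."""
    conditions = (
        ConditionSpec(
            genotype="unc-22(e66)",
            endpoints={
                "contraction_amplitude": (1.0 + d * sd, sd),
                "contraction_frequency": (1.0, 0.15),
            },
        ),
        ConditionSpec(
            genotype="dys-1(tm4402);unc-22(e66)",
            endpoints={
                "contraction_amplitude": (1.0, sd),
                "contraction_frequency": (1.0, 0.15),
            },
        ),
    )
    return CohortSpec(conditions, n_animals, seed)


def null_cohort_preset(
    n_groups: int = 2,
    n_animals: int = 30,
    seed: int = 0,
    endpoint: str = "contraction_frequency",
    mean: float = 1.0,
    sd: float = 0.15,
) -> CohortSpec:
    """Equal-mean conditions, for type-I-error simulations."""
    conditions = tuple(
        ConditionSpec(genotype=f"group{i + 1}", endpoints={endpoint: (mean, sd)})
        for i in range(n_groups)
    )
    return CohortSpec(conditions, n_animals, seed)


def mobility_preset(n_animals: int = 30, seed: int = 0) -> CohortSpec:
    """Day-12 treatment rescue of the double mutant's trace area.

    Trace-area means rise with xanthine-oxidoreductase-inhibitor dose and
    further with co-administered uric acid (dose-ordered means).
    """
    genotype = "dys-1(tm4402);unc-22(e66)"
    levels = [  # (fbx ug/ml, ua mM, trace-area mean px^2)
        (0.0, 0.0, 6000.0),
        (5.0, 0.0, 8000.0),
        (40.0, 0.0, 9500.0),
        (40.0, 2.0, 11500.0),
    ]
    conditions = tuple(
        ConditionSpec(
            genotype=genotype,
            fbx_dose_ug_ml=fbx,
            ua_dose_mM=ua,
            day=12,
            endpoints={"trace_area": (mean, 1500.0)},
        )
        for fbx, ua, mean in levels
    )
    return CohortSpec(conditions, n_animals, seed)


def aging_mobility_preset(
    n_animals: int = 30, seed: int = 0, days: tuple[int, ...] = (4, 7, 9, 12)
) -> CohortSpec:
    """Trace area declining with age, identically in both genotypes."""
    means = {4: 12000.0, 7: 9000.0, 9: 7000.0, 12: 4000.0}
    conditions = []
    for day in days:
        for genotype in ("unc-22(e66)", "dys-1(tm4402);unc-22(e66)"):
            conditions.append(
                ConditionSpec(
                    genotype=genotype,
                    day=day,
                    endpoints={"trace_area": (means[day], 1800.0)},
                )
            )
    return CohortSpec(tuple(conditions), n_animals, seed)


def muscle_integrity_preset(n_animals: int = 30, seed: int = 0) -> CohortSpec:
    """Nuclei counts and whole-body intensity: mutant deficit, dose-dependent
    partial rescue that does not reach the wild-type level."""
    levels = [  # (genotype, fbx, nuclei mean, intensity mean)
        ("wild-type", 0.0, 23.0, 100.0),
        ("dys-1(tm4402)", 0.0, 14.0, 55.0),
        ("dys-1(tm4402)", 5.0, 18.0, 70.0),
        ("dys-1(tm4402)", 10.0, 21.0, 80.0),
    ]
    conditions = tuple(
        ConditionSpec(
            genotype=genotype,
            fbx_dose_ug_ml=fbx,
            day=12,
            endpoints={
                "nuclei_count": (nuc, 2.5),
                "muscle_intensity": (inten, 12.0),
            },
        )
        for genotype, fbx, nuc, inten in levels
    )
    return CohortSpec(conditions, n_animals, seed)
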