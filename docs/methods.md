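# Methods

## Scope and model of the measurement

`wormtwitch` implements four measurement procedures and their shared
statistics:

1. **Contraction assay** — a per-frame body-area signal from a single-worm
   movie, mean-centred, with downward peaks counted as contractions and
   summarised as mean peak-to-trough excursion ("rate of change in body
   area", px²) and contraction frequency (Hz).
2. **Movement-trace area** — the pixel area of the track a worm carves into
   a bacterial lawn over 30 minutes, from one plate photograph.
3. **Fluorescence** — counting GFP-labelled muscle nuclei in a pre-cropped
   bundle image, and background-subtracted whole-body integrated intensity.
4. **Group comparison** — mean ± SEM summaries, one-way fixed-effects ANOVA,
   Tukey HSD (Tukey–Kramer for unequal n), significance at p < 0.05.

The guiding constraint is that none of the upstream assays has a closed-form
reference on real data, so every stage is built to be checkable against a
synthetic generator whose ground truth is exact by construction.

## Contraction assay

### Signal definition

For an analysis window of N frames at interval Δt (0.07 s in the recordings
this assay is designed for), the deviation series is D(t) = A(t) − mean(A).
All downstream statistics are invariant to adding a constant to all areas and
equivariant (in amplitude) to scaling, which the test suite checks as
properties.

### Eligibility filter

A movie is analysed only if the worm's whole body is captured continuously
for *strictly more than* 3 s. "Whole body captured" is operationalised as the
body mask being non-empty and touching no image border — a clipped worm is
the only observable failure mode in a single-worm movie. Duration is
`run_length × Δt` over the longest run of consecutive full-body frames; the
comparison uses a 1 ns guard so that binary-float products such as
30 × 0.1 s do not spuriously count as "more than 3 s". Statistics are
computed on that longest run only, not on the whole movie, since a continuous
capture requirement implies one contiguous analysis window.

### Segmentation

Per frame: threshold (Otsu by default; fixed value as override), keep the
largest 8-connected component if it has at least `min_object_px` = 20 pixels
(debris suppression), else record area 0. Raising a fixed threshold can never
increase any frame's area (monotonicity property, tested).

*Known limitation:* per-frame Otsu is unreliable when the bright foreground
occupies a very small fraction of the frame (a classic Otsu failure mode —
the threshold can fall inside the background noise). On the calibrated
synthetic renderings (worm at 1.0 on a 0.0 background) all quantitative
experiments therefore use the fixed mid-intensity threshold 0.5; Otsu remains
the default for real images, where intensities are not calibrated.

### Peak detection

The deviation series is optionally smoothed with a centred moving average
(odd window, default 3 frames; edge windows shrink symmetrically rather than
zero-pad). Candidate extrema are strict local extrema (flat-topped extrema
report their midpoint; series endpoints are never peaks), filtered by
topographic prominence: walking outward from a peak until a higher sample or
the series end, the prominence is the peak height minus the higher of the two
interval minima. The default prominence threshold is 10 % of the
deviation-series interquartile range — a robust scale that tracks the signal
amplitude.

Two conventions complete the definition:

* **Relaxation rule.** Two contractions must be separated by an actual
  relaxation. Adjacent prominent minima with *no prominent maximum between
  them* are merged, keeping the deepest (earliest on ties). This matters for
  quantized (integer-pixel) area signals, where a flat trough bottom can
  produce two exactly equal prominent dips that are one contraction.
* **Upper-peak selection.** Exactly one upper peak — the highest sample —
  between each adjacent pair of lower peaks, plus the highest prominent
  maximum flanking the first/last lower peak where present. Merged by index,
  upper and lower peaks therefore alternate.

Peak *positions* are found on the smoothed signal; peak *values* are read off
the unsmoothed signal at those indices, so smoothing cannot attenuate
reported amplitudes.

The implementation is the definitional enumeration itself (transparent,
O(n·m)); the test suite cross-checks it exactly against an independent
brute-force oracle built on `scipy.signal.find_peaks` over a thousand random
series.

### Metrics and the rate-of-change reading

For each lower peak the amplitude is the deviation value of the nearest
preceding upper peak minus the trough value; a leading trough with no
preceding upper peak is referenced to the window's first sample (discarding a
real contraction at window start would bias short movies). The
contraction-strength statistic is read as the **mean peak-to-trough
excursion**, `R = Σaᵢ / n`. The alternative operator-precedence reading —
dividing that mean once more by n — shrinks with movie length and cannot
represent a per-contraction strength; it remains selectable
(`rate_formula="mean_excursion_per_contraction"`) for sensitivity analysis.
Frequency is `n / (N·Δt)`; the identity `f·N·Δt = n` holds exactly and is
tested. A movie with zero contractions reports frequency 0 and a NaN-flagged
(undefined) rate, not an error.

## Movement-trace assay

Tracks are dark on a light lawn by default (polarity configurable). The image
is binarised toward the trace polarity (Otsu or fixed), components smaller
than `min_component_px` = 25 pixels are removed as dust, and the remaining
foreground count is the trace area (optionally × scale² for mm²). No
area-to-distance conversion is attempted; none is defined for this assay.

## Fluorescence

**Nuclei counting**: difference-of-Gaussians bandpass over a sigma range
(default 1.5–4 px, matched to nuclear puncta of σ ≈ 2.5 px), then local
maxima with a minimum separation (default 5 px) and height ≥ 30 % of the
response maximum. The bundle region is the supplied image; no automatic
bundle delineation is attempted. On noiseless synthetic images the count is
exact and centres are within 1 px for ≤ 40 spots at ≥ 3σ separation (tested);
the threshold is a stand-in for the human "detectable nucleus" criterion, not
a calibration of it.

**Whole-body intensity**: body mask by Otsu/fixed threshold (largest
component) or supplied explicitly; background level is the intensity mode of
the non-body pixels (exact for quantized/noiseless images; a percentile
option serves continuous noisy data); integrated intensity sums
`pixel − background` over the body, clipped at 0. `integrated = mean × area`
holds identically, and a constant offset to the whole image cancels under the
mode background (both tested).

## Statistics

SEM uses the n−1 sample SD over √n; n = 1 reports SEM 0 with a degeneracy
flag. ANOVA is the standard decomposition; zero within-group variance with
non-zero between-group variance reports F = +∞, p = 0. No normality or
homogeneity pre-test gates the analysis; a Levene-based heterogeneity warning
is advisory only.

Tukey-adjusted p values come from the studentized range distribution,
computed here by direct Gauss–Legendre quadrature of the classical double
integral (240 nodes per axis; the u-axis is restricted to the support of the
scaled-χ density, 1 ± 11/√df). Against an independent implementation the
absolute error is ≈ 2 × 10⁻¹⁴ over k ∈ [2, 8], df ∈ [4, 232] — far inside
the 10⁻⁶ documentation tolerance. `tukey_critical_value` inverts the tail by
bisection. With k = 2 the adjusted p reduces exactly to the two-sided pooled
t-test, which is tested.

## Synthetic data: what it emulates, and what it does not

The generator is the package's oracle, not a biomechanical model:

* **Area signal**: `area(t) = baseline − (amplitude/2)(1 − cos 2πft) + noise`.
  A cosine is the simplest waveform with unambiguous analytic troughs: a
  trough is ground truth iff its analytic minimum lies inside the sampled
  window. Defaults (baseline 600 px², 143 frames at 0.07 s ≈ a 10 s movie)
  match the assay's recording geometry.
* **Movies**: all canvas pixels are ranked by distance to a sinusoidal
  centerline; taking the first k ranked pixels yields a connected worm-shaped
  tube of *exactly* k pixels, so the noiseless rendering round-trips through
  segmentation pixel-exactly. Designated frames are translated past the top
  edge to exercise the border-contact QC rule. Additive Gaussian pixel noise
  (default experiments: SD 0.2 on the 0/1 rendering) induces an area-signal
  noise of ≈ 2 px² SD after largest-component segmentation.
* **Tracks**: a persistent-heading random walk reflected at the plate
  borders, rasterized with Bresenham lines (dilated for stroke width); the
  truth is the union pixel count, so self-crossings are counted once.
* **Nuclei**: isotropic Gaussian spots at integer centres with enforced
  minimum separation (rejection sampling; infeasible packings raise).
* **Cohorts**: per-animal endpoint draws, normal truncated at zero (counts
  rounded). Effect presets are calibrated as standardized differences
  (Cohen's d), not raw physiological units — no per-animal source tables
  exist to match, so only the ordering and significance structure of the
  phenotypes is emulated: amplitude deficit of the double mutant at matched
  frequency (d = 5 at days 4–9, converging by day 12), trace area declining
  with age and rising dose-ordered under treatment, nuclei/intensity deficit
  with partial dose-dependent rescue.

Passing the synthetic battery shows the *measurement chain* is correct under
these conditions; it does not validate performance on real micrographs, where
illumination gradients, worm self-overlap, lawn texture and uncalibrated
intensities are the dominant difficulties and none are simulated.

## Analysis configuration of the synthetic experiments

The quantitative benchmark (tests and `scripts/acceptance.py`) runs the
movie chain with the fixed mid-intensity threshold (see the Otsu note above)
and a prominence threshold of 0.5 × IQR — chosen to sit midway between the
area-noise floor (≈ 2 px²) and the smallest amplitude in the study grid
(50 px²), as appropriate when the target of inference is the count of full
contractions rather than micro-fluctuations. Grid: amplitude ∈ {50, 100,
200} px² × frequency ∈ {0.5, 1, 2} Hz, 100 movies per cell in the test suite
(25 in the faster acceptance script), area-signal SNR ≥ 5 throughout
(empirically ≈ 19 at the smallest amplitude). Observed performance: exact
contraction counts in ≥ 99 % of movies per cell and mean amplitude bias
within 5 % (the residual bias is dominated by sampling discretization — at
2 Hz the nearest frame sits up to 0.44 rad off the analytic extremum,
predicting ≈ −3 %).

The genotype-preset analysis pools the strain × day groups of each endpoint
into one 8-level one-way family (the way an all-bars figure is typically
analysed in GraphPad-style workflows) and then reads the same-day pairs from
the Tukey table; per-day two-group analyses remain available by filtering
the cohort table on `day`. The pooled family also keeps the same-day
frequency comparisons inside a single familywise-error budget. Type-I-error
simulations use two-group null cohorts, where the Tukey pair test is exactly
the pooled t-test and the per-pair rejection rate sits at the nominal 0.05
(with more groups, familywise control pushes per-pair rates well below the
nominal level, which would make "fraction of significant pairs" a biased
estimate of the nominal α).

## Numerical conventions and degenerate inputs

* Deviations sum to zero to 1e-9 relative (mean-centring identity).
* Constant frames/images segment to empty masks (area 0) rather than error;
  an empty *body* mask in intensity quantification is an error, since the
  statistic is undefined.
* Ties: flat extrema report their midpoint; equal-depth merged troughs keep
  the earliest; the background mode takes the smallest modal value.
* Determinism: every generator is a pure function of its spec including the
  seed (`numpy.random.default_rng`); pipeline reruns with the same config and
  seed are byte-identical on all CSV outputs, and the run manifest records a
  SHA-256 per output file.
* Blinding is label masking in software: analysis always operates on opaque
  condition codes, and the key is applied only at reporting, so blinded and
  unblinded runs are numerically identical by construction.

## Out of scope

No biomechanical undulation model, no multi-worm tracking or posture
analysis, no mitochondrial-network morphology or sarcomere-striation scoring
(qualitative, human-judged readouts with no computational definition), no
path-length/speed estimation from trace images, and no repeated-measures
modelling across days (day courses are compared as cross-sections).
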