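# Methods

## Scope

`tubequant` measures filamentous structures (DNA nanotubes) in 2D
fluorescence micrographs, summarises their length distribution, and detects
melting transitions in absorbance-vs-temperature tables. Raw micrographs of
the original experiments are not distributed, so the package ships a
synthetic-scene generator with exact ground truth; all quantitative claims
made by the test suite are claims about recovery of that known truth.

## Synthetic micrographs

A scene (`SceneSpec`) is a set of worm-like filaments on a noisy, unevenly
illuminated background.

**Tube model.** Each tube is a piecewise-linear polyline built from 0.5 px
steps; at every step the heading turns by an angle drawn uniformly in
±`curvature` degrees (default 5°/step, giving the gentle curvature seen in
adsorbed nanotubes; 0 gives straight rods). Lengths are drawn from a
configurable law — `exponential(mean)` matching ideal polymerisation
(default mean 3 μm, a typical early-growth average), `fixed`, or an
explicit list. Placement is uniform in position and orientation with
rejection: a polyline leaving the frame is re-placed (same length), so
ground-truth lengths are exact and boundary-clipped tubes never occur. A
tube longer than the frame diagonal warns and then raises after a bounded
number of attempts.

**Rendering.** Centrelines are painted one supersample pixel wide on a 4×
supersampled grid and block-averaged down, so the painted line ends exactly
at the polyline endpoints and anti-aliasing does not bias recovered
lengths. All apparent width comes from convolution with a Gaussian PSF
(`psf_sigma`, default 1 px), appropriate for a filament (~25 nm diameter)
far below the diffraction limit. The background is
`background_level · (1 + illumination_gradient · ramp)` with a linear
corner-to-corner ramp (defaults 400 counts, 20%), emulating uneven
epi-illumination. Noise is Poisson shot noise on signal + background plus
additive Gaussian read noise (default SD 10 counts), then 16-bit
quantisation. With the default amplitude (2000 counts) the tube SNR is
~40; the defaults describe a bright, well-exposed Cy3 field of view.

**Ground truth.** Per tube: sub-pixel polyline vertices, arc length ×
pixel size (exact to 1e−9 μm), and a crossing flag from pairwise polyline
intersection (shapely). Everything is driven by one `numpy` generator
seeded from `SceneSpec.seed`; identical specs are bit-identical.

**Melting curves.** Absorbance is
`baseline + Σᵢ aᵢ · sigmoid((T − cᵢ)/wᵢ)` with one Gaussian draw per
replicate per temperature. The acceptance scenario uses the two-transition
case — centres 40 °C (sticky ends) and 62 °C (tiles), widths 2.5/3.0 °C,
amplitudes 0.06/0.18 AU on a 0.5 AU baseline, replicate noise 0.003 AU
(typical UV-vis photometric noise), 6 replicates on the 1 °C grid from
20 to 90 °C.

**What the generator does not emulate:** out-of-focus haze, photobleaching
during acquisition, camera fixed-pattern noise, surface-adsorption
artefacts (loops, overlapping bundles beyond simple crossings), and
intensity variation along a tube. Passing recovery tests therefore
demonstrate correctness of the measurement chain under a realistic but
idealised imaging model, not robustness to every real-world artefact.

## Segmentation pipeline

Stage order (`run_pipeline`): median background → Gaussian smoothing →
subtraction (clipped at 0) → automatic threshold → binarise → thin →
endpoint rectification → drop short features → drop branched features →
measure.

- **Background**: median filter over a disk of `median_radius` px
  (default 15, sensible when filaments are a few px wide and ~10–20 px
  radii remove them while tracking illumination). Reflective edges.
- **Smoothing**: Gaussian, `gaussian_sigma` default 1 px (suppresses
  single-pixel noise); σ = 0 is the identity.
- **Threshold**: Otsu (default), Yen, or Triangle. For integer images the
  exact integer histogram is used, so Otsu is the exact maximiser of
  between-class variance over grey levels. A constant image raises; an
  image whose above-threshold mean does not exceed 4 robust noise SDs
  (MAD-based, from the unclipped residual) is skipped as an empty field of
  view — without this guard Otsu splits pure background noise into
  thousands of speckles.
- **Thinning**: `skimage.morphology.thin` (unit thickness, topology
  preserving, idempotent).
- **Endpoint rectification** (`extend_ends`, default on): thinning retracts
  a skeleton from the mask boundary by roughly half the filament width,
  biasing lengths short by ~one width per tube. Each endpoint is walked
  forward through the mask — direction estimated from the last five path
  pixels, forward-cone candidate steps, never creating a branch pixel —
  until the mask boundary. This restores the skeleton span to the mask's
  full extent.
- **Filters**: components with < `min_feature_px` (default 3) skeleton
  pixels are flagged `too_short`; components containing any pixel with
  more than two 8-neighbours are flagged `branched` (crossing filaments
  whose individual lengths are unresolvable). Both are excluded from
  measurement but retained in the `FeatureSet` with flags, and counted in
  the per-image parameter log.
- **Length metrics**:
  - `pixel_count` (default): number of skeleton pixels — the simplest
    region-property proxy; underestimates oblique filaments by up to
    ~10% on average over orientation.
  - `geodesic`: step sum along the path, √2 per diagonal move. Exact on
    axis-aligned and 45° paths but biased up to +8.3% near 22.5° (the
    classic chain-code digitisation bias).
  - `calibrated`: the Vossepoel–Smeulders chain-code estimator —
    0.980 per straight step, 1.406 per diagonal step, −0.091 per direction
    change — whose residual orientation bias is below ~1% for straight
    digital lines. Recommended for accuracy studies.

**Measured accuracy** (synthetic straight tubes, SNR ≥ 5, `calibrated`
metric with endpoint rectification): noise-free worst-case per-tube error
≤ 5% for 20–60 px tubes at all orientations tested; with shot noise the
per-tube scatter has SD ≈ 2% and the mean absolute error stays ≤ 5%,
with individual 20 px tubes occasionally off by ~6% (one pixel is 5% at
that scale — the regime is quantisation-limited). The mean over a scene
ensemble is unbiased to within ~2%.

**Conventions**: 0-based row/column coordinates; 8-connectivity for
labelling and branch detection (4 available); per-image thresholds;
16-bit (or 8-bit) grayscale TIFF input only; lengths reported in px and
μm. The diagnostic overlay marks measured skeletons in red on the
contrast-stretched image.

## Length statistics

- **Average length**: unweighted mean of per-replicate means; the error bar
  is the SD across replicate means (ddof 1), 0 by convention and flagged
  for a single replicate. This matches the "SD of the mean over
  experimental replicates" convention of growth-curve figures.
- **Histograms**: half-open bins [lo, hi); values outside the edges raise
  (callers extend the last edge). Length fractions are per-bin summed
  length over total length; default bin width 1 μm from 0.
- **CCDF**: strict survival P(L > x) at each sorted sample point
  (ties collapse); normalisation divides x by the sample mean and leaves
  survival untouched. The semilog fit is ordinary least squares of
  ln(survival) vs x over the [0, 0.99] quantile range of x (the extreme
  tail of an empirical CCDF is dominated by 1/n noise), excluding
  zero-survival points; at least three usable points are required.
- The fitted slope of a mean-normalised exponential sample converges to −1
  (|slope + 1| ≤ 0.05 in ≥ 95% of seeded runs at n = 10⁴, and ≈ ±0.005
  at n = 10⁵). Because short filaments (< 3 px) are unmeasurable and
  crossing filaments are excluded, pipeline-derived samples are mildly
  truncated/thinned relative to the true length law; at the default scene
  density these selection effects shift the recovered mean by a few
  percent.

## Melting analysis

Replicates are averaged pointwise, smoothed with a centred moving average
(default window 3; edges use a shrunken window so no bias is introduced),
and differentiated with centred finite differences (one-sided at the
ends — exact for linear series). Tm candidates are local maxima of dA/dT
(`scipy.signal.find_peaks`) separated by at least `min_separation`
(default 5 °C, well below the ~22 °C gap between the two expected
transitions); the `n_transitions` (default 2) most prominent are reported
in ascending temperature order. Fewer detectable maxima than requested
raises an error stating how many were found. Detection is invariant to
constant baselines and uniform amplitude scaling. On the 1 °C grid,
noiseless recovery is exact to the grid; at 0.003 AU replicate noise with
6 replicates, recovery is within 2 °C.

## Driver and reproducibility

`end_to_end` runs simulate → segment → stats for `n_scenes` scenes (one
scene = one experimental replicate), with per-scene seeds derived from the
top-level seed via `numpy.random.SeedSequence`, and writes a config
snapshot, records and parameter-log CSVs, histogram and CCDF tables, and a
JSON report including ground-truth vs measured comparisons. Repeated runs
with the same config are byte-identical. Any stage failure aborts with the
stage name.

## Problem sizes used in the test suite

Unit tests use 64–128 px frames; the recovery studies use 50 scenes of
256² px with five straight tubes each, and the end-to-end study 6 scenes of
256² px with twelve exponential tubes each — large enough that each scene
holds well-separated filaments at realistic density while the whole suite
stays fast on one CPU.

## Known limitations

- No gap-closing: a filament fragmented by noise is measured as separate
  (or dropped) pieces. No sub-pixel tracing; accuracy is bounded by the
  pixel grid.
- Crossing filaments are discarded wholesale, which under-samples long
  filaments at high surface density; densities should be kept low (the
  report's `n_crossing` quantifies the loss).
- The empty-field guard assumes foreground is sparse and at least ~4 noise
  SDs above background; extremely dim images (SNR ≲ 3) may be skipped.
- Melting analysis detects derivative maxima only; it does not fit a
  thermodynamic model or correct hyperchromicity baselines.
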