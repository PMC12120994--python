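# tubequant

Quantification of DNA-nanotube growth from fluorescence micrographs.

DNA nanotubes self-assembled from double-crossover (DX) tiles are imaged as
bright, gently curved filaments adsorbed on glass. Their length distribution
is the primary readout of the growth mechanism: an ideal
nucleation-and-elongation process yields exponentially distributed lengths,
so the complementary cumulative distribution function (CCDF),
P(L > x), is a straight line in a semilog plot, and after normalising
lengths by the sample mean every exponential CCDF collapses onto the line of
slope −1. Deviations from that line (excess long tubes, missing tail)
point at end-joining or hindered nucleation. A second readout is thermal
stability: nanotube disassembly produces hyperchromic steps in 260 nm
absorbance, and each melting temperature Tm is a maximum of dA/dT —
typically one transition for sticky-end bonds (Tm¹) and one for the tiles
themselves (Tm²).

`tubequant` implements the full measurement chain for these readouts:

- **`tubequant.simulate`** — synthetic micrographs of surface-adsorbed
  nanotubes with exact per-tube ground truth (worm-like polylines, Gaussian
  PSF, uneven illumination, Poisson + read noise), and synthetic
  multi-sigmoid melting curves with replicate noise. Every downstream stage
  is testable against known truth without any raw data.
- **`tubequant.segment`** — micrograph → per-filament lengths:
  disk-median background estimation, Gaussian smoothing, background
  subtraction, automatic thresholding (Otsu / Yen / Triangle), thinning to
  1-px skeletons with endpoint rectification, removal of too-short
  (< 3 px) and branched (intersecting) features, and length measurement
  (pixel count, √2-weighted step sum, or the bias-corrected
  Vossepoel–Smeulders chain-code estimator).
- **`tubequant.stats`** — replicate-aggregated mean length (mean of
  per-replicate means ± SD across replicates), frequency and
  length-fraction histograms, empirical CCDF, mean-normalisation, and the
  semilog straight-line fit.
- **`tubequant.melting`** — replicate averaging, smoothed finite-difference
  derivative, and Tm detection as the largest dA/dT maxima.
- **`tubequant.config` / CLI** — YAML-configured, fully seeded
  simulate → segment → stats driver with reproducible outputs.

## Worked example

Simulate three replicate fields of view per condition, measure them, and
summarise (the same chain the CLI runs):

```python
from tubequant import RunConfig, end_to_end

cfg = RunConfig(
    pixel_size=0.1,                      # um per pixel
    scene={"image_shape": [256, 256], "n_tubes": 12,
           "length_distribution": {"exponential": 3.0}, "curvature": 5.0},
    pipeline={"gaussian_sigma": 0.5, "length_metric": "calibrated"},
    n_scenes=6, seed=7, output_dir="run",
)
report = end_to_end(cfg)
```

`run/report.json` from this exact call:

```json
{
  "ground_truth": {"n_tubes": 72, "n_crossing": 8, "mean_length_um": 2.697},
  "measured": {"n_features": 54, "mean_length_um": 2.514, "error_um": 0.708},
  "relative_mean_error": 0.068,
  "ccdf": {"normalized_slope": -1.144}
}
```

72 tubes were drawn with exponential(3 μm) lengths; 54 non-intersecting,
non-short filaments were measured. The replicate grand mean (2.51 μm)
recovers the ground-truth mean (2.70 μm — itself a finite-sample draw from
the 3 μm law) within 7%; the error bar is the SD across the six replicate
means. The mean-normalised CCDF slope (−1.14 at n = 54) scatters around the
exponential value −1; with 10⁵ lengths it converges to −1.00 (see below).

The same stages are available from the shell:

```sh
tubequant simulate --n-scenes 3 --n-tubes 12 --mean-length 3.0 --out scenes/
tubequant segment --input scenes/ --pixel-size 0.1 --metric calibrated --out seg/
tubequant stats --records seg/records.csv --out stats/
tubequant melt --input melting.csv --n 2 --out tm.csv
```

`tubequant melt` on a synthetic two-transition curve (6 replicates, 1 °C
grid, 20–90 °C) prints:

```
Tm1 = 40.0 C (dA/dT = 0.0060)
Tm2 = 62.0 C (dA/dT = 0.0150)
```

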