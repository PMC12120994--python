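"""Run configuration and the simulate -> segment -> stats driver.

A run is described by a single YAML document; every run writes a config
snapshot sufficient to reproduce it exactly.  All randomness flows from one
top-level seed through per-scene seeds derived with ``numpy``'s
``SeedSequence``, so a repeated run is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import segment, simulate, stats

__all__ = ["RunConfig", "load_config", "save_config", "end_to_end"]

_SCENE_KEYS = {"image_shape", "n_tubes", "length_distribution", "curvature",
               "psf_sigma", "tube_amplitude", "background_level",
               "illumination_gradient", "read_noise_sd", "shot_noise"}
_PIPELINE_KEYS = {"median_radius", "gaussian_sigma", "threshold_method",
                  "min_feature_px", "connectivity", "length_metric"}
_STATS_KEYS = {"bin_width", "fit_quantiles"}
_TOP_KEYS = {"pixel_size", "scene", "pipeline", "stats", "n_scenes", "seed",
             "output_dir", "verbosity", "save_images"}


@dataclass
class RunConfig:
    """Merged scene + pipeline + statistics options for one driver run."""

    pixel_size: float
    scene: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)
    stats: dict = field(default_factory=lambda: {"bin_width": 1.0,
                                                 "fit_quantiles": [0.0, 0.99]})
    n_scenes: int = 3
    seed: int = 0
    output_dir: str = "tubequant_run"
    verbosity: int = 1
    save_images: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_scenes < 1:
            raise ValueError("n_scenes must be >= 1")
        _check_keys(self.scene, _SCENE_KEYS, "scene")
        _check_keys(self.pipeline, _PIPELINE_KEYS, "pipeline")
        _check_keys(self.stats, _STATS_KEYS, "stats")
        self.stats = {"bin_width": 1.0, "fit_quantiles": [0.0, 0.99], **self.stats}

    def scene_spec(self, seed: int) -> simulate.SceneSpec:
        kw = dict(self.scene)
        if "image_shape" in kw:
            kw["image_shape"] = tuple(kw["image_shape"])
        if "length_distribution" in kw and isinstance(kw["length_distribution"], dict):
            kw["length_distribution"] = dict(kw["length_distribution"])
        return simulate.SceneSpec(pixel_size=self.pixel_size, seed=seed, **kw)

    def pipeline_config(self) -> segment.PipelineConfig:
        return segment.PipelineConfig(**self.pipeline)

    def to_dict(self) -> dict:
        return asdict(self)


def _check_keys(d: dict, allowed: set, section: str) -> None:
    if not isinstance(d, dict):
        raise ValueError(f"section {section!r} must be a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {section!r}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Parse and fully validate a YAML run configuration.

    Unknown keys are rejected; ``pixel_size`` is required and named in the
    error when absent.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    if "pixel_size" not in raw:
        raise ValueError("missing required key: pixel_size")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def end_to_end(config: RunConfig) -> dict:
    """Generate scenes, measure them, summarise, and write all outputs.

    Each scene is treated as one experimental replicate.  Returns (and
    writes as JSON) a report comparing ground truth with the measured
    summary.  Any stage failure aborts with the stage name in the error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config_snapshot.yaml")
    child_seeds = [int(s.generate_state(1)[0] % 2**31)
                   for s in np.random.SeedSequence(config.seed).spawn(config.n_scenes)]
    pipe_cfg = config.pipeline_config()

    records, logs, samples, truth_lengths, truth_crossing = [], [], [], [], 0
    n_truth = 0
    for i, scene_seed in enumerate(child_seeds):
        stage = "simulate"
        try:
            spec = config.scene_spec(scene_seed)
            img, truth = simulate.render_scene(spec)
            img.image_id = f"scene_{i:03d}"
            if config.save_images:
                simulate.write_scene(img, truth, out / f"{img.image_id}.tif",
                                     out / f"{img.image_id}_truth.csv")
            stage = "segment"
            result = segment.run_pipeline(img, pipe_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed on scene {i}: {exc}") from exc
        records.extend(result.records)
        logs.append(result.parameter_log)
        lengths = np.array([r.length_um for r in result.records])
        if lengths.size:
            samples.append(stats.LengthSample(lengths, replicate_id=f"scene_{i:03d}"))
        truth_lengths.extend(t.true_length_um for t in truth)
        truth_crossing += sum(t.crosses_another for t in truth)
        n_truth += len(truth)

    import pandas as pd

    rec_df = pd.DataFrame([asdict(r) for r in records],
                          columns=["image_id", "feature_id", "length_px", "length_um"])
    rec_df.to_csv(out / "records.csv", index=False, float_format="%.6f")
    pd.DataFrame(logs).to_csv(out / "parameter_log.csv", index=False)

    report = {
        "n_scenes": config.n_scenes,
        "seed": config.seed,
        "ground_truth": {
            "n_tubes": n_truth,
            "n_crossing": truth_crossing,
            "mean_length_um": float(np.mean(truth_lengths)) if truth_lengths else None,
        },
        "measured": {"n_features": len(records)},
    }
    if samples:
        summary = stats.mean_length(samples)
        report["measured"].update(
            mean_length_um=summary.grand_mean, error_um=summary.error,
            replicate_means_um=list(summary.replicate_means))
        if truth_lengths:
            report["relative_mean_error"] = abs(
                summary.grand_mean - report["ground_truth"]["mean_length_um"]
            ) / report["ground_truth"]["mean_length_um"]
        pooled = stats.LengthSample(np.concatenate([s.lengths for s in samples]))
        bw = float(config.stats["bin_width"])
        edges = np.arange(0, pooled.lengths.max() + 2 * bw, bw)
        hist_c = stats.frequency_histogram(pooled, edges)
        hist_f = stats.length_fraction_histogram(pooled, edges)
        pd.DataFrame({"bin_lo_um": edges[:-1], "bin_hi_um": edges[1:],
                      "count": hist_c.counts,
                      "length_fraction": hist_f.length_fractions}
                     ).to_csv(out / "histograms.csv", index=False,
                              float_format="%.6f")
        ccdf = stats.normalize_ccdf(stats.empirical_ccdf(pooled))
        try:
            stats.fit_semilog_slope(ccdf, tuple(config.stats["fit_quantiles"]))
            report["ccdf"] = {"normalized_slope": ccdf.slope,
                              "intercept": ccdf.intercept}
        except ValueError:
            report["ccdf"] = {"normalized_slope": None, "intercept": None}
        pd.DataFrame({"length_um": ccdf.lengths, "survival": ccdf.survival,
                      "normalized_x": ccdf.normalized_x}
                     ).to_csv(out / "ccdf.csv", index=False, float_format="%.6f")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
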