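"""Growth statistics for filament length samples.

Implements the summaries used to characterise DNA-nanotube growth: mean
length with replicate error bars, count and length-fraction histograms,
and the complementary cumulative distribution function (CCDF) with its
semilog straight-line fit.  An ideal polymerisation process yields
exponentially distributed lengths, whose CCDF is linear in a semilog plot;
after dividing lengths by the sample mean every exponential CCDF collapses
onto the line of slope -1, making the normalised slope a growth-mechanism
diagnostic (end-joining or hindered nucleation bend it away from -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LengthSample",
    "GrowthSummary",
    "HistogramResult",
    "CCDFResult",
    "mean_length",
    "frequency_histogram",
    "length_fraction_histogram",
    "empirical_ccdf",
    "normalize_ccdf",
    "fit_semilog_slope",
    "exponential_reference",
    "records_to_samples",
]


@dataclass
class LengthSample:
    """Per-replicate collection of filament lengths in micrometres."""

    lengths: np.ndarray
    replicate_id: str = ""
    timepoint: object = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1:
            raise ValueError("lengths must be 1D")
        if self.lengths.size and np.any(self.lengths <= 0):
            raise ValueError("all lengths must be > 0")

    @property
    def n(self) -> int:
        return self.lengths.size

    @property
    def mean(self) -> float:
        return float(self.lengths.mean())


@dataclass(frozen=True)
class GrowthSummary:
    """Replicate-aggregated average length.

    ``error`` is the standard deviation across replicate means (0 by
    convention for a single replicate, flagged via ``single_replicate``).
    """

    replicate_means: tuple
    grand_mean: float
    error: float
    n_total: int
    single_replicate: bool = False


@dataclass(frozen=True)
class HistogramResult:
    bin_edges: np.ndarray
    counts: np.ndarray | None = None
    length_fractions: np.ndarray | None = None


@dataclass
class CCDFResult:
    """Empirical survival curve P(length > x) at the sorted sample points."""

    lengths: np.ndarray            # sorted ascending, um
    survival: np.ndarray           # fraction strictly greater than each length
    sample_mean: float
    normalized_x: np.ndarray | None = None
    slope: float | None = None
    intercept: float | None = None
    fit_range: tuple | None = None


def mean_length(samples) -> GrowthSummary:
    """Unweighted mean of per-replicate means; error = SD across replicates."""
    samples = list(samples)
    if not samples:
        raise ValueError("at least one sample is required")
    for s in samples:
        if s.n == 0:
            raise ValueError(f"replicate {s.replicate_id!r} is empty")
    means = np.array([s.mean for s in samples])
    single = len(means) == 1
    error = 0.0 if single else float(means.std(ddof=1))
    return GrowthSummary(replicate_means=tuple(means),
                         grand_mean=float(means.mean()), error=error,
                         n_total=int(sum(s.n for s in samples)),
                         single_replicate=single)


def _bin_indices(values: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be 1D, sorted, with >= 2 entries")
    if values.size and (values.min() < edges[0] or values.max() >= edges[-1]):
        raise ValueError("data outside bin edges; extend the last edge")
    # half-open bins [lo, hi): a value on an interior edge falls in the upper bin
    return np.digitize(values, edges, right=False) - 1


def frequency_histogram(sample: LengthSample, bin_edges) -> HistogramResult:
    """Counts per half-open bin [lo, hi)."""
    idx = _bin_indices(sample.lengths, np.asarray(bin_edges, dtype=float))
    counts = np.bincount(idx, minlength=len(bin_edges) - 1)
    return HistogramResult(bin_edges=np.asarray(bin_edges, float), counts=counts)


def length_fraction_histogram(sample: LengthSample, bin_edges) -> HistogramResult:
    """Share of the total summed length contributed by each bin."""
    if sample.n == 0:
        raise ValueError("length fractions are undefined for an empty sample")
    edges = np.asarray(bin_edges, dtype=float)
    idx = _bin_indices(sample.lengths, edges)
    sums = np.bincount(idx, weights=sample.lengths, minlength=len(edges) - 1)
    return HistogramResult(bin_edges=edges,
                           length_fractions=sums / sample.lengths.sum())


def empirical_ccdf(sample: LengthSample) -> CCDFResult:
    """Survival P(length > x) evaluated at each sorted sample length."""
    if sample.n == 0:
        raise ValueError("CCDF of an empty sample is undefined")
    x = np.sort(sample.lengths)
    # strictly-greater count handles ties correctly
    survival = (x.size - np.searchsorted(x, x, side="right")) / x.size
    return CCDFResult(lengths=x, survival=survival, sample_mean=float(x.mean()))


def normalize_ccdf(ccdf: CCDFResult) -> CCDFResult:
    """Divide the length axis by the sample mean (survival unchanged)."""
    if ccdf.sample_mean <= 0:
        raise ValueError("sample mean must be > 0")
    ccdf.normalized_x = ccdf.lengths / ccdf.sample_mean
    return ccdf


def fit_semilog_slope(ccdf: CCDFResult, fit_range=(0.0, 0.99)) -> tuple[float, float]:
    """Least-squares line through ln(survival) vs length.

    Uses the normalised axis when present, otherwise the raw lengths.
    ``fit_range`` bounds, as quantiles of the x values, exclude the noisy
    extreme tail; zero-survival points are always excluded.
    """
    x_axis = ccdf.normalized_x if ccdf.normalized_x is not None else ccdf.lengths
    lo_q, hi_q = fit_range
    lo, hi = np.quantile(x_axis, [lo_q, hi_q])
    keep = (ccdf.survival > 0) & (x_axis >= lo) & (x_axis <= hi)
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} usable points in the fit range; "
                         "need >= 3")
    slope, intercept = np.polyfit(x_axis[keep], np.log(ccdf.survival[keep]), 1)
    ccdf.slope, ccdf.intercept = float(slope), float(intercept)
    ccdf.fit_range = tuple(fit_range)
    return float(slope), float(intercept)


def exponential_reference(mean: float, x) -> np.ndarray:
    """Model survival exp(-x/mean) for overlaying on an empirical CCDF."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return np.exp(-np.asarray(x, dtype=float) / mean)


def records_to_samples(records_df, length_col="length_um",
                       replicate_col="replicate_id", timepoint_col="timepoint"):
    """Group a records table into LengthSamples per (timepoint, replicate)."""
    import pandas as pd

    df = records_df.copy()
    if replicate_col not in df.columns:
        df[replicate_col] = df.get("image_id", "replicate_1")
    if timepoint_col not in df.columns:
        df[timepoint_col] = 0
    samples = []
    for (tp, rep), grp in df.groupby([timepoint_col, replicate_col], sort=True):
        samples.append(LengthSample(lengths=grp[length_col].to_numpy(),
                                    replicate_id=str(rep), timepoint=tp))
    return samples
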