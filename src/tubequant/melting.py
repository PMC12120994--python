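"""Melting-temperature detection from UV absorbance-vs-temperature data.

DNA nanotube disassembly shows up as hyperchromic steps in the 260 nm
absorbance during a temperature ramp; each melting temperature Tm is the
location of a maximum of dA/dT.  Two-tile-lattice nanotubes show two
transitions: sticky-end disassembly (Tm1) followed by tile melting (Tm2).

Replicate absorbance readings are averaged, optionally smoothed with a
short moving average, differentiated with centred finite differences
(one-sided at the ends), and the requested number of derivative maxima is
returned in ascending temperature order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "MeltingCurve",
    "TmResult",
    "PeakDetectionError",
    "average_replicates",
    "derivative_curve",
    "detect_tm",
    "analyze_melting_curve",
]


class PeakDetectionError(RuntimeError):
    """Raised when fewer derivative maxima are found than requested."""


@dataclass
class MeltingCurve:
    """Temperatures (degC, strictly ascending) with per-replicate absorbance
    (AU), shape (n_temperatures, n_replicates)."""

    temperatures: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim == 1:
            self.absorbance = self.absorbance[:, None]
        if self.temperatures.ndim != 1 or self.absorbance.ndim != 2:
            raise ValueError("temperatures must be 1D and absorbance 2D")
        if self.absorbance.shape[0] != self.temperatures.size:
            raise ValueError("replicate rows must match the temperature grid")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("replicate rows are incomplete (non-finite values)")

    @property
    def n_replicates(self) -> int:
        return self.absorbance.shape[1]


@dataclass(frozen=True)
class TmResult:
    """Detected transitions, ordered by temperature: (Tm degC, peak dA/dT)."""

    transitions: tuple  # of (tm_C, peak_height)

    @property
    def temperatures(self) -> tuple:
        return tuple(t for t, _ in self.transitions)


def average_replicates(curve: MeltingCurve) -> np.ndarray:
    """Pointwise mean absorbance across replicates."""
    return curve.absorbance.mean(axis=1)


def derivative_curve(series, smoothing_window: int = 3,
                     temperatures=None) -> np.ndarray:
    """dA/dT by centred differences after moving-average smoothing.

    ``smoothing_window`` points (<=1 disables smoothing; edges use a
    shrunken window).  Without an explicit temperature grid a uniform
    1 degC spacing is assumed.  Endpoints use one-sided differences.
    """
    a = np.asarray(series, dtype=float)
    if a.ndim != 1 or a.size < 3:
        raise ValueError("need a 1D series with >= 3 points")
    if smoothing_window > 1:
        kernel = np.ones(int(smoothing_window)) / int(smoothing_window)
        # normalised convolution keeps edge values unbiased
        num = np.convolve(a, kernel, mode="same")
        den = np.convolve(np.ones_like(a), kernel, mode="same")
        a = num / den
    if temperatures is None:
        return np.gradient(a)
    T = np.asarray(temperatures, dtype=float)
    if T.size != a.size:
        raise ValueError("temperature grid must match the series")
    return np.gradient(a, T)


def detect_tm(derivative, temperatures, n_transitions: int = 2,
              min_separation: float = 5.0) -> TmResult:
    """The ``n_transitions`` largest local maxima of dA/dT.

    Maxima closer than ``min_separation`` (degC) are merged into the higher
    one.  Raises :class:`PeakDetectionError` (reporting how many maxima
    were found) when the curve has fewer usable peaks than requested.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    d = np.asarray(derivative, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if d.size != T.size:
        raise ValueError("derivative and temperature grids must match")
    step = float(np.median(np.diff(T))) if T.size > 1 else 1.0
    distance = max(1, int(round(min_separation / step)))
    peaks, props = find_peaks(d, distance=distance, prominence=0.0)
    if peaks.size < n_transitions:
        raise PeakDetectionError(
            f"found {peaks.size} local maxima, {n_transitions} requested")
    order = np.argsort(props["prominences"])[::-1][:n_transitions]
    chosen = np.sort(peaks[order])
    return TmResult(transitions=tuple((float(T[i]), float(d[i])) for i in chosen))


def analyze_melting_curve(curve: MeltingCurve, n_transitions: int = 2,
                          smoothing_window: int = 3,
                          min_separation: float = 5.0) -> TmResult:
    """Replicate-average -> smooth -> differentiate -> pick Tm peaks."""
    mean = average_replicates(curve)
    deriv = derivative_curve(mean, smoothing_window, curve.temperatures)
    return detect_tm(deriv, curve.temperatures, n_transitions, min_separation)
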