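"""Synthetic fluorescence micrographs of surface-adsorbed DNA nanotubes.

Real micrographs of Cy3-labelled nanotubes show bright, gently curved,
diffraction-blurred filaments on an unevenly illuminated noisy background.
This module renders such scenes with exact per-tube ground truth (polyline
vertices, arc length, crossing flag) so that the full measurement pipeline
can be validated without any raw data.  It also synthesises UV-absorbance
melting curves as sums of sigmoidal transitions with replicate noise.

Tubes are modelled as piecewise-linear worm-like polylines: each step turns
by an angle drawn uniformly in ±``curvature`` degrees.  Polylines are drawn
on a 4x supersampled grid and block-averaged down to avoid aliasing bias in
recovered lengths.  Tubes whose polyline would leave the frame are re-placed
rather than clipped, so the recorded ground-truth length is always exact.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import scipy.ndimage as ndi
import tifffile
from shapely.geometry import LineString

from .melting import MeltingCurve
from .segment import Micrograph

__all__ = [
    "SceneSpec",
    "TubeTruth",
    "GroundTruth",
    "sample_lengths",
    "render_scene",
    "make_melting_curve",
    "write_scene",
    "write_melting_csv",
    "read_melting_csv",
]

_SUPERSAMPLE = 4
_STEP_PX = 0.5  # polyline step length in base-resolution pixels
_MAX_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic micrograph.

    Lengths and pixel size are in micrometres; intensities in camera counts
    of the 16-bit range; ``curvature`` is the maximum bend per polyline step
    in degrees (0 gives straight tubes); ``illumination_gradient`` is the
    fractional background change corner-to-corner.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    n_tubes: int = 20
    length_distribution: dict | tuple | list = field(
        default_factory=lambda: {"exponential": 3.0}
    )
    curvature: float = 5.0
    psf_sigma: float = 1.0
    tube_amplitude: float = 2000.0
    background_level: float = 400.0
    illumination_gradient: float = 0.2
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be 2D with sides >= 8")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be >= 0")
        if self.psf_sigma <= 0 or self.tube_amplitude <= 0 or self.background_level <= 0:
            raise ValueError("psf_sigma, tube_amplitude, background_level must be > 0")
        for name in ("curvature", "illumination_gradient", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["image_shape"] = list(self.image_shape)
        return d


@dataclass(frozen=True)
class TubeTruth:
    """Ground truth for one rendered tube."""

    tube_id: int
    vertices: np.ndarray  # (n, 2) sub-pixel (row, col) coordinates
    true_length_um: float
    crosses_another: bool


GroundTruth = list  # list[TubeTruth]


def _normalise_length_spec(spec) -> tuple[str, object]:
    """Accept {'exponential': m} / {'fixed': v} / {'values': [...]} or
    ('exponential', m) tuples or a bare list of values."""
    if isinstance(spec, dict):
        if len(spec) != 1:
            raise ValueError("length distribution dict must have exactly one key")
        kind, param = next(iter(spec.items()))
    elif isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], str):
        kind, param = spec
    elif isinstance(spec, (list, np.ndarray)):
        kind, param = "values", list(spec)
    else:
        raise ValueError(f"unrecognised length distribution spec: {spec!r}")
    kind = kind.lower()
    if kind not in ("exponential", "fixed", "values"):
        raise ValueError(f"unknown length distribution kind: {kind!r}")
    return kind, param


def sample_lengths(distribution, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` tube lengths (um) from a distribution specification.

    ``distribution`` is ``{"exponential": mean}``, ``{"fixed": value}``,
    ``{"values": [...]}`` (cycled if shorter than ``n``) or the equivalent
    tuple/list forms.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind, param = _normalise_length_spec(distribution)
    if kind == "exponential":
        mean = float(param)
        if mean <= 0:
            raise ValueError("exponential mean must be > 0")
        return rng.exponential(mean, size=n)
    if kind == "fixed":
        value = float(param)
        if value <= 0:
            raise ValueError("fixed length must be > 0")
        return np.full(n, value)
    values = np.asarray(param, dtype=float)
    if values.size == 0 and n > 0:
        raise ValueError("empty value list")
    if np.any(values <= 0):
        raise ValueError("all listed lengths must be > 0")
    reps = int(np.ceil(n / max(values.size, 1))) if n else 0
    return np.tile(values, reps)[:n] if n else np.empty(0)


def _make_polyline(rng, length_px: float, shape, curvature_deg: float) -> np.ndarray | None:
    """One placement attempt; returns (n,2) vertices or None if out of frame."""
    n_steps = max(1, int(np.ceil(length_px / _STEP_PX)))
    step = length_px / n_steps
    start = rng.uniform([0, 0], [shape[0] - 1, shape[1] - 1])
    heading = rng.uniform(0, 2 * np.pi)
    bends = rng.uniform(-np.deg2rad(curvature_deg), np.deg2rad(curvature_deg), n_steps)
    headings = heading + np.concatenate([[0.0], np.cumsum(bends[1:])])
    steps = step * np.column_stack([np.sin(headings), np.cos(headings)])
    verts = np.vstack([start, start + np.cumsum(steps, axis=0)])
    if (verts[:, 0].min() < 0 or verts[:, 0].max() > shape[0] - 1
            or verts[:, 1].min() < 0 or verts[:, 1].max() > shape[1] - 1):
        return None
    return verts


def _arc_length(vertices: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(vertices, axis=0), axis=1).sum())


def _rasterise(polylines, shape) -> np.ndarray:
    """Render unit-amplitude centrelines on a supersampled grid, then
    block-average down to base resolution (anti-aliased).

    The painted line is one supersample pixel wide, so the rendered tube
    ends exactly at the polyline endpoints (no cap overhang); all apparent
    width comes from the PSF, as for a sub-resolution filament.  The
    block mean is scaled so a line crossing a base pixel deposits ~1.
    """
    ss = _SUPERSAMPLE
    canvas = np.zeros((shape[0] * ss, shape[1] * ss), dtype=bool)
    for verts in polylines:
        seg_len = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        total = seg_len.sum()
        n_pts = max(2, int(np.ceil(total * ss / 0.25)))
        t = np.linspace(0, 1, n_pts)
        # arc-length parametrised sampling of the polyline
        cum = np.concatenate([[0], np.cumsum(seg_len)]) / max(total, 1e-12)
        rows = np.interp(t, cum, verts[:, 0]) * ss
        cols = np.interp(t, cum, verts[:, 1]) * ss
        r = np.clip(np.rint(rows).astype(int), 0, canvas.shape[0] - 1)
        c = np.clip(np.rint(cols).astype(int), 0, canvas.shape[1] - 1)
        canvas[r, c] = True
    blocks = canvas.reshape(shape[0], ss, shape[1], ss)
    return blocks.mean(axis=(1, 3)) * ss


def _crossing_flags(polylines) -> list[bool]:
    lines = [LineString(np.fliplr(v)) for v in polylines]  # (x, y) order
    flags = [False] * len(lines)
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            if lines[i].intersects(lines[j]):
                flags[i] = flags[j] = True
    return flags


def render_scene(spec: SceneSpec) -> tuple[Micrograph, GroundTruth]:
    """Render a synthetic micrograph and its exact ground truth.

    Tubes are placed with uniform random position and orientation and
    re-drawn (same length) if any vertex would fall outside the frame; a
    tube longer than the image diagonal can never fit and raises after the
    bounded retry budget.  The rendered polyline is convolved with a
    Gaussian PSF, added to a linearly tilted background, and corrupted with
    Poisson shot noise and Gaussian read noise before 16-bit quantisation.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    lengths_um = sample_lengths(spec.length_distribution, spec.n_tubes, rng)
    diagonal_px = float(np.hypot(*shape))

    polylines = []
    for L_um in lengths_um:
        L_px = L_um / spec.pixel_size
        if L_px > diagonal_px:
            warnings.warn(
                f"tube of {L_um:.2f} um ({L_px:.0f} px) exceeds the image diagonal; "
                "placement will fail", stacklevel=2)
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            verts = _make_polyline(rng, L_px, shape, spec.curvature)
            if verts is not None:
                polylines.append(verts)
                break
        else:
            raise RuntimeError(
                f"could not place a {L_um:.2f} um tube within "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts")

    tube_image = _rasterise(polylines, shape)
    signal = ndi.gaussian_filter(tube_image * spec.tube_amplitude, spec.psf_sigma,
                                 mode="reflect")
    rr, cc = np.meshgrid(np.linspace(0, 1, shape[0]), np.linspace(0, 1, shape[1]),
                         indexing="ij")
    background = spec.background_level * (1 + spec.illumination_gradient * (rr + cc) / 2)
    expected = signal + background
    img = rng.poisson(expected).astype(float) if spec.shot_noise else expected.copy()
    if spec.read_noise_sd > 0:
        img += rng.normal(0, spec.read_noise_sd, shape)
    img = np.clip(np.rint(img), 0, 2**16 - 1).astype(np.uint16)

    flags = _crossing_flags(polylines)
    truth = [
        TubeTruth(i, verts, _arc_length(verts) * spec.pixel_size, flags[i])
        for i, verts in enumerate(polylines)
    ]
    micrograph = Micrograph(intensity=img, bit_depth=16, pixel_size=spec.pixel_size,
                            image_id=f"synthetic_seed{spec.seed}")
    return micrograph, truth


def make_melting_curve(transition_centers, transition_widths, amplitudes,
                       baseline=0.5, noise_sd=0.0, n_replicates=6,
                       temperature_grid=None, seed=None) -> MeltingCurve:
    """Synthesise an absorbance-vs-temperature table.

    Absorbance is ``baseline + sum_i amplitude_i * sigmoid((T - center_i) /
    width_i)`` with one Gaussian noise draw per replicate per temperature,
    emulating repeated 260 nm readings on a 1 degC ramp.
    """
    centers = np.asarray(transition_centers, dtype=float)
    widths = np.asarray(transition_widths, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if not (centers.size == widths.size == amps.size):
        raise ValueError("centers, widths and amplitudes must have equal length")
    if np.any(widths <= 0):
        raise ValueError("transition widths must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    T = (np.arange(20.0, 91.0) if temperature_grid is None
         else np.asarray(temperature_grid, dtype=float))
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly ascending")
    mean = baseline * np.ones_like(T)
    for c, w, a in zip(centers, widths, amps):
        mean = mean + a / (1 + np.exp(-(T - c) / w))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    absorbance = mean[:, None] + rng.normal(0, noise_sd, (T.size, n_replicates))
    return MeltingCurve(temperatures=T, absorbance=absorbance)


# ---------------------------------------------------------------------------
# plain-text writers

def write_scene(micrograph: Micrograph, truth: GroundTruth, tif_path, truth_path) -> None:
    """Write the image as 16-bit TIFF and the ground truth as CSV."""
    tifffile.imwrite(str(tif_path), micrograph.intensity)
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tube_id", "vertices_json", "true_length_um", "crosses_another"])
        for t in truth:
            w.writerow([t.tube_id, json.dumps(np.round(t.vertices, 4).tolist()),
                        f"{t.true_length_um:.6f}", int(t.crosses_another)])


def write_melting_csv(curve: MeltingCurve, path) -> None:
    """Column 1 temperature_C, columns 2..n+1 replicate absorbances."""
    n_rep = curve.absorbance.shape[1]
    header = ["temperature_C"] + [f"replicate_{i + 1}" for i in range(n_rep)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for T, row in zip(curve.temperatures, curve.absorbance):
            w.writerow([f"{T:g}"] + [f"{a:.6f}" for a in row])


def read_melting_csv(path) -> MeltingCurve:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    return MeltingCurve(temperatures=data[:, 0], absorbance=data[:, 1:])
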