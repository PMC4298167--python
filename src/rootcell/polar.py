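"""Polar resampling and 1D peak-based cell counting.

Cells are counted on intensity profiles taken from the polar-transformed
image (rows = radius, columns = angle, center at the top): a radial line
crosses one bright periclinal wall per layer boundary, an angular line at
a cell-file radius crosses one bright anticlinal wall per cell.  Peaks
are local maxima filtered by prominence ("noise tolerance"): the height
of a maximum above the higher of the two bounding minima reachable
without crossing a larger value.

Counting a cell file over a partial angular span extrapolates the full
count as round-half-up(raw / coverage), mirroring the supervised tool's
behaviour when the user traces a line over only part of a damaged image.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .preprocess import CalibratedImage, PipelineParams


@dataclasses.dataclass
class PolarImage:
    """Image resampled on a (radius, angle) grid about ``center``.

    Row r is radius r in pixels (row 0 = the center); column a is angle
    a * 2*pi/n_angles, with angle 0 along +col and increasing
    counter-clockwise.  Columns are periodic.
    """

    pixels: np.ndarray
    center: tuple
    n_angles: int

    @property
    def r_max(self) -> int:
        return self.pixels.shape[0] - 1

    @property
    def angular_step(self) -> float:
        return 2 * np.pi / self.n_angles


@dataclasses.dataclass
class CountProfile:
    """One counting line and its result."""

    orientation: str               # "radial" or "angular"
    fixed_coord: float             # angle index (radial) or radius (angular)
    span: tuple                    # (start, end) along the line, in samples
    profile: np.ndarray
    maxima: np.ndarray             # positions along the line, ascending
    raw_count: int
    coverage: float
    extrapolated_count: int
    noise_tolerance: float


def round_half_up_int(x: float) -> int:
    return int(np.floor(x + 0.5))


def polar_transform(img, center, n_angles: int, r_max: int) -> PolarImage:
    """Bilinear Cartesian-to-polar resampling; outside samples are 0."""
    px = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    cy, cx = float(center[0]), float(center[1])
    h, w = px.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"center {center} lies outside the {h}x{w} image")
    if r_max < 1 or n_angles < 8:
        raise ValueError("need r_max >= 1 and n_angles >= 8")
    r = np.arange(r_max + 1, dtype=np.float64)[:, None]
    theta = np.arange(n_angles, dtype=np.float64)[None, :] * (2 * np.pi / n_angles)
    rowc = cy - r * np.sin(theta)
    colc = cx + r * np.cos(theta)
    out = ndi.map_coordinates(px.astype(np.float64), [rowc, colc],
                              order=1, mode="constant", cval=0.0)
    return PolarImage(out.astype(np.float32), (cy, cx), n_angles)


def find_profile_maxima(profile, noise_tolerance: float, periodic: bool = False) -> np.ndarray:
    """Positions of local maxima with prominence >= noise_tolerance.

    Plateaus report their center sample (rounded down for even plateaus).
    With ``periodic=True`` the profile is treated circularly and a maximum
    spanning the seam is counted once.
    """
    x = np.asarray(profile, dtype=np.float64)
    if x.size < 3:
        raise ValueError("profile must have at least 3 samples")
    if not periodic:
        peaks, _ = find_peaks(x, prominence=noise_tolerance)
        return peaks.astype(np.int64)
    if np.all(x == x[0]):
        return np.array([], dtype=np.int64)
    # cut the circle at (one of) the global minima: every circular
    # prominence path through the cut passes the global minimum, so linear
    # prominences on the rotated profile equal the circular ones
    shift = int(np.argmin(x))
    y = np.roll(x, -shift)
    y = np.concatenate([y, y[:1]])
    peaks, _ = find_peaks(y, prominence=noise_tolerance)
    pos = np.sort((peaks + shift) % x.size)
    return pos.astype(np.int64)


def _as_per_angle(value, n_angles: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(n_angles, float(arr))
    if arr.shape != (n_angles,):
        raise ValueError("per-angle radius array must have length n_angles")
    return arr


def _snap_to_clear_column(polar: PolarImage, col: int, inner, outer,
                          window: int, tol: float, margin: int) -> int:
    """Shift a radial line to the nearby angle resolving the most walls.

    Emulates the supervised user, who draws counting lines where the
    periclinal walls are distinct rather than along anticlinal walls
    (which merge neighboring peaks).  Among the +-window candidate
    columns the one with the most prominent maxima on the span wins;
    ties break on the dimmest profile, then on the lowest column index.
    Deterministic.
    """
    n = polar.n_angles
    best, best_key = col, None
    for d in range(-window, window + 1):
        c = (col + d) % n
        i0 = max(0, round_half_up_int(inner[c]))
        i1 = min(polar.r_max, round_half_up_int(outer[c]))
        if i1 <= i0:
            continue
        lo, hi = max(0, i0 - margin), i1
        seg = np.asarray(polar.pixels[lo:hi + 1, c], dtype=np.float64)
        pk = find_profile_maxima(seg, tol) + lo
        count = int(((pk >= i0 - 1) & (pk <= i1)).sum())
        key = (-count, float(polar.pixels[i0:i1 + 1, c].mean()), c)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def count_layers(polar: PolarImage, inner_r, outer_r, params: PipelineParams):
    """Count cortex cell layers on radial lines.

    ``inner_r`` (stele boundary) and ``outer_r`` (inner edge of the
    sclerenchyma band) may be scalars or per-angle arrays.  Lines are
    placed at evenly spaced angles with a seeded offset, each snapped to
    the nearby column resolving the most walls.  The profile runs from
    just inside the stele boundary up to the band inner edge, so each
    detected maximum is the inner periclinal wall of one counted layer
    (the band itself bounds the outermost layer and registers no
    maximum): per-line layer count = number of maxima (+ configurable
    offset).  Returns the mean count and the per-line profiles; lines
    with no detected maxima are excluded.
    """
    n = params.n_layer_lines
    inner = _as_per_angle(inner_r, polar.n_angles)
    outer = _as_per_angle(outer_r, polar.n_angles)
    rng = np.random.default_rng(params.rng_seed)
    offset = int(rng.integers(0, polar.n_angles))
    window = max(3, polar.n_angles // 48)
    margin = 4
    profiles, counts = [], []
    for k in range(n):
        col = (offset + round_half_up_int(k * polar.n_angles / n)) % polar.n_angles
        col = _snap_to_clear_column(polar, col, inner, outer, window,
                                    params.noise_tolerance, margin)
        i0 = round_half_up_int(inner[col])
        i1 = round_half_up_int(outer[col])
        if not i0 < i1:
            raise ValueError("inner_r must be smaller than outer_r on every line")
        lo = max(0, i0 - margin)
        hi = min(polar.r_max, i1)
        seg = np.asarray(polar.pixels[lo:hi + 1, col], dtype=np.float64)
        pk = find_profile_maxima(seg, params.noise_tolerance) + lo
        pk = pk[(pk >= i0 - 1) & (pk <= i1)]
        raw = int(pk.size)
        prof = CountProfile(
            orientation="radial", fixed_coord=float(col), span=(i0, i1),
            profile=seg, maxima=pk, raw_count=raw, coverage=1.0,
            extrapolated_count=raw, noise_tolerance=params.noise_tolerance,
        )
        profiles.append(prof)
        if raw > 0:
            counts.append(max(0, raw + params.layer_count_offset))
    if not counts:
        raise ValueError("no cell-layer maxima detected on any radial line")
    return float(np.mean(counts)), profiles


def count_cells_in_file(polar: PolarImage, file_radius: float, span_fraction: float,
                        params: PipelineParams) -> CountProfile:
    """Count the cells of one cell file on an angular line.

    A full circle (``span_fraction = 1``) counts periodically, each
    anticlinal-wall maximum once; a partial span counts non-periodically
    and extrapolates by round-half-up(raw / coverage).
    """
    if not (0 < span_fraction <= 1):
        raise ValueError("span_fraction must lie in (0, 1]")
    r = round_half_up_int(file_radius)
    if not (1 <= r <= polar.r_max):
        raise ValueError(f"file radius {file_radius} outside [1, {polar.r_max}]")
    row = np.asarray(polar.pixels[r, :], dtype=np.float64)
    if span_fraction == 1:
        pk = find_profile_maxima(row, params.noise_tolerance, periodic=True)
        raw = int(pk.size)
        return CountProfile("angular", float(r), (0, polar.n_angles - 1), row, pk,
                            raw, 1.0, raw, params.noise_tolerance)
    n_cols = max(3, round_half_up_int(span_fraction * polar.n_angles))
    seg = row[:n_cols]
    pk = find_profile_maxima(seg, params.noise_tolerance, periodic=False)
    raw = int(pk.size)
    extrap = round_half_up_int(raw / span_fraction)
    return CountProfile("angular", float(r), (0, n_cols - 1), seg, pk,
                        raw, span_fraction, extrap, params.noise_tolerance)


def place_file_radii(layer_profiles, n_files: int, override=None, outer_bound=None):
    """Derive cell-file radii from the periclinal walls of the layer lines.

    Candidate radii are midpoints between consecutive wall maxima
    (augmented by ``outer_bound``, the sclerenchyma inner edge, which
    bounds the outermost file), averaged over the radial lines that agree
    on the modal wall count, ordered outermost first; the first
    ``n_files`` are returned.  Explicit ``override`` radii are returned
    as-is.  Returns (radii, warnings).
    """
    if override is not None:
        return [float(r) for r in override], []
    counts = [p.raw_count for p in layer_profiles if p.raw_count > 0]
    if not counts:
        return [], ["no periclinal walls detected; cannot place cell files"]
    vals, freq = np.unique(counts, return_counts=True)
    modal = int(vals[np.argmax(freq + vals / (vals.max() + 1.0))])  # tie -> richer line
    walls = np.mean(
        [np.sort(p.maxima) for p in layer_profiles if p.raw_count == modal], axis=0
    )
    walls = list(walls)
    if outer_bound is not None and walls and outer_bound > walls[-1] + 1:
        walls.append(float(outer_bound))
    mids = [(walls[i] + walls[i + 1]) / 2.0 for i in range(len(walls) - 1)]
    mids = sorted(mids, reverse=True)
    warnings = []
    if len(mids) < n_files:
        warnings.append(
            f"only {len(mids)} cell-file radii available (requested {n_files})"
        )
    return [float(m) for m in mids[:n_files]], warnings
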