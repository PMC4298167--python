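"""Image loading and the fixed preprocessing chain.

Every analysis starts from the same deterministic chain applied to a
single-root transverse-section micrograph: grayscale conversion (for RGB
input), Gaussian smoothing, percentile contrast stretching, automatic (or
overridden) thresholding, and morphological smoothing of the resulting
selection.  Fluorescence images have bright cell walls on a dark
background; bright-field images are inverted at the thresholding step so
that foreground always means "cell wall".

All images are 8-bit internally.  16-bit input is min-max rescaled on
load.  The rounding convention throughout the package is round half up.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage as ndi
from skimage.morphology import disk

MODALITIES = ("fluorescence", "brightfield")
UNIT_MODES = ("pixel", "calibrated")

#: smallest accepted image side, in pixels
MIN_SIDE = 64


def round_half_up(x):
    """Round to nearest integer, ties away from zero-point-five upward."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclasses.dataclass
class PipelineParams:
    """Tunable parameters of the whole pipeline.

    The defaults reproduce the tool's standard operating point: stele oval
    sized so that root area / stele area = 4, cell layers averaged over 3
    radial lines, 6 cell files counted, peak prominence ("noise tolerance")
    of 20 intensity levels on an 8-bit scale.
    """

    verbose: bool = True
    modality: str = "fluorescence"
    unit_mode: str = "pixel"
    stele_proportion: float = 4.0
    n_layer_lines: int = 3
    n_cell_files: int = 6
    noise_tolerance: float = 20.0
    gaussian_sigma: float = 1.5
    contrast_saturation: float = 0.0035
    threshold_override: int | None = None
    smoothing_radius: int = 3
    manual_nm: int | None = None
    manual_ncm: int | None = None
    rng_seed: int = 0
    # segmentation details (exposed, see docs/methods.md)
    min_cmx_area: int = 80
    cmx_circularity: float = 0.5
    scler_search_fraction: float = 0.35
    scler_min_band_px: int = 3
    angular_median_width: int = 9
    # counting details
    n_angles: int = 720
    layer_count_offset: int = 0
    cell_file_span: float = 1.0
    file_radii: list | None = None
    calibration: float | None = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.unit_mode not in UNIT_MODES:
            raise ValueError(f"unit_mode must be one of {UNIT_MODES}, got {self.unit_mode!r}")
        if not self.stele_proportion > 1:
            raise ValueError("stele_proportion must be > 1 (stele strictly inside root)")
        if self.n_layer_lines < 1 or self.n_cell_files < 1:
            raise ValueError("n_layer_lines and n_cell_files must be >= 1")
        if self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if not (0 <= self.contrast_saturation < 0.5):
            raise ValueError("contrast_saturation must lie in [0, 0.5)")
        if self.threshold_override is not None and not (0 <= self.threshold_override <= 255):
            raise ValueError("threshold_override must lie in [0, 255]")
        if self.smoothing_radius < 0:
            raise ValueError("smoothing_radius must be >= 0")
        if self.calibration is not None and not (np.isfinite(self.calibration) and self.calibration > 0):
            raise ValueError("calibration must be a positive finite scalar (um/px)")

    def replace(self, **kw) -> "PipelineParams":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class CalibratedImage:
    """A single-channel 8-bit micrograph with acquisition metadata.

    ``calibration`` is the pixel size in micrometres per pixel, when known.
    """

    pixels: np.ndarray
    modality: str = "fluorescence"
    calibration: float | None = None
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("CalibratedImage expects a 2D intensity array")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer) or px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must be integers in [0, 255]")
            px = px.astype(np.uint8)
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(
                f"image {self.source_id!r} is {px.shape[0]}x{px.shape[1]}; "
                f"at least {MIN_SIDE}x{MIN_SIDE} required"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.calibration is not None and not (np.isfinite(self.calibration) and self.calibration > 0):
            raise ValueError("calibration must be a positive finite scalar (um/px)")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        return CalibratedImage(pixels, self.modality, self.calibration, self.source_id)


def to_grayscale(rgb_pixels: np.ndarray) -> np.ndarray:
    """Convert an RGB array to 8-bit grayscale with standard luminance weights.

    Uses 0.299 R + 0.587 G + 0.114 B, rounded half up.
    """
    rgb = np.asarray(rgb_pixels, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(round_half_up(gray), 0, 255).astype(np.uint8)


def load_image(path, params: PipelineParams) -> CalibratedImage:
    """Load a TIFF/PNG/JPEG raster as a CalibratedImage.

    RGB input is converted via :func:`to_grayscale`; 16-bit grayscale is
    linearly min-max rescaled onto [0, 255].
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if raw.shape[2] == 4:  # drop alpha
            raw = raw[..., :3]
        if raw.dtype == np.uint16:
            raw = (raw // 257).astype(np.uint8)
        gray = to_grayscale(raw)
    elif raw.ndim == 2:
        if raw.dtype == np.uint8:
            gray = raw
        elif np.issubdtype(raw.dtype, np.integer):
            lo, hi = int(raw.min()), int(raw.max())
            if hi == lo:
                gray = np.zeros(raw.shape, dtype=np.uint8)
            else:
                gray = round_half_up((raw.astype(np.float64) - lo) * 255.0 / (hi - lo))
                gray = np.clip(gray, 0, 255).astype(np.uint8)
        else:
            raise IOError(f"unsupported pixel type {raw.dtype} in {path}")
    else:
        raise IOError(f"unsupported image shape {raw.shape} in {path}")
    return CalibratedImage(
        gray, modality=params.modality, calibration=params.calibration, source_id=path.name
    )


def gaussian_smooth(img, sigma: float):
    """Gaussian filter with edge replication, requantized to 8-bit.

    Accepts a CalibratedImage or a bare uint8 array and returns the same
    kind.  ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    px = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    if sigma == 0:
        out = px.copy()
    else:
        sm = ndi.gaussian_filter(px.astype(np.float64), sigma, mode="nearest")
        out = np.clip(round_half_up(sm), 0, 255).astype(np.uint8)
    return img.with_pixels(out) if isinstance(img, CalibratedImage) else out


def enhance_contrast(img, saturation: float):
    """Linear percentile stretch saturating ``saturation`` per tail.

    The ``saturation`` quantile maps to 0 and the ``1 - saturation``
    quantile to 255; values outside clip.  Constant images are returned
    unchanged.
    """
    if not (0 <= saturation < 0.5):
        raise ValueError("saturation must lie in [0, 0.5)")
    px = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    lo = float(np.percentile(px, saturation * 100.0))
    hi = float(np.percentile(px, (1.0 - saturation) * 100.0))
    if hi <= lo:
        out = px.copy()
    else:
        stretched = (px.astype(np.float64) - lo) * 255.0 / (hi - lo)
        out = np.clip(round_half_up(stretched), 0, 255).astype(np.uint8)
    return img.with_pixels(out) if isinstance(img, CalibratedImage) else out


def otsu_threshold(pixels: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold over all 256 levels.

    Maximizes the between-class variance of the split {v <= t} / {v > t};
    foreground is everything strictly above t.  Ties (e.g. the empty gap
    of a well-separated bimodal histogram) resolve to the middle of the
    maximizing plateau.  For a constant image the constant level is
    returned (empty foreground).
    """
    px = np.asarray(pixels)
    hist = np.bincount(px.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    if total == 0:
        raise ValueError("empty pixel set")
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    csum = np.cumsum(hist * np.arange(256))[:-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return int(px.ravel()[0])
    mu0 = np.where(valid, csum / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (csum[-1] + hist[255] * 255 - csum) / np.where(w1 > 0, w1, 1), 0.0)
    var = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -1.0)
    ties = np.flatnonzero(var == var.max())
    return int(ties[len(ties) // 2])


def binarize(img, threshold_override: int | None = None, modality: str | None = None) -> np.ndarray:
    """Threshold an image into a boolean foreground (cell wall) mask.

    Foreground = pixels strictly above the threshold.  Bright-field images
    are inverted (255 - v) before thresholding so that walls are always
    foreground.  Without an override the threshold is chosen by
    :func:`otsu_threshold` on the (possibly inverted) image.
    """
    if isinstance(img, CalibratedImage):
        px = img.pixels
        modality = modality or img.modality
    else:
        px = np.asarray(img, dtype=np.uint8)
        modality = modality or "fluorescence"
    if modality == "brightfield":
        px = (255 - px.astype(np.int16)).astype(np.uint8)
    if threshold_override is not None:
        if not (0 <= threshold_override <= 255):
            raise ValueError("threshold_override must lie in [0, 255]")
        t = int(threshold_override)
    else:
        t = otsu_threshold(px)
    return px > t


def smooth_selection(mask: np.ndarray, radius: int) -> np.ndarray:
    """Smooth a selection by enlarging then shrinking it.

    Morphological closing with a disk of the given radius; radius 0 is the
    identity.  The mask is padded before closing so the result always
    contains the input, including at image borders.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    padded = np.pad(mask, radius, mode="constant", constant_values=False)
    closed = ndi.binary_closing(padded, structure=disk(radius))
    return closed[radius:-radius, radius:-radius]


def preprocess_chain(img: CalibratedImage, params: PipelineParams):
    """Run grayscale -> Gaussian -> contrast -> threshold.

    Returns ``(proc, mask, threshold)`` where ``proc`` is the smoothed,
    contrast-stretched 8-bit image with fluorescence polarity (bright
    walls) regardless of the input modality, ``mask`` the binary wall
    mask and ``threshold`` the level actually used.
    """
    proc = gaussian_smooth(img, params.gaussian_sigma)
    proc = enhance_contrast(proc, params.contrast_saturation)
    px = proc.pixels
    if img.modality == "brightfield":
        px = (255 - px.astype(np.int16)).astype(np.uint8)
    if params.threshold_override is not None:
        t = int(params.threshold_override)
    else:
        t = otsu_threshold(px)
    mask = px > t
    proc_norm = CalibratedImage(px, "fluorescence", img.calibration, img.source_id)
    return proc_norm, mask, t
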