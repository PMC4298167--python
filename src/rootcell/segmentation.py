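"""Region selection: root, stele oval, central metaxylem, cortex.

The four selections mirror the supervised tool's R/S/X/C steps:

* root  — largest connected wall-mask component, hole-filled and smoothed;
* stele — a moment-matched ellipse at the root centroid whose area is
  root_area / proportion (proportion defaults to 4);
* central metaxylem — bright-walled vessels inside the stele, found by a
  stele-restricted re-threshold plus size and circularity filters;
* cortex — the region radially inside the sclerenchyma band, whose inner
  edge is traced per angle in polar space.

Derived areas follow the tool's arithmetic: the external layer area is
root minus measured cortex, and the reported cortex area is measured
cortex minus stele.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, measure
from skimage.morphology import disk

from .preprocess import (CalibratedImage, PipelineParams, preprocess_chain,
                         smooth_selection)
from .polar import polar_transform

REGION_LABELS = ("root", "stele", "central_metaxylem", "cortex")


@dataclasses.dataclass
class RegionSelection:
    """A labeled filled region: mask, closed contour(s) and area."""

    label: str
    mask: np.ndarray
    contour: list
    area_px: int
    area_units: float | None = None
    n_components: int = 1
    warnings: list = dataclasses.field(default_factory=list)
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.label not in REGION_LABELS:
            raise ValueError(f"label must be one of {REGION_LABELS}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area_px must equal the number of foreground pixels")

    @property
    def centroid(self) -> tuple:
        rr, cc = np.nonzero(self.mask)
        return (float(rr.mean()), float(cc.mean()))


@dataclasses.dataclass
class AreaSet:
    """The area arithmetic of one image, in the active unit."""

    roota: float
    stelea: float
    cma: float
    cortex_measured: float
    ela: float
    ctxa: float


def _make_selection(label: str, mask: np.ndarray, calibration: float | None = None,
                    warnings=None, meta=None) -> RegionSelection:
    mask = np.asarray(mask, dtype=bool)
    contours = measure.find_contours(mask.astype(np.float64), 0.5)
    n_comp = int(measure.label(mask, connectivity=2).max()) if mask.any() else 0
    area = int(mask.sum())
    return RegionSelection(
        label=label, mask=mask, contour=[np.asarray(c) for c in contours],
        area_px=area,
        area_units=(area * calibration ** 2) if calibration else None,
        n_components=max(n_comp, 1) if mask.any() else 0,
        warnings=list(warnings or []), meta=dict(meta or {}),
    )


def select_root(img: CalibratedImage, params: PipelineParams,
                proc_mask=None) -> RegionSelection:
    """Select the whole root section.

    Runs the preprocessing chain, keeps the largest connected wall
    component, fills its holes and smooths the selection by closing.
    Rejects blank images and sections truncated by two or more borders.
    """
    if proc_mask is None:
        _, mask, _ = preprocess_chain(img, params)
    else:
        mask = proc_mask
    if not mask.any():
        raise ValueError(f"no foreground found in {img.source_id!r}")
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    # largest component; equal areas tie-break on smaller centroid row, col
    props.sort(key=lambda p: (-p.area, p.centroid[0], p.centroid[1]))
    comp = lab == props[0].label
    r0, c0, r1, c1 = props[0].bbox
    h, w = mask.shape
    touched = sum([r0 == 0, c0 == 0, r1 == h, c1 == w])
    if touched >= 2:
        raise ValueError(
            f"root section in {img.source_id!r} touches {touched} image borders "
            "(truncated section)"
        )
    filled = ndi.binary_fill_holes(comp)
    smoothed = smooth_selection(filled, params.smoothing_radius)
    smoothed = ndi.binary_fill_holes(smoothed)
    return _make_selection("root", smoothed, params.calibration)


def select_stele(root: RegionSelection, proportion: float) -> RegionSelection:
    """Draw the stele as a moment-matched ellipse of area root/proportion.

    Centered at the root centroid, oriented and shaped by the root mask's
    second central moments; reduces to a concentric disk for circular
    roots.  If the ellipse pokes out of the root it is shrunk to fit and
    a warning recorded.
    """
    if proportion <= 1:
        raise ValueError("proportion must be > 1")
    if root.n_components != 1:
        raise ValueError("root selection must be a single component")
    mask = root.mask
    cy, cx = root.centroid
    rr, cc = np.nonzero(mask)
    dy, dx = rr - cy, cc - cx
    mu20 = float(np.mean(dy * dy))
    mu02 = float(np.mean(dx * dx))
    mu11 = float(np.mean(dy * dx))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 1e-12), max(evals[1], 1e-12)
    q = np.sqrt(lam_major / lam_minor)  # semi-axis ratio a/b
    target = root.area_px / proportion
    b = np.sqrt(target / (np.pi * q))
    a = q * b
    # major-axis direction (dy, dx); skimage rotation is measured from the
    # row axis toward the column axis
    vy, vx = evecs[:, 1]
    rot = np.arctan2(vx, vy)
    warnings = []
    scale = 1.0
    for _ in range(60):
        err, ecc = draw.ellipse(cy, cx, a * scale, b * scale,
                                shape=mask.shape, rotation=rot)
        emask = np.zeros(mask.shape, dtype=bool)
        emask[err, ecc] = True
        if np.all(mask[emask]):
            break
        scale *= 0.98
    else:
        raise ValueError("could not fit the stele ellipse inside the root")
    if scale != 1.0:
        warnings.append(f"stele ellipse shrunk by factor {scale:.3f} to fit the root")
    sel = _make_selection("stele", emask, None, warnings,
                          meta={"semi_axes": (a * scale, b * scale),
                                "rotation": rot, "center": (cy, cx)})
    if root.area_units is not None and root.area_px:
        sel.area_units = sel.area_px * root.area_units / root.area_px
    return sel


def _circularity(region) -> float:
    p = region.perimeter
    return 4 * np.pi * region.area / (p * p) if p > 0 else 0.0


def select_central_metaxylem(img: CalibratedImage, stele: RegionSelection,
                             params: PipelineParams, proc: CalibratedImage | None = None):
    """Select and count the central metaxylem vessels inside the stele.

    Re-thresholds the preprocessed image on stele pixels only, closes the
    wall mask, fills vessel rings into discs and keeps components with
    area >= min_cmx_area and circularity 4*pi*A/P**2 >= the threshold.
    A manual count (params.manual_ncm) replaces the automatic one while
    the selection is retained.  Returns (selection, ncm).
    """
    if proc is None:
        proc, _, _ = preprocess_chain(img, params)
    interior = ndi.binary_erosion(stele.mask, structure=disk(5))
    warnings = []
    if not interior.any():
        sel = _make_selection("central_metaxylem", np.zeros_like(stele.mask),
                              params.calibration, ["stele too small for vessel search"])
        return sel, (params.manual_ncm if params.manual_ncm is not None else 0)
    # half-level between the tissue floor and the wall peak: unlike a
    # variance-split threshold this does not drift with the wall-pixel
    # fraction, so single and clustered vessels are sized alike
    px = proc.pixels[interior]
    t = 0.5 * (np.percentile(px, 20) + np.percentile(px, 99.5))
    wallmask = interior & (proc.pixels > t)
    wallmask = smooth_selection(wallmask, 1)
    filled = ndi.binary_fill_holes(wallmask)
    # the half-level crossing of the blurred wall ridge sits ~sigma
    # outside the wall edge; peel that back before the size filter
    if params.gaussian_sigma > 0:
        filled = ndi.binary_erosion(
            filled, structure=disk(max(1, int(params.gaussian_sigma))))
    border = interior & ~ndi.binary_erosion(interior, structure=disk(2))
    lab = measure.label(filled, connectivity=2)
    keep = np.zeros_like(filled)
    ncm_auto = 0
    for region in measure.regionprops(lab):
        comp = lab == region.label
        # pericycle-wall remnants hug the search border; a vessel at worst
        # grazes it
        if (comp & border).sum() > 0.1 * region.area:
            continue
        if region.area < params.min_cmx_area:
            continue
        if _circularity(region) < params.cmx_circularity:
            continue
        keep |= comp
        ncm_auto += 1
    if ncm_auto == 0:
        warnings.append("no central metaxylem vessel detected")
    sel = _make_selection("central_metaxylem", keep, params.calibration, warnings)
    sel.n_components = max(ncm_auto, 0)
    ncm = params.manual_ncm if params.manual_ncm is not None else ncm_auto
    return sel, int(ncm)


def _circular_median(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    half = width // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    out = ndi.median_filter(padded, size=width, mode="nearest")
    return out[half:half + values.size]


def _fill_nan_circular(values: np.ndarray) -> np.ndarray:
    bad = np.isnan(values)
    if not bad.any():
        return values
    n = values.size
    idx = np.arange(n)
    good = ~bad
    # circular nearest-neighbor interpolation over angle
    out = values.copy()
    out[bad] = np.interp(idx[bad], idx[good], values[good], period=n)
    return out


def select_cortex(img: CalibratedImage, root: RegionSelection, stele: RegionSelection,
                  params: PipelineParams, proc: CalibratedImage | None = None) -> RegionSelection:
    """Select the tissue radially inside the sclerenchyma band.

    In polar space about the stele centroid, the sclerenchyma is the
    outermost thick bright band within the outer search window of the
    local root radius; the cortex boundary is the band's inner edge per
    angle, median-filtered over angle.  Falls back to an eroded root mask
    when the band is undetected over more than a quarter of the angles.
    """
    if proc is None:
        proc, _, _ = preprocess_chain(img, params)
    center = stele.centroid
    h, w = root.mask.shape
    rr, cc = np.nonzero(root.mask)
    r_max = int(np.ceil(np.hypot(rr - center[0], cc - center[1]).max())) + 5
    r_max = min(r_max, int(np.hypot(h, w)))
    n_ang = params.n_angles
    pol = polar_transform(proc, center, n_ang, r_max)
    pol_root = polar_transform(root.mask.astype(np.float64), center, n_ang, r_max)
    root_extent = pol_root.pixels >= 0.5

    # global band location on the angular-mean radial profile: the band is
    # bright at every angle, so it dominates the mean; thresholding at the
    # half-level of the search window puts the crossing of the blurred
    # edge on the rendered edge itself
    wgt = root_extent.astype(np.float64)
    mean_prof = (pol.pixels * wgt).sum(axis=1) / np.maximum(wgt.sum(axis=1), 1.0)
    r_local_all = np.array([
        np.nonzero(root_extent[:, a])[0].max() if root_extent[:, a].any() else 0
        for a in range(n_ang)
    ])
    r_med = int(np.median(r_local_all[r_local_all > 0])) if (r_local_all > 0).any() else 0
    lo_g = int(np.ceil((1.0 - params.scler_search_fraction) * r_med))
    g_in = g_out = None
    if r_med > lo_g + params.scler_min_band_px:
        win = mean_prof[lo_g:r_med + 1]
        t_b = (win.min() + win.max()) / 2.0
        runs, n_runs = ndi.label(win >= t_b)
        # the band is the widest strong run: single periclinal walls blur
        # to narrower runs, and the run touching the window's outer end is
        # the root boundary wall, not the band
        best_len = 0
        for rid in range(n_runs, 0, -1):
            pos = np.nonzero(runs == rid)[0]
            # a credible band is interior to the window (its inner edge is
            # visible, and the run touching the outer end is the root
            # boundary wall) and of bounded width
            if pos[0] == 0 or pos[-1] >= win.size - 2:
                continue
            if pos.size > 0.75 * win.size:
                continue
            if pos.size >= max(params.scler_min_band_px, best_len + 1):
                g_in, g_out = lo_g + int(pos[0]), lo_g + int(pos[-1])
                best_len = pos.size

    inner_edge = np.full(n_ang, np.nan)
    if g_in is not None:
        delta = 5
        r_lo = max(0, g_in - delta)
        r_hi = min(r_max, g_in + delta)
        for a in range(n_ang):
            idx = np.nonzero(pol.pixels[r_lo:r_hi + 1, a] >= t_b)[0]
            if idx.size:
                inner_edge[a] = r_lo + idx[0]

    undetected = float(np.mean(np.isnan(inner_edge)))
    warnings = []
    if g_in is None or undetected > 0.25:
        warnings.append(
            f"sclerenchyma band undetected for {undetected:.0%} of angles; "
            "falling back to eroded root mask"
        )
        r_eq = np.sqrt(root.area_px / np.pi)
        thickness = max(2, int(round(0.15 * r_eq)))
        cortex_mask = ndi.binary_erosion(root.mask, structure=disk(thickness))
        cortex_mask = ndi.binary_fill_holes(cortex_mask | stele.mask)
        pol_ctx = polar_transform(cortex_mask.astype(np.float64), center, n_ang, r_max)
        ext = pol_ctx.pixels >= 0.5
        boundary = np.array([
            np.nonzero(ext[:, a])[0].max() if ext[:, a].any() else 0.0
            for a in range(n_ang)
        ], dtype=np.float64)
        band_c = boundary + thickness / 2.0
        g_in, g_out = None, None
    else:
        inner_edge = _fill_nan_circular(inner_edge)
        boundary = _circular_median(inner_edge, params.angular_median_width)
        band_c = boundary + (g_out - g_in) / 2.0
        theta = np.arange(n_ang) * (2 * np.pi / n_ang)
        poly_r = center[0] - boundary * np.sin(theta)
        poly_c = center[1] + boundary * np.cos(theta)
        fr, fc = draw.polygon(poly_r, poly_c, shape=root.mask.shape)
        cortex_mask = np.zeros_like(root.mask)
        cortex_mask[fr, fc] = True
        cortex_mask = ndi.binary_fill_holes((cortex_mask & root.mask) | stele.mask)

    sel = _make_selection("cortex", cortex_mask, params.calibration, warnings,
                          meta={"band_inner_r": boundary, "band_center_r": band_c,
                                "band_global": (g_in, g_out),
                                "center": center, "n_angles": n_ang, "r_max": r_max})
    return sel


def compute_areas(root: RegionSelection, stele: RegionSelection,
                  cmx: RegionSelection, cortex: RegionSelection,
                  calibration: float | None = None) -> AreaSet:
    """Derive the reported areas from the four selections.

    ELA = ROOTA - measured cortex; CTXA = measured cortex - STELEA.  With
    a calibration c (um/px), areas are scaled by c**2.
    """
    roota, ctx_m = root.area_px, cortex.area_px
    stelea, cma = stele.area_px, cmx.area_px
    pairs = [("roota >= cortex_measured", roota, ctx_m),
             ("cortex_measured >= stelea", ctx_m, stelea),
             ("stelea >= cma", stelea, cma),
             ("cma >= 0", cma, 0)]
    for name, lhs, rhs in pairs:
        if lhs < rhs:
            raise ValueError(f"area ordering violated: {name} (got {lhs} < {rhs})")
    scale = calibration ** 2 if calibration else 1
    return AreaSet(
        roota=roota * scale, stelea=stelea * scale, cma=cma * scale,
        cortex_measured=ctx_m * scale,
        ela=(roota - ctx_m) * scale, ctxa=(ctx_m - stelea) * scale,
    )
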