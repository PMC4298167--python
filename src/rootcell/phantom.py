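"""Synthetic root-section phantoms with exact ground truth.

A phantom emulates the concentric anatomy of a rice radicle transverse
section imaged by cell-wall autofluorescence: from the outside inward,
epidermis, exodermis, a dense bright sclerenchyma annulus, several cortex
cell layers, endodermis/pericycle, and a stele containing peripheral
metaxylem vessels and one-to-several large central metaxylem vessels.
Cell walls are bright (periclinal walls are circles, anticlinal walls are
radial segments subdividing each ring into cells); tissue is dim and the
background dark.  Gaussian noise is added last.

Ground truth (areas, counts, wall radii) is taken from the same label map
used to render the image, so it is exact for the rendered instance and
free of analytic rasterization bias.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import CalibratedImage, round_half_up


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic root section.

    Radii must satisfy stele < scler_inner < scler_outer < root and fit in
    the image.  ``cells_per_file`` lists the cell count of each counted
    (cortex) ring, outermost first; ``None`` derives counts from ring
    circumference at ~10 px per cell.
    """

    image_size: tuple = (512, 512)
    center: tuple | None = None
    root_radius: float = 120.0
    scler_outer_radius: float = 106.0
    scler_inner_radius: float = 100.0
    stele_radius: float = 60.0
    n_cortex_layers: int = 5
    cells_per_file: list | None = None
    wall_thickness: float = 2.0
    wall_intensity: int = 220
    tissue_intensity: int = 60
    background_intensity: int = 10
    noise_sigma: float = 8.0
    n_cmx: int = 1
    cmx_radius: float = 12.0
    n_mx: int = 8
    mx_radius: float = 4.0
    modality: str = "fluorescence"
    angular_jitter: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if self.center is None:
            self.center = (self.image_size[0] / 2.0, self.image_size[1] / 2.0)
        if not (0 < self.stele_radius < self.scler_inner_radius
                < self.scler_outer_radius < self.root_radius):
            raise ValueError(
                "radii must satisfy 0 < stele < scler_inner < scler_outer < root; got "
                f"stele={self.stele_radius}, scler_inner={self.scler_inner_radius}, "
                f"scler_outer={self.scler_outer_radius}, root={self.root_radius}"
            )
        h, w = self.image_size
        cy, cx = self.center
        if (cy - self.root_radius < 0 or cy + self.root_radius >= h
                or cx - self.root_radius < 0 or cx + self.root_radius >= w):
            raise ValueError("root circle does not fit inside the image")
        if self.n_cortex_layers < 1:
            raise ValueError("need at least one cortex layer")
        if not (self.wall_intensity > self.tissue_intensity >= self.background_intensity):
            raise ValueError("need wall_intensity > tissue_intensity >= background_intensity")
        if self.n_cmx < 0 or self.cmx_radius <= 0:
            raise ValueError("invalid central metaxylem specification")
        if self.cells_per_file is not None and len(self.cells_per_file) != self.n_cortex_layers:
            raise ValueError("cells_per_file must list one count per cortex layer")


@dataclasses.dataclass
class GroundTruth:
    """Exact per-instance truth, measured on the rendered label map."""

    true_root_area: int
    true_cortex_area: int
    true_stele_area: int
    true_cma: int
    true_ncm: int
    true_nm: int
    true_ncl: int
    true_cells_per_file: list
    wall_radii: list
    file_radii: list
    center: tuple


def _default_cells(spec: PhantomSpec, ring_mids):
    # outermost first; ~10 px of arc per cortex cell, never fewer than 12
    return [max(12, int(round(2 * np.pi * r / 10.0))) for r in ring_mids]


def _wall_angles(k: int, jitter: float, rng) -> np.ndarray:
    base = np.arange(k) * (2 * np.pi / k)
    if jitter > 0:
        base = base + rng.uniform(-0.5, 0.5, size=k) * jitter * (2 * np.pi / k)
    return np.mod(base, 2 * np.pi)


def _paint_anticlinal(img, dist, ang, r_in, r_out, angles, half_t):
    """Set wall pixels for radial segments between r_in and r_out."""
    ring = (dist >= r_in) & (dist <= r_out)
    if not ring.any():
        return
    a = ang[ring]
    diff = np.abs(a[:, None] - angles[None, :])
    d = np.minimum(diff, 2 * np.pi - diff).min(axis=1)
    # angular half-width of a wall of fixed thickness shrinks with radius
    hw = half_t / np.maximum(dist[ring], 1.0)
    sel = d <= hw
    idx = np.flatnonzero(ring.ravel())[sel]
    img.ravel()[idx] = True


def generate_phantom(spec: PhantomSpec):
    """Render one phantom; returns ``(CalibratedImage, GroundTruth)``.

    Deterministic for a fixed spec (the spec carries its own rng_seed).
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    cy, cx = spec.center
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    dist = np.hypot(rows, cols)
    # angle 0 along +col, counter-clockwise with rows pointing down
    ang = np.mod(np.arctan2(-rows, cols), 2 * np.pi)

    t = spec.wall_thickness
    half_t = t / 2.0

    root_mask = dist <= spec.root_radius
    cortex_mask = dist <= spec.scler_inner_radius   # region inside the sclerenchyma
    stele_mask = dist <= spec.stele_radius

    # periclinal (circular) walls bounding the counted rings; the wall at
    # scler_inner coincides with the sclerenchyma band's inner edge
    n = spec.n_cortex_layers
    wall_radii = np.linspace(spec.stele_radius, spec.scler_inner_radius, n + 1)
    ring_mids = [(wall_radii[i] + wall_radii[i + 1]) / 2.0 for i in range(n)][::-1]
    cells = list(spec.cells_per_file) if spec.cells_per_file is not None \
        else _default_cells(spec, ring_mids)

    wall = np.zeros((h, w), dtype=bool)
    for r_w in wall_radii[:-1]:
        wall |= np.abs(dist - r_w) <= half_t
    # sclerenchyma: dense bright annulus
    wall |= (dist >= spec.scler_inner_radius) & (dist <= spec.scler_outer_radius)
    # external layers: exodermis/epidermis boundary wall and the root
    # boundary wall (inner-aligned so the wall lies inside the root)
    mid_ext = (spec.scler_outer_radius + spec.root_radius) / 2.0
    wall |= np.abs(dist - mid_ext) <= half_t
    wall |= (dist >= spec.root_radius - t) & (dist <= spec.root_radius)

    # anticlinal walls: cortex rings (counted) ...
    for i in range(n):
        r_in, r_out = wall_radii[n - 1 - i], wall_radii[n - i]  # ring i, outermost first
        angles = _wall_angles(cells[i], spec.angular_jitter, rng)
        _paint_anticlinal(wall, dist, ang, r_in - half_t, r_out + half_t, angles, half_t)
    # ... and external rings (uncounted, ~8 px cells) for wall connectivity
    for r_in, r_out in ((spec.scler_outer_radius, mid_ext), (mid_ext, spec.root_radius)):
        r_mid = (r_in + r_out) / 2.0
        k = max(12, int(round(2 * np.pi * r_mid / 8.0)))
        angles = _wall_angles(k, spec.angular_jitter, rng)
        _paint_anticlinal(wall, dist, ang, r_in - half_t, r_out + half_t, angles, half_t)

    # vessels in the stele: peripheral metaxylem (small) and central
    # metaxylem (large, counted + measured); walls are inner-aligned rings
    cma_mask = np.zeros((h, w), dtype=bool)
    lumen = np.zeros((h, w), dtype=bool)

    def _vessel(vy, vx, radius, wall_t):
        d = np.hypot(rows - (vy - cy), cols - (vx - cx))
        ringw = (d >= radius - wall_t) & (d <= radius)
        return d <= radius, ringw, d < radius - wall_t

    phase = rng.uniform(0, 2 * np.pi)
    if spec.n_cmx == 1:
        cmx_centers = [(cy, cx)]
    else:
        rr = 2.1 * spec.cmx_radius
        cmx_centers = [(cy - rr * np.sin(phase + 2 * np.pi * j / spec.n_cmx),
                        cx + rr * np.cos(phase + 2 * np.pi * j / spec.n_cmx))
                       for j in range(spec.n_cmx)]
    for (vy, vx) in cmx_centers:
        disc, ringw, lum = _vessel(vy, vx, spec.cmx_radius, t)
        cma_mask |= disc
        wall |= ringw
        lumen |= lum
    mx_ring_r = 0.65 * spec.stele_radius
    mx_phase = rng.uniform(0, 2 * np.pi)
    n_mx_drawn = 0
    for j in range(spec.n_mx):
        a = mx_phase + 2 * np.pi * j / max(spec.n_mx, 1)
        vy, vx = cy - mx_ring_r * np.sin(a), cx + mx_ring_r * np.cos(a)
        # real metaxylem sit in the free space around the central vessels;
        # keep a wall-to-wall gap that survives optical blur
        clearance = spec.cmx_radius + spec.mx_radius + 8.0
        if any(np.hypot(vy - y0, vx - x0) < clearance for (y0, x0) in cmx_centers):
            continue
        disc, ringw, lum = _vessel(vy, vx, spec.mx_radius, min(t, 2.0))
        wall |= ringw
        lumen |= lum
        n_mx_drawn += 1

    wall &= root_mask

    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    img[root_mask] = spec.tissue_intensity
    img[lumen] = spec.background_intensity  # vessel lumens are dark
    img[wall] = spec.wall_intensity

    if spec.modality == "brightfield":
        img = 255.0 - img
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(round_half_up(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        true_root_area=int(root_mask.sum()),
        true_cortex_area=int(cortex_mask.sum()),
        true_stele_area=int(stele_mask.sum()),
        true_cma=int(cma_mask.sum()),
        true_ncm=spec.n_cmx,
        true_nm=n_mx_drawn,
        true_ncl=n,
        true_cells_per_file=cells,
        wall_radii=[float(r) for r in wall_radii],
        file_radii=[float(r) for r in ring_mids],
        center=(float(cy), float(cx)),
    )
    image = CalibratedImage(img, modality=spec.modality,
                            source_id=f"phantom_seed{spec.rng_seed}")
    return image, truth


def phantom_suite(seed: int, n: int):
    """Draw ``n`` phantoms from documented parameter ranges, reproducibly.

    Root radius 80-160 px, stele at half the root radius, 3-6 cortex
    layers, 12-64 cells per file (capped so that cell arcs stay wider than
    ~2.5 wall thicknesses and remain resolvable), 1-4 central metaxylem
    vessels, noise sigma 0-15.  Returns a list of (spec, image, truth).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        root_r = float(rng.integers(80, 161))
        stele_r = root_r / 2.0
        scler_inner = round(root_r * 5.0 / 6.0)
        scler_outer = scler_inner + 6.0
        # a cortex ring thinner than ~6 px is below the resolvable cell
        # size at this magnification; cap the layer count accordingly
        n_layers_cap = int(min(6, (scler_inner - stele_r) / 6.0))
        n_layers = int(rng.integers(3, max(4, n_layers_cap + 1)))
        wall_radii = np.linspace(stele_r, scler_inner, n_layers + 1)
        cells = []
        for i in range(n_layers)[::-1]:
            r_mid = (wall_radii[i] + wall_radii[i + 1]) / 2.0
            k_max = min(64, int(2 * np.pi * r_mid / 8.0))
            cells.append(int(rng.integers(12, max(13, k_max + 1))))
        n_cmx = int(rng.integers(1, 5))
        cmx_cap = (stele_r - 8.0) / 3.1 if n_cmx > 1 else stele_r - 8.0
        cmx_r = float(min(rng.uniform(10.0, 16.0), cmx_cap))
        size = int(2 * (root_r + 30))
        spec = PhantomSpec(
            image_size=(size, size),
            root_radius=root_r,
            scler_outer_radius=scler_outer,
            scler_inner_radius=float(scler_inner),
            stele_radius=stele_r,
            n_cortex_layers=n_layers,
            cells_per_file=cells,
            n_cmx=n_cmx,
            cmx_radius=cmx_r,
            n_mx=int(rng.integers(6, 13)),
            noise_sigma=float(rng.uniform(0.0, 15.0)),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = generate_phantom(spec)
        out.append((spec, image, truth))
    return out
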