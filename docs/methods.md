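# Methods

## Pipeline model

`rootcell` treats a transverse root section as concentric tissue rings
whose boundaries are bright (autofluorescent) cell walls.  Every image
passes through one fixed preprocessing chain — grayscale conversion
(luminance weights 0.299/0.587/0.114, rounded half up), Gaussian
smoothing, linear percentile contrast stretch, thresholding — and four
region selections, in the order a supervised operator would run them:

1. **Root.**  Foreground = pixels strictly above the threshold
   (automatic threshold: exhaustive 256-level between-class-variance
   maximization; ties, e.g. the empty gap of a well-separated bimodal
   histogram, resolve to the plateau middle).  The largest connected
   component is kept (ties broken by smaller centroid row, then column),
   holes are filled, and the selection is smoothed by morphological
   closing (disk radius 3).  Sections touching two or more image borders
   are rejected as truncated.  Bright-field input is inverted before
   thresholding; nothing else changes.
2. **Stele.**  An ellipse at the root centroid with orientation and axis
   ratio from the root mask's second central moments, scaled so its area
   is root area / `stele_proportion` (default 4, the tool's standard
   anatomy assumption).  For a circular root this reduces to a
   concentric disk.  If the ellipse pokes outside the root it is shrunk
   in 2% steps until contained, with a warning.
3. **Central metaxylem.**  Inside the stele (eroded by 5 px to exclude
   the pericycle wall), walls are re-thresholded at the half-level
   between the tissue floor (20th percentile) and the wall peak (99.5th
   percentile) of stele pixels.  The half-level is used instead of a
   variance split because it does not drift with the wall-pixel
   fraction, so images with one vessel and with four are sized alike.
   The wall mask is closed (radius 1), rings are filled into discs, and
   the discs eroded by ~sigma to undo blur dilation before filtering:
   components must avoid the search border (less than 10% overlap), have
   area >= `min_cmx_area` (80 px) and circularity 4πA/P² >= 0.5.  CMA is
   the kept area; NCM the kept count, replaced by `manual_ncm` when
   supplied.  The peripheral metaxylem count NM is always user-supplied
   (`manual_nm`) and reported as missing otherwise — automatic counting
   of the small peripheral vessels is deliberately out of scope.
4. **Cortex.**  The sclerenchyma is located on the angular-mean radial
   profile of the polar-transformed image: within the outer 35% of the
   median root radius, the band is the widest run above the half-level
   of that window that neither touches the window ends (the outer run is
   the root boundary wall) nor exceeds 75% of the window.  Because the
   threshold sits at the half-level, the crossing of the blurred band
   edge falls on the rendered edge itself, so no bias correction is
   needed.  The per-angle inner edge is then refined within ±5 px of the
   global edge, gaps interpolated circularly, and the boundary median-
   filtered over angle (width 9 samples, which removes the ≤5-sample
   excursions caused by anticlinal walls crossing the band).  The cortex
   is the filled polygon inside this boundary, constrained to contain
   the stele and stay inside the root.  If no credible band covers 75%
   of angles, the fallback is the root eroded by 15% of its equivalent
   radius, with a warning.

Derived areas follow the tool's arithmetic exactly: external layer area
ELA = ROOTA − measured cortex, reported cortex area CTXA = measured
cortex − STELEA.  These identities hold to the pixel for every
successful run; violated orderings abort the image with the violated
inequality named.

## Polar counting

The polar transform resamples bilinearly onto a (radius, angle) grid —
1 px radial steps, 720 angular samples (0.5°), angle 0 along +col
increasing counter-clockwise, center at the stele centroid.  Peaks on a
profile are local maxima with prominence >= the noise tolerance
(default 20 of 255); plateaus report their center, and full-circle
profiles are treated circularly by cutting at a global minimum (every
circular prominence path through the cut passes that minimum, so linear
prominences equal circular ones), which also counts a seam-spanning
maximum once.

**Layers (NCL).**  `n_layer_lines` (default 3) radial lines are placed
at evenly spaced angles from a seeded offset; each line then snaps to
the neighboring column (±7.5°) that resolves the most prominent maxima,
emulating the operator's habit of drawing lines between, not along,
anticlinal walls.  A line's profile runs from just inside the stele
boundary to the sclerenchyma inner edge; each maximum is the inner
bounding wall of one counted layer (the band bounds the outermost layer
and contributes no maximum), so the per-line count is simply the number
of maxima.  The count-to-maxima offset remains configurable
(`layer_count_offset`) because wall-counting conventions differ.  NCL is
the mean over lines; lines with no maxima are excluded with a warning.

**Cell files (NCF).**  Candidate file radii are midpoints between
consecutive periclinal-wall maxima (averaged over the lines agreeing on
the modal wall count, augmented by the band inner edge which bounds the
outermost file), outermost first; explicit radii in the config override
them.  A full-circle count is the number of periodic maxima; a partial
span (coverage c) counts non-periodically and extrapolates as
round-half-up(raw / c).

## Synthetic phantoms

The generator renders the concentric anatomy with bright walls
(default 220), dim tissue (60), dark background (10), wall thickness
2 px, and seeded Gaussian noise; bright-field output is the inversion of
the noiseless rendering before noise.  Anticlinal walls subdivide each
cortex ring (positions jittered by 10% of the cell's angular width) and
the external layers (~8 px cells, which also keeps the wall network
connected for root selection).  Central metaxylem vessels are
dark-lumen discs with bright walls near the stele center; peripheral
metaxylem are 4 px vessels on a ring at 0.65 stele radius, skipped where
they would collide with a central vessel (real vessels do not
interpenetrate).  Ground truth is measured on the rendered label map,
not analytic formulas, so segmentation tests carry no rasterization
bias.

`phantom_suite` draws root radius 80–160 px, stele at half the root
radius (the default area proportion of 4), sclerenchyma at 5/6 of the
root radius, 3–6 cortex layers capped so rings stay >= ~6 px tall, 12–64
cells per file capped so cell arcs stay >= ~8 px, 1–4 central metaxylem,
and noise sigma 0–15.  The caps are realism constraints: cells below
those sizes are unresolvable at the magnification class the tool
targets and do not occur in its input images.

What the phantoms do **not** emulate: uneven illumination, section
damage and debris inside the root, out-of-focus blur gradients,
non-elliptical stele shapes, and biological irregularity of wall
spacing beyond the angular jitter.  Passing tests therefore demonstrate
correctness of the measurement logic under controlled contrast and
geometry, not segmentation robustness on degraded field images — the
supervision hooks (threshold and selection overrides, review overlays)
exist precisely because real images need them.

## Numerical choices

* 8-bit internal representation; 16-bit input min–max rescaled on load;
  rounding is half-up everywhere.
* Gaussian smoothing sigma 1.5 px: small enough to keep adjacent
  periclinal walls separable at ~6 px ring spacing, large enough that
  smoothed sensor noise (sigma <= 15) stays far below the default
  prominence tolerance of 20.
* Contrast stretch saturation 0.35% per tail, the common automatic
  enhancement convention.
* Closing radius 3 px for selection smoothing; closing is performed on a
  padded array so it is extensive (never removes foreground) at borders.
* Determinism: all randomness (line offsets, phantom draws) flows from
  explicit integer seeds through `numpy.random.default_rng`; repeated
  runs are byte-identical, which the test suite asserts on the TSV and
  JSON outputs.
* Degenerate inputs: blank images, truncated sections, flat profiles and
  geometrically impossible phantom specs are rejected with named
  reasons; a batch continues past per-image failures and signals them
  via exit status 2.

## Known limitations

* The stele is modeled as an ellipse of fixed area ratio; steles that
  deviate strongly from the root's moment ellipse are mis-sized, and the
  default proportion 4 is an anatomical convention, not a measurement.
* Cell files are counted at automatically placed radii between detected
  periclinal walls; files outside the stele–sclerenchyma span (e.g.
  epidermis) are only reachable via explicit `file_radii` overrides.
* Layer counting assumes near-concentric anatomy; strongly oblique
  sections violate the polar model and are out of scope.
* NM (peripheral metaxylem) has no automatic detector by design.
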