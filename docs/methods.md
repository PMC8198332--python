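# Methods

## Scope and model

The package quantifies follicular thyroid architecture from
three-channel fluorescence rasters. The underlying tissue model is the
classic equatorial mid-section view: follicles are topologically
annular — a lumen (colloid cavity) surrounded by a single epithelial
cell layer whose outer face carries a basal lamina. All measurements
are two-dimensional; no attempt is made to correct for sectioning
geometry, so areas and the epithelial-extension proxy are section-plane
quantities, comparable across groups only for equivalently sampled
mid-sections.

## Pipelines

**Intensity compartmentalization.** Total marker signal is the plain
intensity sum over the field. Intracellular signal is the sum under the
thresholded cytoplasm mask; extracellular signal is defined by
subtraction, so conservation (`intra + extra = total`) holds exactly by
construction. Pericellular (apical-membrane-associated) marker cannot
be separated from luminal marker by mask logic and is deliberately
reported inside the extracellular pool. Per-cell normalization divides
by the nucleus count of the whole field; a per-follicle variant is
available through the morphometry records but is an extension, not the
reference behavior. No background subtraction is performed: on images
whose field is mostly empty, additive background noise inflates the
extracellular pool (the whole-field sum integrates it), which is the
expected behavior of whole-image intensity measurement and the reason
group comparisons should use matched acquisition settings.

**Segmentation.** The merged gray image (unweighted channel mean —
the merge weights of the original acquisition software are not
standardized, and equal weights keep the operation involution-free and
documentable) is thresholded into a tissue mask; the basal-lamina
channel is thresholded, morphologically closed (disk radius 2 px, to
bridge small staining gaps) and skeletonized to 1-px curves. Lumen
candidates are 8-connected components of the inverted tissue mask with
equivalent diameter `2*sqrt(A/pi)` in 25–800 px. Components touching
the image border are discarded (they are truncated by the field of
view; this also removes the surrounding background region on fields the
tissue does not fill). Surviving objects are hole-filled so that a
lumen retains the pixels of dead-cell remnants it encloses. Candidates
are filtered by form factor at 0.3 (inclusive: FF = 0.3 is retained;
the strictness at the boundary is a convention this package fixes,
since only the cutoff value itself is standard).

**Follicle propagation.** Follicles grow from lumen seeds through true
pixels of the boundary image (tissue minus lamina skeleton). Distance
is geodesic in the 8-connected chamfer metric (axial step 1, diagonal
step sqrt(2)), computed exactly per lumen with `skimage.graph.
MCP_Geometric` on a bounding box padded by the expansion cap; a pixel
joins the nearest lumen provided its geodesic distance from that
lumen's pixels is at most the 30-px cap, with exact ties broken toward
the lower label. The chamfer metric overestimates Euclidean distance by
at most ~8% (worst at 22.5° to the axes), so an uncapped follicle front
is an octagon-flavored disc; with the standard barrier-limited growth
this is immaterial because the lamina, not the cap, stops the front.
Barrier pixels are never entered, hence follicles exclude the 1-px
skeleton line — which is also how the recovered epithelium areas should
be interpreted (lamina excluded).

**Relations.** A nucleus belongs to the follicle containing its
centroid (rounded to the nearest pixel); centroids on background give
parent 0. Centroid assignment was chosen over overlap-fraction
assignment because it is unambiguous for convex parents and cheap;
for the thin-epithelium geometries here the two rules coincide.
Dead-cell remnants are nuclei whose centroid falls inside a lumen
object, each assigned to that lumen.

## Form-factor estimation

`FF = 4*pi*A/P^2` is exquisitely sensitive to the perimeter estimator,
and no off-the-shelf raster estimator reproduces the closed-form values
of the three calibration shapes used here (disc: FF 1.0; square:
π/4 ≈ 0.785; 1×10 bar: ≈ 0.260) simultaneously — weighted
boundary-step estimators collapse on 1-px-thin objects, and Crofton
estimators under-measure axis-aligned rectangles. The package therefore
fixes its own documented estimator:

1. extract the object boundary as the marching-squares iso-contour at
   level 0.5 (a sub-pixel polygon along pixel-box cracks with
   45° corner cuts); hole boundaries are included;
2. smooth each closed contour with a Taubin non-shrinking filter
   (λ = 0.3, μ = −0.34, 12 passes) to remove the rasterization
   staircase, which otherwise inflates perimeters of smooth oblique
   boundaries by ~5%; Taubin's pass-band design preserves genuine
   corners and thin-bar end caps that plain Laplacian smoothing would
   erode;
3. sum polygon edge lengths, and floor the result at the isoperimetric
   bound `2*sqrt(pi*A)` so the form factor of degenerate few-pixel
   objects cannot exceed 1.

Calibration values (area in pixel counts): disc r=64 → FF 0.966,
r=16 → 0.980, square 20×20 → 0.808, 1×10 bar → 0.293, 5×50 bar →
0.265. All are within ±0.05 of their closed forms, and the bar falls
below the 0.3 roundness cutoff while all discs clear it with margin.

## Epithelial extension

`EExt = sqrt(A_fol/pi) − sqrt(A_lum/pi)`, the difference of
equivalent-disc radii. For a concentric circular follicle this equals
the epithelial height exactly; for elongated or irregular follicles it
is a smoothed proxy that under-reports local height variation. The
quantity is translation- and rotation-invariant and scales linearly
with pixel size. **Caveat:** area-based epithelial-height proxies vary
between labs; this package's definition is the one stated here, chosen
for exactness on circular geometry, and should be named when reporting.

## Cohort statistics

Measurements from different animal cohorts are divided by the mean of
the wild-type controls of their own cohort and metric, making the WT
fold change exactly 1 per cohort. Dunnett's many-to-one procedure
(`scipy.stats.dunnett`) tests each genotype against WT at family-wise
α = 0.05, operating on the fold-change scale — the scale on which
cohorts are poolable. Consequently p-values are invariant to rescaling
all raw values of a metric but not to additive shifts (ratios are not
shift-invariant). The test unit defaults to animal means (one value per
animal, replicate sections averaged first); `unit="observation"` keeps
individual rows for sensitivity checks. The adjusted p-value is
evaluated by randomized quasi-Monte Carlo integration of the
multivariate t; the generator is pinned so identical tables give
identical p-values (integration jitter is ~1e-4 and far below any
decision threshold). Band densitometry is supported only as the ratio
`band / lane_total` with `lane_total > 0`.

## Phantom generator

The generator renders the tissue model directly, with exact bookkeeping:

* Follicle centers are drawn by rejection sampling with a 5-px minimum
  gap between outer boundaries (follicles in mid-sections are discrete
  and non-touching); placement failure after 2000 attempts raises an
  error naming the follicle.
* Per follicle: lumen radius and epithelial thickness are uniform in
  their configured ranges. The basal lamina is rendered as the
  outermost 1-px shell of the epithelial annulus in the marker channel,
  so (a) its skeleton is the shell itself and the propagation barrier
  sits exactly at the truth follicle boundary, and (b) lamina signal
  lies inside the cytoplasm mask and therefore counts as intracellular
  marker, as the compartment bookkeeping requires. The truth "follicle"
  object excludes this 1-px line, matching what barrier-limited
  propagation measures.
* Nuclei are 7-px discs blurred with a 0.8-px Gaussian, placed with
  ≥ 9.5 px center spacing so that blob detection can recover counts
  exactly; if a follicle's epithelium cannot hold the drawn number at
  that spacing, the achieved count is recorded in the truth table (the
  truth always describes what was rendered). Dead-cell remnants are
  placed inside lumina: `n_dead = round(f/(1−f) · n_epithelial)`, i.e.
  dead cells are the fraction `f` of all rendered nuclei.
* Marker compartments: intracellular signal (lamina shell + vesicular
  puncta at 0.6 amplitude) is rendered first; the diffuse luminal value
  is then set so the luminal share of total marker signal equals
  `luminal_marker_fraction` exactly on the noiseless image. Truth sums
  are taken before noise.
* Noise is additive Gaussian, clipped below 0. Defaults: 2048×2048 px
  at 0.62 µm/px, 30 follicles, lumen radii 18–55 px, epithelium
  12–18 px, 8–20 nuclei per follicle, dead-cell fraction 0.04, luminal
  marker fraction 0.31, noise SD 0.01. The pixel size is a free choice
  (the original acquisitions' magnification is not standardized) and is
  exposed in the spec.

**What the phantom does not emulate:** optical PSF and resolution
anisotropy, uneven illumination, autofluorescence, chromatin texture,
partial-volume effects of 3-D sectioning, touching or collapsed
follicles, and stromal tissue between follicles. Passing recovery tests
on phantoms therefore demonstrates the correctness of the measurement
logic, not robustness to real-microscopy artifacts; thresholds for real
batches must still be chosen per acquisition batch.

## Numerical conventions

Rasters are row-major with 0-based indices; pixel area is
`pixel_size²`; all reported areas are µm². Thresholding is inclusive
(≥). Interactive object editing is replaced by a reproducible override
operation (drop listed labels / add objects from a provided mask).
Default batch thresholds (marker 0.75, cytoplasm 0.35, nuclei 0.40,
tissue 0.12 on the [0, 1] scale) are calibrated on phantoms, since no
reference manual values exist; an Otsu fallback is available but off by
default. The heat map uses a linear, clipped mapping of lumen area onto
a fixed colormap with an explicit `vmax` (default 12 000 µm²) instead
of a manually inserted reference object, trading visual convention for
bit-reproducibility.

## Problem sizes

The shipped analysis uses 1024² sections with 12 follicles and 4
animals per genotype group, and the recovery tests use 512²–2048²
phantoms; all sizes are configurable and were chosen as the smallest
fields that exercise every pipeline stage with realistic object counts.
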