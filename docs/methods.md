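# Methods

`echolv` implements a semi-automatic pipeline for segmenting the left
ventricular (LV) cavity in dynamic 2D-echocardiography 4-chamber sequences
over a complete cardiac cycle, and for deriving the area variation curve
(AVC) and area variation fraction (AVF). This note records the model, the
parameter choices, the numerical decisions, and the known limitations.

## Pipeline

The method assumes a sequence covering two consecutive cardiac cycles with
ECG R-wave frame markers, and a single manual input: an atrioventricular
barrier (a horizontal pixel segment) placed over the mitral valve in the
first frame.

**Preprocessing** (five stages, each mapping [0, 1] images to [0, 1] images
of the same shape):

1. *ECG-synchronized time averaging.* Composite frame `k` is the pixelwise
   mean of frames `k` and `k+1` of each of the two R-wave-aligned cycles
   (four frames). At a cycle's last frame, `k+1` wraps to the cycle start
   (cardiac periodicity); if the second cycle is shorter than the first,
   indices beyond its end fall back to two-frame averaging within cycle 1.
   Averaging halves the effective temporal resolution: a composite frame's
   content (including the valve state) spans its two-frame window, which the
   phantom's ground-truth helpers (`valve_open_any_window`,
   `window_valve_row`) account for.
2. *Shift-invariant wavelet denoising* (optional; intended for noisy
   acquisitions). Undecimated 2-D transform, Daubechies-12, 4 levels, soft
   thresholding at the universal threshold `sigma * sqrt(2 ln n)` per
   level. The noise scale is the median absolute deviation of the finest
   diagonal band (÷0.6745); with the normalized transform the band noise
   level halves per coarser level, so each level is thresholded on its own
   scale (a single global threshold would erase coarse structure and
   over-smooth). When the estimated scale falls below the 16-bit
   quantization step the stage returns its input unchanged, keeping it an
   exact identity on clean images. Circular-shift equivariance is exact
   when no boundary padding is needed (image sides divisible by
   `2^levels`); otherwise reflective padding limits it to the interior.
3. *Edge enhancement.* `clip(m − α · (LoG_σ ∗ m))` with gain α = 1 and
   scale σ = 2 px. The discrete Laplacian-of-Gaussian kernel is truncated
   at 4σ and corrected to sum exactly to zero so the filter responds only
   to structure, never to the mean level (identity on constants).
   Borders are reflective.
4. *Grayscale morphological smoothing:* closing(r=1) → opening(r=1) →
   closing(r=3), Euclidean-disk structuring elements
   (offsets with `i² + j² ≤ r²`). Removes isolated extrema that would seed
   spurious watershed basins.
5. *Homotopy modification.* Threshold `T` = lower-median pixel intensity:
   in a frame focused on the ventricle at least half the pixels belong to
   dark blood pool or scan sector, so the median separates blood-level
   minima from bright-tissue noise minima. Markers are seeded at the
   regional minima with value ≤ `T` and, by default, *consolidated* to the
   full connected component of the sub-threshold set containing them (a
   closing with a disk of radius 3 bridges speckle gaps, and enclosed
   above-threshold islands are hole-filled). Consolidation is essential on
   speckled data: residual texture leaves many separate shallow minima
   inside one blood pool, and seeding each individually would dam the pool
   into fragments — precisely the supersegmentation this stage exists to
   prevent. Minima imposition is by grayscale reconstruction by erosion
   (Soille's construction, rescaled back into [0, 1]), after which the
   image's regional minima are exactly the marker components
   (oracle-checked in the tests).

**Segmentation** (per composite frame of cycle 1):

1. *Barrier insertion.* The barrier pixels are set to the maximum intensity
   in the homotopy-modified image, and removed from the marker mask (with
   components relabelled). Both steps are needed: marker-controlled
   flooding seeds one basin per marker component, so a bright line alone
   cannot split an already-connected blood-pool marker spanning the open
   valve. Secondary (static) barriers are handled identically.
2. *Marker-controlled watershed by immersion*, implemented in-package
   (numba-compiled priority flood with an explicit binary heap; a pure
   NumPy/heapq fallback is used if numba is unavailable). Deterministic
   semantics: pixels are popped in order of (intensity, insertion age);
   insertions happen while scanning settled pixels in raster order and
   neighbours in a fixed row-major order; a popped pixel whose settled
   8-neighbours carry one distinct label joins that basin, one seeing two
   or more labels becomes a dam pixel (label 0, Meyer's rule) and spreads
   no further; pixels enclosed entirely by dams keep label 0. The tests
   hold this kernel to *exact* agreement with an independent
   linear-scan implementation of the same documented semantics.
3. *Region selection.* The basin containing the reference point (the
   barrier midpoint raised by a quarter of the image height — inside the
   ventricle by construction) is selected; without one, the largest basin
   whose centroid lies in the central window (middle half of each
   dimension) wins. The ref-point rule takes priority because a
   neighbouring basin that annexes myocardium or scan sector during
   plateau flooding can out-size the ventricle while remaining nominally
   central.
4. *Contour correction.* The watershed boundary typically sits within the
   myocardium, so the basin over-estimates the cavity. The blood/muscle
   threshold is 0.5 × the mean *time-averaged* intensity over the basin's
   boundary pixels (the later enhancement stages distort tissue
   intensities, so the stage-1 composite is the intensity source). The
   at-or-above-threshold pixels inside the basin form the muscle mask
   (smoothed by binary closing+opening, disk r=3); subtracting it estimates
   the cavity, which is smoothed (closing+opening, disk r=9), clamped to
   the basin, and reduced to its largest component. Containment
   `corrected ⊆ basin` therefore holds exactly. Barrier pixels are excluded
   from the corrected mask and the area count (the barrier is an artificial
   border, not anatomy).
5. *Barrier tracking.* The barrier keeps its prescribed x-range; its row
   moves to the lowest-positioned pixel of the previous frame's *corrected*
   mask. Tracking from the corrected cavity rather than the raw watershed
   region is a deliberate choice: the basin's outer boundary meanders
   within the myocardium speckle-dependently, making its lowest pixel a
   biased, high-variance estimator of the mitral plane, while the corrected
   mask's lowest pixel is the blood/endocardium interface itself. Frames
   that fail segmentation are flagged and skipped (keeping the previous
   barrier); a run fails only if more than half the frames do.

**AVC / AVF.** Area per frame = foreground pixel count × pixel area
(`dy·dx` mm² → cm²); failed frames stay as visible gaps (no interpolation).
End-diastole is the first segmented frame strictly after the R wave
(`ed_at_r` switches to the at-R convention), end-systole the frame of
minimal area (earliest on ties), and AVF = 100 × (A − E)/A.

**Agreement metrics.** RMSd (root mean squared distance between
index-paired contour points after both contours are re-rooted at their
minimal-(y, x) pixel, oriented clockwise, and the longer evenly decimated
at indices `round(i·L/N)`), CCC (Pearson correlation of the mean-removed
binary masks), PE (`100·||A|−|M||/|M|`), and ES
(`100·(|A∩M̄|+|Ā∩M|)/|M|`). Index pairing (rather than optimal
assignment) is a fixed, deterministic convention. In `correct_contour` the
boundary *set* (pixels with a 4-connected background neighbour) replaces
the ordered trace, since only the mean intensity is needed and jagged
basins make ordered tracing fragile; ordered contours (Moore boundary
trace with state-cycle termination) are used for outputs and metrics.

## The phantom

The synthetic generator emulates an apical 4-chamber acquisition zoomed on
the LV. Defaults are the study conditions: 256×256 frames, 37 frames per
cycle at 44 Hz, two cycles, 0.5×0.5 mm pixels, ED/ES cavity area fractions
0.20/0.128 (true AVF ≈ 36%, realized within ±1.5 points by
rasterization), mitral valve open during cycle fraction [0.5, 0.95),
unit-mean multiplicative gamma speckle with dispersion 0.15 (shape
1/0.15²), and a ±0.02 cycle-to-cycle intensity offset. Noise is drawn
from one `SeedSequence` child per frame, so per-frame speckle is
reproducible independently of evaluation order.

Geometry, chosen once to reflect the anatomy the method relies on:

* the cavity is a truncated ellipse (apical taper, flat base) whose
  vertical semi-axis is solved per frame by bisection so the rasterized
  area follows a piecewise-cosine two-phase profile (systolic shrink to ES
  at cycle fraction 0.35, diastolic refill) — area change is predominantly
  longitudinal, with the base descending during filling;
* the basal border is saddle-shaped: the central valve segment sits 5 px
  apical of the lateral hinge corners, so the cavity's lowest pixels are
  the corners. The initial barrier spans the valve segment only; the
  corners stay outside it and keep driving the automatic vertical
  tracking (a barrier spanning the full base would pin its own tracking);
* a bright (1.0) specular endocardial line, 4 px thick, wraps every
  blood/tissue interface, with 0.7 myocardium behind it; the watershed
  ridge therefore sits at the interface line. The myocardial shell is
  thick (40 px) so that bright tissue fills just under half the frame and
  the median intensity lands at the top of the blood-pool mode at every
  cardiac phase — the zoomed-acquisition regime the homotopy threshold
  assumes;
* a dark atrium sits below the wall (top edge tracking the base, fixed
  bottom), and during the open-valve window a 20 px channel pierces the
  wall, merging the two blood pools exactly as the open mitral valve does;
* the dark scan sector outside the shell is split by the heart touching
  the top and bottom image borders, so background basins stay peripheral;
* the whole scene is blurred with a σ = 1 px Gaussian point-spread before
  speckle is applied.

What the phantom does **not** model: anisotropic point-spread and depth
attenuation, rib shadowing and reverberation artifacts, intensity
inhomogeneity across the sector, leaflet motion (the valve is a binary
open/closed channel), out-of-plane motion, and heart-rate variability
beyond a global intensity jitter. Passing the recovery tests therefore
shows the pipeline is internally consistent and robust to fully developed
speckle at the stated level — not that it meets any particular accuracy on
clinical images.

The operator-variability harness draws `n_operators × n_reps` initial
barriers with endpoints jittered uniformly within ±(dx, dy) of the true
barrier, runs the full pipeline for each (sharing the barrier-independent
preprocessing), and reports per-frame mean area, per-frame standard
deviation as a percent of the mean, and the AVF spread across runs.

## Numerical choices and degenerate inputs

* Lower median (element `(n−1)//2` of the sorted values) and
  earliest-index tie rules throughout, for determinism.
* Watershed flooding ties break by insertion age; insertions occur in
  raster order, making the partition deterministic and platform-stable.
* Constant images: every preprocessing stage is an exact identity;
  homotopy modification treats any image with range ≤ 1e-9 (float rounding
  from the convolution stages) as a single plateau minimum.
* Contours: single-pixel masks yield a length-1 contour; empty or
  multi-component masks are validation errors. The Moore trace terminates
  on the first repeated (pixel, backtrack) state, which handles convoluted
  blobs whose boundary cycle does not include the artificial initial
  state.
* CCC is undefined (error) for constant masks; PE/ES require a nonempty
  reference mask; AVF requires `0 < E ≤ A`.
* 8-bit rasters are rescaled by 1/255, 16-bit by 1/65535.

## Validation summary

The test suite checks exact metric identities, exact equivalence of the
watershed kernel and the agreement metrics with independent brute-force
oracles, stage-level preprocessing contracts, the containment invariant
across seeded phantom runs, parameter recovery on the default phantom
(AVF within 4 points of truth; mean per-frame PE below 12%; mean CCC above
0.90), the necessity of the barrier (without it, the selected basin on
open-valve frames exceeds the true cavity by well over 30% through atrial
leakage; with it, it does not), and the variability harness (zero jitter
reproduces bit-identical runs; ±(3, 2) px jitter over 40 runs leaves the
AVF spread below 2 points). `scripts/acceptance.py` recomputes these
quantities from scratch. Problem sizes (default phantom, 37 composite
frames, 40-run harness) were chosen to make the whole validation run in a
few minutes on one CPU.

## Known limitations

* The corrected boundary sits on the bright interface skirt, biasing areas
  ~2-3 px outward (a few percent of area, cancelling in the AVF); the
  tracked barrier row inherits the same small positive bias relative to
  the true hinge row.
* During the open-valve window the tracked barrier follows the open
  valve's dark throat rather than the annulus, so its row deviates more
  there; the AVC is barely affected because the hinge corners bound the
  cavity laterally.
* The watershed partition depends on the documented tie rules; other
  watershed implementations (different tie-breaking, no dam pixels) will
  produce slightly different basins on plateaus.
* Undecimated wavelet denoising at 4 levels needs image sides ≥ 16 and
  pads non-multiple sizes reflectively, which breaks exact shift
  equivariance near borders.
* Only the first cycle is segmented (the second supplies the averaging
  partner), matching the two-cycle acquisition design.
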