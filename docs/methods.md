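# Methods

## Scope and model

`granulemap` quantifies punctate fluorescence structures — mitochondrial
RNA granules (MRGs), dsRNA foci, nucleoids — in calibrated multi-channel
2-D images, the way such structures are analysed in studies of
mitochondrial gene expression:

1. **Object-based colocalization.** Each channel is thresholded into
   foci (8-connected components of above-threshold pixels). For every
   *query* focus the pixel intersection with the *union* of the
   *reference* channel's foci is counted exactly and expressed as a
   percentage of the query focus's own area. Foci are classed
   **none** (0% intersection), **complete** (≥ 100 − tol %, default
   tol = 1), or **partial** (anything in between), and a frame summary
   reports the three classes as percentages of all query foci measured.
   Intensity-correlation coefficients (Pearson, Manders) are
   deliberately out of scope; the method is object-based.
2. **Shape descriptors.** Per focus: area (pixel count × pixel_size²,
   exact), major/minor axis of the ellipse with the same normalized
   second central moments as the pixel set (axis length = 4·√eigenvalue
   of the pixel covariance, so a disk's axes equal its diameter), and
   eccentricity √(1 − (minor/major)²). Single-pixel and collinear foci
   are degenerate: they get one-pixel axes and are flagged.
3. **Mask-containment filtering.** Foci must lie within the
   mitochondrial-network mask. "Lie within" is configurable: centroid
   pixel inside (default), strict majority of pixels inside, or at
   least one pixel inside. The rule used is always logged.
4. **Per-cell quantification.** Cells are seeded from nuclei (DAPI) and
   grown over the cell-body foreground by watershed on the
   distance-to-nucleus map, so cells partition the foreground and each
   contains exactly one nucleus. Per cell: foci count and density per
   µm² of mitochondrial network, mean intensity inside the
   mitochondrial submask, integrated (summed) intensity over the cell,
   cytoplasmic area (whole cell minus nucleus; configurable to whole
   cell), and mitochondrial area.
5. **Cell-cycle gating.** Phases are called from marker means with the
   precedence S → G2 → G1: nuclear EdU positivity wins (EdU marks
   active replication and cyclin-A is present in both S and G2), then
   cyclin-A positivity marks G2, then a DAPI-positive nucleus is G1;
   otherwise the cell is unassigned. Cyclin-A is measured over the
   whole cell by default (nuclear-only is a config option, since
   staining protocols differ in compartment).
6. **Summaries.** Group tables report n, mean, and sample SD (n − 1
   denominator; missing for singletons). Inferential statistics are out
   of scope.

## Synthetic data generator

No public microscopy accompanies the quantities this package computes,
so the generator is a first-class module that renders frames with known
ground truth at the two imaging regimes the measurements come from.

**STED-like regime (default).** 512×512 px at 0.02 µm/px. A tubular
mitochondrial mask is built from correlated random walks dilated to the
tube width (0.3 µm) until coverage reaches `network_density` (0.2);
walks add ~1.5% coverage each, keeping the result within ±20% of the
request. Two foci channels are planted inside the network: dsRNA
(query, mean area 0.019 µm²) and BrU (reference, 0.017 µm²), 100 foci
each, areas lognormal with CV 0.3, rendered as constant-intensity
rasterized disks (plateau 200). The planted overlap composition
defaults to 3% complete / 65% partial / 32% none — the composition
observed for dsRNA versus nascent BrU-RNA — with per-category counts
from the largest-remainder rule.

Planting is exact on pixels:

- *complete*: a disk concentric with its reference partner, at least
  one pixel of radius smaller (partners are chosen to fit the sampled
  query radius where possible), hence 100% contained and robust to
  blur-induced boundary shifts;
- *partial*: a disk with the query channel's own sampled radius, offset
  from its partner along a random direction; offsets are searched so
  the rasterized intersection fraction falls inside
  `partial_overlap_range` (default 0.3–0.7) and never touches any other
  reference focus, so the planted fraction *is* the measured truth;
- *none*: placed with a clearance gap (3 px + 2 PSF sigmas) from every
  reference focus;
- foci within one channel keep a ≥ 4 px boundary gap so they remain
  separate 8-connected components even after blur-grown contours.

**Confocal-like regime (`GeneratorParams.confocal`).** 0.1 µm/px with
whole cells on a jittered grid: circular cells (radius 2.4 µm) with
nuclei (0.9 µm), a per-cell perinuclear network (walks seeded inside
each cytoplasm, coverage 0.45 of the annulus, tube 0.7 µm), DAPI, EdU,
cyclin-A, and a uniform cell-body channel for region growing. Phases
follow `phase_mix` (G1 0.5 / S 0.3 / G2 0.2, largest-remainder counts);
each cell draws its marker level from a normal with the positive or
negative mean for its phase (defaults 150/15, SD 12 — cleanly
separable, as gating markers are in practice). Cell radii are an
order of magnitude below physiological so that hundreds of cells fit a
desk-scale frame; none of the per-cell statistics depend on absolute
cell size. Apparent focus area in this regime is 0.10 µm²
(PSF-broadened sizes, not the super-resolved ones).

**Noise model.** Gaussian PSF blur (σ 0.04 µm STED-like, 0.1 µm
confocal-like), then scaled-Poisson shot noise, then additive Gaussian
read noise (SD 20 ≈ SNR 10 against the focus plateau), clipped at zero.
`noiseless()` disables all three, in which case the rendered channels
equal the planted rasters exactly.

**Determinism.** All randomness flows from `seed` through named
`SeedSequence` streams; identical parameters give bit-identical frames
and truth tables.

## Matched-recovery configuration

Truth-recovery runs segment foci with an absolute threshold matched to
the generator, the analogue of the manual thresholding used on real
images:

- noiseless frames: threshold = plateau/2, no smoothing → planted pixel
  sets, counts, and categories are recovered exactly;
- noisy frames: 1 px Gaussian pre-smoothing (matched filter at PSF
  scale) and threshold = plateau/4. The lower cutoff is needed because
  PSF blur dims the smallest foci below half the plateau; at a quarter
  of it the faintest planted focus still clears the threshold by ~9
  residual-noise SDs while the background stays far below. Under this
  configuration the mean recovered composition over 10 seeds is within
  ~1 percentage point of the planted one per category.

## Numerical choices

- **Thresholding** defaults to Otsu (the reproducible stand-in for
  manual thresholding) with an absolute override; the cutoff used is
  recorded on every mask and in the run log. Otsu on a constant
  non-zero image raises (degenerate histogram); an all-zero image gives
  an empty mask.
- **Per-cell marker gating** uses an exact exhaustive-split Otsu on the
  per-cell marker means (histogram Otsu is unstable on a few dozen
  values); the cutoff is the midpoint of the optimal split. The DAPI
  minimum is 0.2× the median nuclear DAPI (a presence check). All three
  cutoffs can be overridden.
- **Nucleus detection** smooths DAPI at nucleus scale (σ 2 px) and
  applies a contrast gate (foreground mean ≥ 2× background mean):
  Otsu splits even pure noise, and the gate is what lets frames without
  nuclei pass through the pipeline without fabricating cells.
- **Connectivity** is 8-neighbour everywhere; coordinates are 0-based
  (row, col) at pixel centers; centroids are unweighted pixel-center
  means.
- **min_size** defaults to 4 px (rejects single-pixel noise at
  super-resolution sampling).
- **complete_tol** defaults to 1%: strict 100% containment is fragile
  to single boundary pixels under rasterization; the tolerance is
  configurable.
- **Largest-remainder rounding** (ties broken by key order) keeps
  planted category and phase counts summing exactly to the requested
  totals.
- **Focus-to-cell assignment** is by centroid; foci outside all cells
  are dropped and counted in the log.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
frames generated at call time: 512×512 STED-like frames with 100 foci
per channel (10 seeds for category recovery), 1024×1024 confocal-like
frames with 100–200 cells (10 seeds for narrow-separation phase
recovery), 200 random blob pairs for the pixel-count oracle, and paired
end-to-end runs for byte-level determinism.

## What passing tests do and do not show

The generator reproduces the *geometry* the analysis contracts depend
on — tubular masks, disk-like foci with controlled overlap, separable
marker populations, Poisson–Gaussian noise — so recovery tests validate
the measurement pipeline: exact pixel accounting, correct
categorization, correct gating logic, determinism. They do not certify
performance on real micrographs, where foci are not disks, backgrounds
are structured, networks are imaged with anisotropic PSFs, and marker
populations overlap for biological reasons. Thresholds on real data
remain the operator's responsibility, which is why every threshold is
configurable and logged.

## Known limitations

- 2-D only; no 3-D stacks, deconvolution, flat-field or drift
  correction, photobleaching, or time series.
- The Gaussian PSF is isotropic; no realistic optics.
- Watershed cell growing assumes roughly convex cells around their
  nuclei; heavily overlapping or irregular cells will be split along
  distance geodesics, not true membranes.
- Phase gating is a three-marker decision rule, not a cell-cycle model;
  DAPI content (2N/4N) is not used.
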