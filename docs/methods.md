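# Methods

This note documents the models, estimators, parameter choices and known
limitations of `ertrack`. It covers what each stage assumes, what the
synthetic generator does and does not emulate, and the design decisions
taken where more than one reasonable convention exists.

## Coordinate and unit conventions

Coordinates are `(x, y) = (column, row)`, 0-based, with pixel centers at
integer positions. Physical calibration defaults to 0.134 µm/px and
0.05 s/frame (a 100×/1.45 objective and 20 Hz streaming); both are
configurable and written into every run's resolved config. Distances in
the ER index are kept in pixels — only the sign of the index enters
classification, so the unit is inert there.

## Synthetic-microscopy generator

The generator produces the study conditions the analysis was built for,
with known ground truth.

- **Field**: one cell per field, default 256 × 256 px (~34 µm), the
  footprint of a typical adherent HeLa cell.
- **ER geometry**: persistent random-walk tubules dilated to ~3 px plus
  an optional central sheet ellipse; default area fraction ~0.15–0.24.
  The rendered ER channel is the mask scaled to a fixed intensity and
  blurred (σ = 1 px). The ER is static across the movie — real ER
  remodels on the seconds scale, which this generator does not emulate,
  so passing tests say nothing about segmentation robustness to ER
  motion.
- **Particles**: two populations. Free particles take 2D Brownian steps
  with per-axis variance 2DΔt, reflected at field borders; ER-tethered
  particles take Brownian steps with a proposed step rejected (position
  repeated) whenever its rounded position leaves the ER mask. Rejection
  confinement is the simplest model that yields slow, ER-resident
  tracks; it is not harmonic tethering and produces slightly
  sub-Brownian short-lag statistics for the tethered class, which is
  immaterial because only the order of magnitude relative to the
  mobility cut-off matters. Defaults D_tethered = 0.01,
  D_free = 0.3 µm²/s straddle the 0.06 µm²/s classification cut-off
  from either side; a default scene holds 40 particles (12 tethered,
  28 free), which yields roughly 30–55 tracks ≥ 30 frames per cell —
  the per-cell bookkeeping range of the real acquisitions.
- **Rendering**: each particle is an isotropic 2D Gaussian (σ = 1.3 px,
  peak amplitude 200 over background 100) summed onto the background;
  Poisson shot noise plus Gaussian read noise (σ = 2); output uint16.
  The implied peak SNR of ~11 is an assumption, not a reproduction —
  photon budgets for the original movies are not published.
  Photobleaching, blinking, z-defocus and EMCCD excess noise are not
  simulated; the analysis operates on single-plane 2D tracks and none
  of the tested statistics depend on these effects.
- **Bead pairs**: channel A holds Gaussian beads at random positions,
  channel B the same beads through a known affine, with optional
  localization noise; used to validate registration round-trip.
- **Foci scenes**: cells at uniform background with disc foci at a
  known fold-enrichment; the truth fraction is computed from noiseless
  intensities.
- **smFISH-IF scenes**: cells as discs with a DAPI nucleus, cytoplasmic
  background in the mRNA channel, mRNA spots in the cytoplasmic
  annulus, and a translation-site (GFP) partner spot within 1 px for a
  `round(fraction · n)` subset; spots have a Gaussian axial profile
  over adjacent z-slices.

Every generator is deterministic given its parameters and seed.

## Spot detection

Scale-normalized negated Laplacian of Gaussian (σ = radius/√2, filter
truncated at 8σ so constant images give numerically zero response),
local maxima with disc-footprint non-maximum suppression, quality
threshold in response units, and closed-form quadratic 3×3 subpixel
refinement clamped to ±0.5 px per axis. Quadratic refinement
approximates Gaussian maximum-likelihood localization; at SNR ~10 it
localizes isolated spots to ≲0.1 px RMSE with recall 1.0 for spots
separated by ≥ 5 px. Sub-resolution pairs are merged by construction —
no deconvolution is attempted. Quality thresholds are per-channel
config values set manually, as in the original workflows; there is no
automatic thresholding.

## Registration

Bead fields are paired by mutual nearest neighbors (sufficient for
sparse TetraSpeck fields; the descriptor-based matching of
general-purpose registration plugins is unnecessary here) and fitted
with a least-squares 6-parameter affine. The fit is exact (residual
< 1e-9 px) on noise-free data and degrades gracefully with
localization noise. In the live pipeline the affine is applied to
*coordinates*, never by resampling the particle movie, preserving
subpixel localizations; image resampling (bilinear, zero-filled) exists
for visualization only. The bead-matching radius (default 10 px) is a
free parameter — the original calibration tolerance is not published.

## Tracking

Greedy frame-to-frame linking: candidate links to open track heads are
sorted by ascending distance and assigned one at a time, each detection
used once; links require distance ≤ max_disp (default 8 px = 4σ of the
fastest expected per-frame step, ⌈4·√(4·D_free·Δt)/pixel⌉); a track may
bridge ≤ max_gap empty frames with the threshold scaled by √(gap+1);
singletons are discarded. Global (LAP) assignment was deliberately not
used: at these densities the solutions differ negligibly, and the
greedy rule is verifiable against exhaustive enumeration on toy
instances.

**Known limitation — identity switches.** When two fast particles
approach within a few pixels, no frame-to-frame nearest-neighbor
assignment (greedy or global) can keep their identities straight, and
diffusive re-encounters make at least one swap per encounter nearly
certain. Measured on default synthetic scenes, ~85–90% of tracks
≥ 30 frames follow a single ground-truth particle; the remainder swap
between two particles of (almost always) the same population, which
leaves the per-cell classification statistics essentially unbiased but
means individual track identities should not be over-interpreted.
Motion-model (Kalman) linking, which could help, is out of scope.

## ER association

- **Segmentation**: Gaussian smoothing (default σ = 0: the PSF already
  band-limits the signal; raise for low-SNR single frames) followed by
  Otsu, fixed, or probability-map (≥ 0.5) thresholding, with removal of
  objects < 9 px. The live pipeline segments the time-averaged ER
  channel. This replaces the trainable pixel classifier of
  interactive workflows — no training data ships with this package —
  and external probability maps can be ingested instead.
- **Signed distance map**: +EDT to the nearest background pixel on the
  mask, −EDT to the nearest mask pixel off it; degenerate all-on /
  all-off masks are capped at ± the image diagonal. Verified exactly
  against an all-pairs brute-force oracle.
- **Cumulative index**: the map is sampled at each detection's nearest
  integer pixel (the distance map consumed as an image); bilinear
  interpolation is available as an option. The index sums these values
  over the track. An alternative reading — summing probability-map
  intensities directly — is supported by segmenting in probability
  mode; distance-sum is the default.
- **IDC**: lag-1 MSD/(4Δt) over consecutive-frame pairs only
  (gap-bridged pairs excluded). This estimator is unbiased for
  Brownian motion (calibration on 500 simulated tracks recovers
  D = 0.02 and 0.3 µm²/s within ±5%); localization noise adds a small
  positive offset ~σ_loc²/Δt (~0.004 µm²/s at 0.1 px RMSE), well below
  the 0.06 µm²/s cut-off. Note the published description of the
  quantity ("mean of displacements") is dimensionally a length; the
  µm²/s scale of the reported axes forces the squared, normalized form
  used here, and exact numerical equivalence with the original
  workflow's component is not claimed.
- **Classification**: ER-associated ⟺ IDC < 0.06 µm²/s (strict) and
  index > 0 (strict). Per-cell fractions use tracks ≥ 30 frames and
  cells with ≥ 3 such tracks. Cell assignment takes the ROI label
  under the track's median position; without an ROI mask the whole
  field is one cell (one cell per field is the acquisition geometry).

End-to-end on default scenes (10 cells × 50 particles), true tethered
fractions 0.05/0.3/0.6 are recovered within ~0.02 on average — the
residual bias is a slight dilution of the denominator by fragmented
free tracks.

## Foci quantification

Per cell: background = median intensity over the cell mask (robust to
the foci, which cover few pixels; the original definition of "cellular
background" is not published, so per-cell median is this package's
documented choice); focus pixels are cell pixels ≥ fold × background
(inclusive, default fold = 5); foci are 8-connected components ≥ 4 px
(hot-pixel suppression; configurable, not from any publication);
a cell has foci when the foci share of total intensity is ≥ 1%
(inclusive). The criterion is a ratio of sums over the same cell, so it
is invariant to global intensity scaling, and raising `fold` can only
shrink the foci set.

## smFISH-IF

Max projection over z; separate LoG detection per channel; pairing as
mutual nearest neighbors with Euclidean distance ≤ 3 px in the
projection (interpreted in pixels, as specified for the original
analysis), ties broken to the lowest index; nuclei by Otsu on DAPI
(filled, size-filtered ≥ 50 px), cytoplasm by a manual threshold on
the smFISH background channel minus nuclei, cell instances by
watershed expansion of nuclear seeds through the cytoplasm. The
per-cell translating fraction counts cytoplasmic mRNA spots only
(whether the original denominator included nuclear spots is unknown;
cytoplasm-only is the documented default). Missed mRNA detections are
independent of translation status and so do not bias the fraction;
missed GFP detections bias it slightly downward and spurious mutual
pairs slightly upward — on default scenes with truth 0.5 the recovered
mean is within ±0.04.

## Problem sizes and numerical choices

Tests and the acceptance script use 10 cells × 50 particles × 100
frames per condition for the live pipeline, 500 tracks for IDC
calibration, 100 random instances for each brute-force oracle, and
9-cell smFISH scenes — sizes at which the measured quantities are
stable across seeds while a full validation run completes in about a
minute. Ties in nearest-neighbor queries and plateau maxima resolve to
the lowest index and are logged. Empty ER masks are valid (all
distances negative ⇒ no track can classify as associated); tracks with
no consecutive-frame pair have undefined IDC and are excluded with a
warning.
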