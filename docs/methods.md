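# Methods

`droptex` scores robotically captured images of protein-crystallization
droplets by the posterior probability that they contain crystals or
crystalline behaviour, and ranks the droplets of a plate into a viewing
order. This note records the models, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Texture model

Droplet texture is described with textons: prototype vectors of local
filter responses. Each pixel is filtered with a 38-kernel rotation-variant
bank — edge (first-derivative-of-Gaussian) and bar (second-derivative)
kernels at 6 orientations × 3 scales, plus an isotropic Gaussian and a
Laplacian of Gaussian — and the six orientation responses of each edge/bar
scale are collapsed to their maximum, giving an 8-vector per pixel that is
quasi-invariant to texture rotation (exact for 30° multiples, up to
resampling error). The per-image descriptor is the frequency histogram of
nearest-texton labels (Euclidean distance) over droplet pixels.

Parameters of the bank:

* `scale_factor` (default 0.5): multiplies all σ of the full-scale bank.
  The full bank uses (σ_perp, σ_elong) ∈ {(1,3), (2,6), (4,12)} px for the
  oriented kernels, σ = 10 px for the Gaussian/LoG, and a 49×49 support;
  the default half-scale bank scales every σ by 0.5 and therefore uses a
  25×25 support, which is also what the 13-pixel boundary-extension pad
  (half the filter size + 1) assumes.
* Kernel normalization: oriented and LoG kernels are zero-mean with unit
  L1 norm (standard texton practice, keeps response magnitudes
  commensurate); the Gaussian sums to 1.
* Convolution uses reflected borders; pixels within half a support of the
  image border are flagged and never counted in histograms.

## Dictionary construction

The dictionary is built in two stages from two seeded synthetic training
sets (100 precipitation wells, 52 crystal-containing wells — the sizes of
the corresponding real training sets):

1. Per image, pixel response vectors are clustered with a
   variational-Bayes Gaussian mixture (Dirichlet-process weights, diagonal
   covariances, component cap 25, weight-pruning threshold 10⁻³, seeded).
   The cap and threshold are the only knobs; the effective number of
   components is chosen by the data, typically around 10 per image.
2. The pooled per-image centres are reduced by DP-means: a point farther
   than λ from every centre starts a new cluster, penalized λ² per cluster
   in the objective Σ‖x−μ‖² + λ²k. Precipitate-image centres and
   crystal-related centres are reduced separately and concatenated.
   "Crystal-related" is decided automatically: a centre qualifies when at
   least half of its supporting pixels fall inside the image's ground-truth
   crystal mask (the synthetic generator emits these masks; with real data
   this step would be manual curation).

The fixed-λ protocol (λ = 0.5) is supported directly. The shipped
reference dictionary instead calibrates λ by bisection so the final size
is exactly 300 entries; if no λ yields the exact count (the size is a step
function of λ), the smallest dictionary above the target is trimmed by
repeatedly averaging its closest pair. Entries are ordered with the
lowest-magnitude texton first and the rest by increasing distance to it.

DP-means implementation: the classic sequential sweep is order- and
initialization-dependent and systematically misses merges of clusters
separated by between λ and λ√2, where merging lowers the objective. We
therefore alternate assignment sweeps with objective-driven local moves
(cluster merges, single-point splits, size-corrected single-point
relocations) and restart from several seeded initializations (single
cluster, farthest-first partitions at k = 2…8, random partitions for small
inputs), keeping the lowest objective. On instances with ≤ 8 points this
reproduces the exhaustive-search optimum across hundreds of random cases;
at dictionary scale (~10³ centres) the relocation scan is disabled and a
single initialization is used for speed.

## Image-processing pipeline

1. **Greyscale + contrast**: luminance conversion, linear stretch to
   0–255.
2. **Registration and fault screening**: a per-subwell background (mean of
   empty-plate images) is registered to each image by exhaustive integer
   translation minimizing the mean absolute difference (ties → smallest
   |dx|+|dy|, then lexicographic). The frame-masked, z-scored well
   interior yields 54 gradient statistics (4 moments + 50 unit-width
   histogram bins centred 0…49, larger gradients clipped into the last
   bin) that join 6 droplet shape features (area, well-relative centroid,
   second-moment eccentricity, major/minor axis lengths; zeros when
   unsegmentable) in a 60-feature random forest (seeded, OOB-scored).
3. **Droplet segmentation**: gradient magnitude (Sobel of a σ=1-smoothed
   image) with registered-frame pixels zeroed, resampled to polar
   coordinates (1 px radial, 1° angular) about a seed centre (centroid of
   the background-subtracted foreground), then a circular shortest path
   (row step ≤ 1 per degree, closed) through the negated gradient. The
   polar cost is weighted by radius so the path optimizes the physical
   line integral of gradient along the contour; without this, 360-column
   sums favour small high-contrast loops around interior precipitate.
   A result is rejected — triggering a retry on a strongly gamma-corrected
   image (low-pass σ = 10) and then on a blurred one — when its area falls
   outside [2%, 95%] of the well interior, more than 10% of the boundary
   lies on the frame, or the minimum radius drops below 0.45× the median
   (a deep concave bite that a sessile drop cannot have; this third
   criterion is ours, added because partial dips onto dark masses pass the
   first two). If all attempts fail the droplet is flagged unsegmentable
   and excluded.
4. **Shadow correction**: per-pixel gamma, Î = 255·(I/255)^γ with
   γ = clamp(imLP/255, 0.05, 1) and imLP a Gaussian low-pass (σ = 1) of
   the image. Dark shadowed rims are lifted strongly; bright centres pass
   through. This form was chosen for its properties: monotone per pixel,
   range-preserving, with γ directly weighted by local intensity, and the
   0.05 clamp preventing blow-up in near-black regions.
5. **Boundary extension**: the cropped droplet (bounding box plus a 28-px
   margin so the ring fits inside the polar image of R = half the larger
   crop dimension) is resampled to polar form about its centroid; per
   angular column the 13 radii beyond the boundary are set to the median
   of the 10 innermost adjacent pixels, and only this ring is written back
   to Cartesian space (bilinear in r and θ, nearest-neighbour fill for
   ring pixels without a polar antecedent). Ring pixels never enter
   histograms.
6. **Standardize + downscale**: z-score over droplet pixels, bilinear
   downscale by `image_scale` (0.25 by default; 0.5 for imagers with
   roughly half the pixel pitch, targeting an effective working resolution
   of a few µm/px), then re-centred so the delivered array has mean 0 and
   unit variance to within 10⁻⁶.

## Ranking

A two-class random forest (500 trees, seeded) is trained on raw histogram
counts labelled interesting (human score ≥ 3: microcrystals and better)
versus uninteresting (score < 3 or unscored). Raw counts are used because
tree splits are monotone-invariant and droplet pixel counts carry size
information. No threshold is applied: the posterior of the interesting
class is the score, droplets are viewed in descending score order (ties
broken by image id for a reproducible order), wells optionally aggregate
their subwells by maximum score. The sorted scores of a plate form its
profile; the profile summary reports, per score cutoff, the fraction of
plates whose first true crystal would be found above the cutoff and the
mean fraction of uninteresting droplets below it, plus each plate's
first-crystal rank.

## Synthetic test bed

The generator renders what a plate imager sees: a dark plastic frame with
corner shadows, a sessile drop with a shadowed rim (depth 70 grey levels
over the outer 14% of the radius by default), and one of eight outcome
classes — clear, granular precipitate, needle/plate crystals (1–5 bright
convex polygons with straight high-gradient edges), microcrystal showers
(100–500 bright specks), smooth phase-separation blobs, and the three
dispensing/imaging faults (empty well, undersized drop, off-frame well).
Textures are tuned for controllable statistical structure, each class
exciting distinct filter channels, not for photorealism. Optional knobs
create known-hard segmentation cases: a reduced rim depth and a large,
very dark, soft-edged precipitate mass (the case the σ=10 gamma fallback
is designed to rescue). Every image is a deterministic function of
(spec, seed) and ships with ground-truth droplet and crystal masks.

What passing tests show — and do not show: recovery and enrichment results
on this generator demonstrate that the implementation is internally
correct (oracle-exact shortest paths and labelling, calibrated dictionary
size, segmentation that survives frames and dark masses, rankers that
separate classes the filter bank can see). They do not certify performance
on real droplet images, whose precipitation continuum, focus artefacts,
detergent drops and polarization colour effects the generator does not
model.

## Problem sizes and determinism

The shipped test suite uses a 300-entry dictionary built from the full
100+52 synthetic training sets, a 100-droplet segmentation suite, a
500-droplet training corpus with 10-fold cross-validation, and 20 test
plates of 15 droplets; these sizes keep a full run in the minutes range
on one core while matching the stated training-set sizes where they
exist. All randomness flows from explicit seeds (NumPy `SeedSequence`
spawning per image), so dictionary construction and every downstream
result are bit-reproducible for a given seed.

## Known limitations

* The VB-GMM stage inherits sklearn's variational approximation; the
  effective component count depends mildly on the cap and tolerance.
* Segmentation assumes the drop encloses its seed centre and is star-shaped
  about it (one radius per degree); pathological multi-lobed drops violate
  this.
* The fault classifier is trained on synthetic faults only; the >94%
  real-data accuracy reported for the original system is not reproducible
  here and is not claimed.
* The blurred-image segmentation fallback recovers gross failures but with
  lower boundary accuracy than the gamma-corrected retry.
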