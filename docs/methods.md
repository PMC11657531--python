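# Methods

## Problem and model

`brainvox` implements the quantification stage of a whole-brain cleared-tissue
imaging experiment: two groups of subjects (e.g. an amyloidosis mouse model
vs. non-carrier controls), each contributing a 3D immunofluorescence volume
per channel (amyloid plaques, microglia, tyrosine hydroxylase), registered to
a common atlas with a labeled region hierarchy. The analysis asks *where in
the brain do the groups differ*, and then *does that difference survive
direct, segmentation-based measurement in each subject's native image*.

The pipeline is:

1. **Preprocessing (tissue space).** Rolling-ball background subtraction,
   implemented as slice-wise grayscale opening (erosion then dilation with a
   disk). The disk radius is expressed in pixels of the image it is applied
   to: 20 px is the convention for full-resolution light-sheet data
   (~3.5 µm pixels, i.e. a ~70 µm ball), which corresponds to ~3 px at the
   25 µm atlas resolution the phantoms use. Capillary-like artifacts are
   flagged by a deterministic rule (voxels above an intensity quantile,
   grouped into 26-connected components, flagged when the principal-axis
   elongation of the component's coordinate cloud is ≥ 3) and zeroed. This is
   a rule-based stand-in for an interactively trained pixel classifier;
   externally produced masks can be supplied instead.
2. **Voxel-wise inference (atlas space).** Each subject's volume is z-scored
   inside a brain mask that excludes ventricles and undefined tissue
   (mask-restricted mean and population SD), smoothed with a Gaussian kernel
   (σ = 100 µm by default, interpreted per-axis in voxels), and entered into
   a two-sample permutation t-test. Group labels are the exchangeable unit;
   when the number of distinct balanced relabelings C(n, n_A) is at most the
   requested permutation count, the null is enumerated exhaustively and
   p = b/m with b counting assignments (including the observed one) whose
   statistic is at least as extreme; otherwise m random relabelings are drawn
   and the add-one estimator (b+1)/(m+1) is used so p-values are valid and
   never zero. Benjamini–Hochberg step-up FDR is applied over in-mask voxels
   at level q (0.2 for plaque/microglia channels, 0.4 for TH), reporting the
   realized adjusted-p cutoff. Significant voxels are clustered by connected
   components — positive-t and negative-t voxels separately, so adjacent
   opposite-sign effects never merge — and components below the extent
   threshold (400 voxels for plaque/microglia, 100 for TH) are discarded.
3. **Cluster validation (tissue space).** Each surviving cluster is warped to
   each subject's full-resolution native grid (nearest neighbour through the
   inverse of the stored tissue→atlas affine). Label density is
   100 × (segmented voxels in cluster)/(cluster voxels); cell density is the
   number of 6-connected segmentation components whose centroid voxel lies in
   the cluster, divided by the cluster's physical volume in mm³ (optionally
   restricted to an anatomical mask). A cluster is *valid* when an unpaired
   pooled-variance one-tailed t-test in the direction of the voxel-wise sign
   gives p < α = 0.05.
4. **Regional composition.** Valid clusters are intersected with the atlas
   label volume; per-leaf voxel counts and percents are reported. If the top
   four regions cover more than 80% of a cluster they are reported at leaf
   level; otherwise leaves are collapsed into their parents one hierarchy
   level at a time (re-testing after each level) until the criterion holds or
   the root is reached. Collapse is volume-conserving at every step; ties in
   the top-k ranking break by ascending region id. Atlas-background voxels
   inside a cluster are reported as "undefined" and never collapse.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| rolling-ball radius | 20 px (full res) / 3 px (25 µm) | background ball radius in pixels of the target image |
| smoothing kernel | σ = 100 µm | Gaussian σ, converted to voxels per axis |
| permutations | 1,000 (desk) / 18,000 (full scale) | exhaustive enumeration used automatically when cheaper |
| q | 0.2 (plaque/microglia), 0.4 (TH) | BH FDR level over in-mask voxels |
| extent threshold | 400 voxels (plaque/microglia), 100 (TH) | minimum cluster size |
| cluster connectivity | 26 | 6/18/26 configurable; cell counting always uses 6 |
| α | 0.05 one-tailed | validation significance level |

## The synthetic phantom

No real volumes ship with the package, so a generator produces two-group
cohorts on a toy atlas: an ellipsoidal "hemisphere" partitioned into
contiguous leaf regions nested under parents under one root, with a ventricle
and an undefined leaf in the exclusion set. Channels emulate the statistical
structure the analysis assumes:

* **plaque**: Poisson-placed Gaussian blobs (half-max radius 20–40 µm,
  amplitude 1), density per group and region class — by default
  800 (deep) / 400 (other) plaques/mm³ in group A and 2400/400 in group B, a
  3× excess confined to designated "deep layer" leaves;
* **microglia**: gamma-speckle baseline, multiplied by a halo gain within
  75 µm of every plaque centre (the aggregation radius is a free phantom
  parameter, not a biological claim);
* **th**: capsule-shaped fibre tracts with group-dependent intensity plus
  spherical somata in a designated soma leaf;
* **artifacts**: high-intensity capsule segments added to the plaque and
  microglia channels;
* additive Gaussian noise (σ = 0.05) everywhere.

Truth masks record each object's analytic profile above its half-maximum
before noise, so ground truth is exact and resolution-independent. Phantoms
are generated directly in atlas space (identity transforms); warping is
exercised separately with synthetic rigid transforms. All outputs are pure
functions of (spec, seeds); per-subject and per-channel random streams are
spawned independently so one channel's draws cannot perturb another's.

The default densities were chosen so that the expected number of blobs inside
one smoothing kernel volume is well above 1 in both groups (≈13 in A's deep
regions, ≈38 in B's): per-voxel group separation then reflects the planted
mean effect rather than Poisson placement noise. The phantom hemisphere is a
scaled-down object (64³ at 25 µm ≈ 1.6 mm across), so per-kernel counts, not
absolute density, carry the realism. At these densities blob-union overlap
deflates the label-density ratio slightly below the placed 3× (to ≈2.7); the
recovery checks use the measured ratio.

### What the phantom does not model

Optics (PSF, light-sheet striping), stitching seams, bleaching,
illumination fields, real anatomy, and registration error (transforms are
inputs). Passing phantom tests therefore demonstrates the statistical
machinery — calibration under the null, recovery of planted effects,
exactness of the density formulas — not robustness to acquisition artifacts
beyond the simple capillary-like tubes included.

## Numerical choices and edge cases

* Voxel centre convention: index *i* sits at physical position
  (*i* + 0.5) × voxel size, 0-based, µm everywhere; transforms map physical
  coordinates between spaces and volumes are resampled by pull-back.
* Permutation ties are counted with a 10⁻¹² tolerance so bit-identical
  statistics compare as ties rather than depending on summation order.
* A voxel with zero pooled variance in the observed data gets p = 1 and is
  flagged; degenerate validation data (zero pooled variance) gives p = 1 for
  equal means and p = 0 when the difference lies in the tested direction.
* The BH cutoff is the largest p passing the step-up rule (0 when none pass);
  the significant mask is p ≤ cutoff, which equals the BH rejection set.
* Smoothing uses reflection boundaries, so constant images are fixed points
  and interior intensity is preserved.
* Cell membership uses the nearest voxel to the component centroid; a
  boundary-touching cell is counted exactly once.
* Block-mean downsampling pads edge blocks by replication; voxel size scales
  by the factor.

## Known limitations

* Validation is performed on the same subjects that defined the clusters, so
  it is partially circular: selection favours voxels where the same random
  fluctuations that drove the t-map also drive the density measure. On
  phantoms this shows up as occasional validated *relative* clusters of the
  opposite sign (per-subject z-scoring makes unaffected regions relatively
  dimmer in the affected group). The planted-effect checks therefore require
  direction, overlap with the planted regions, and ratio recovery — not
  merely "some valid cluster".
* With very small groups the exhaustive permutation p-value floor
  (2/C(n, n_A) two-sided) interacts with FDR: at 4+4 subjects, discoveries
  are only possible when at least q × (2/70)⁻¹ ≈ 14% of in-mask voxels reach
  the floor. This matches the behaviour of label-permutation inference in the
  tooling this package mirrors and is documented rather than patched.
* Only affine transforms are estimated-free inputs; displacement fields can
  be composed but are never estimated.
* The interactive pixel classifier of the original workflow is replaced by
  deterministic rules; externally supplied masks are the intended path for
  real data.

## Test and acceptance problem sizes

Phantom-based checks run at 64³ voxels with 4+4 subjects and 500 requested
permutations (exhaustive enumeration of the 70 balanced relabelings applies
automatically), 20 null seeds and 10 planted seeds; these sizes were chosen
as the smallest at which the calibration and recovery properties are stable
across seeds. `scripts/acceptance.py` recomputes all headline quantities from
scratch at the same sizes.
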