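# Methods

## The proximity statistic and its null model

The question addressed is whether fluorescent puncta of a candidate
contact-site protein are closer to an organelle (ER or mitochondria) than
chance allows. The data are per-cell sets of punctum trajectories and
per-frame organelle masks. Every detection of every frame contributes one
sample: the minimal Euclidean distance, in nanometers, from the subpixel
punctum centroid to the nearest organelle-positive pixel center (0 when
the centroid's pixel is itself positive). Pooling frames weights
long-lived puncta more, which is deliberate: the quantity of interest is
the probability distribution of punctum positions over time, not a
per-object summary. A per-track time-averaged variant is available
(aggregate the sample table by `track_id`) but pooling is the default.

The per-cell statistic is the fraction of samples at or below a threshold,
100 nm by default and inclusive (the conventional cytoplasmic gap at
ER-mitochondria contacts is 10–30 nm; 100 nm adds the localization and
segmentation uncertainty of confocal data).

The null model randomizes *trajectories*, not points: each track is moved
as a rigid body — uniform random translation (anchor drawn uniformly over
cytoplasm pixels with subpixel jitter), plus, by default, a uniform random
rotation about the trajectory centroid — and the placement is
rejection-sampled until every point lies inside the cytoplasm mask (at
most `max_attempts` = 100 draws, after which the original placement is
kept and a warning issued; this occurs only when a trajectory barely fits
its cell). Randomizing whole trajectories preserves the temporal
autocorrelation of the motion, so the null destroys only position
information. Rotation is included by default to remove orientation bias in
elongated cells; `mode="translate"` disables it for sensitivity analysis.
The per-cell null fraction is the mean over `n_replicates` = 100
randomizations (50 in the acceptance script; the means are stable well
below one percentage point at either setting).

Observed and null fractions are compared across cells with a two-sided
Student's paired t-test on the per-cell differences; means are reported
± SEM (SD/√n). Two-sided is the conservative reading when sidedness is
not pre-registered.

### Numerical choices

* Coordinates are (row, col), 0-based, pixel centers at integer
  coordinates; all distances are computed in pixels and scaled by the
  pixel size (nm/px) at the boundary of each function.
* Subpixel point-to-mask distances are *exact* nearest-neighbor queries
  over positive pixel centers (a cached KD-tree per mask), not
  interpolations of the per-pixel distance transform; the per-pixel
  `DistanceMap` (scipy's exact Euclidean distance transform) is retained
  for area-fraction and visualization purposes. This keeps an O(N·M)
  brute-force oracle exact to 1e-9 nm.
* Rigid motions are applied as `anchor + rotated_offsets`, which preserves
  within-track displacement magnitudes to machine precision (the test
  tolerance is 1e-9 nm; bitwise identity is not attainable in floating
  point once a rotation is involved).
* The paired test raises a degenerate-test error when all differences are
  identical (zero variance), rather than returning p = NaN.
* Distance histograms are normalized to integrate to exactly 1 over
  [0, max]; the empirical CDF is right-continuous, so CDF(threshold)
  equals the fraction-within statistic by construction.

## Detection and tracking

Detection is scale-normalized Laplacian-of-Gaussian blob finding:
`log_sigma_px` = 1.6 matches a ~200 nm FWHM spot sampled at 80 nm/px;
local maxima above `min_response` (10 intensity units ≈ 1/15 of the
rendered spot amplitude) are refined by an intensity-weighted centroid in
a (2·ceil(2σ)+1)² window after subtracting the window minimum. Linking is
greedy mutual-nearest assignment: candidate links within `max_disp_px` = 5
per frame step are accepted in ascending distance order; a track missed
for up to `max_gap` = 1 frame may be re-linked with the gate scaled by the
gap. Greedy assignment is adequate at the sparse densities of punctum data
and attains the exhaustively enumerated optimum on well-separated
configurations (tested); a full linear-assignment solver would matter only
at densities where punctum identity is ambiguous anyway. Tracks shorter
than 3 detections are discarded by default — randomization statistics need
trajectories, not single-frame flickers.

## Segmentation

Organelle channels are thresholded (Otsu by default, or a fixed
threshold) and components below `min_object_px` are removed. The
cytoplasm is delimited from a plasma-membrane stain as the filled interior
of the largest closed boundary; the nucleus is not excluded (whether the
placement domain should exclude it is not decidable from typical membrane
stains; an exclusion mask can be intersected by the caller). Organelle
masks are recomputed per frame by default because the ER is highly mobile;
a single static mask can be passed for speed.

## The synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions under which the pipeline is validated.

**Cell geometry** (256×256 px at 80 nm/px by default — the pixel size is
typical confocal sampling with a 63×/1.4 NA objective): the cytoplasm is
a single filled ellipse (~53% of the frame); the ER is a random spanning
tree over `er_nodes` scattered nodes drawn as ~3 px wide anti-aliased
tubules; mitochondria are `n_mito` disjoint ellipses with aspect ratio
2–6. Defaults were calibrated to the chance levels published for live
cells: the randomized fraction-within-100 nm directly estimates the area
fraction of the organelle's 100 nm neighborhood in the cytoplasm, reported
as ≈47% for the ER and ≈13% for mitochondria; `er_nodes` = 1050 and
`n_mito` = 24 (semi-minor 2.5–4 px) reproduce those footprints. Exact
morphology beyond these densities is irrelevant to the statistics being
validated.

**Trajectories**: each punctum is seeded organelle-associated with
probability `p_assoc` (uniformly within `assoc_radius` = 100 nm of the
target organelle, enforced on the exact point distance) or uniformly in
the cytoplasm. Associated puncta are modeled as tethered: an anchor point
rides the organelle's per-frame rigid jitter (integer-pixel translations,
sd `organelle_motion_sd` = 20 nm/frame, kept in exact register with the
shifted masks) plus a fresh non-cumulative wobble (sd
`residual_motion_sd` = 10 nm/frame). Free puncta perform a Gaussian random
walk (sd `diffusion_step_sd` = 40 nm/frame) reflected at the cytoplasm
boundary. `p_assoc` defaults to 0.45, which at the default ER footprint
yields an observed fraction of ≈0.71 — the regime of a genuine
contact-site protein.

**Rendering**: puncta are Gaussian spots (sd `psf_sigma` = 120 nm),
organelle channels are their masks at fixed amplitude lightly blurred,
the membrane channel is the cytoplasm outline; Poisson noise (gain
`noise_poisson_scale` = 1 photon/unit) is applied before Gaussian read
noise (`noise_gaussian_sd` = 2). At these settings detection recovers
≥90% of ground-truth puncta at a 2 px match radius; losses are genuine
merges of overlapping spots.

**Immunogold fields**: square images of 11.125 µm² with `mito_region_count`
elliptical outlines covering `mito_region_area_fraction` of the area;
cluster counts are Poisson(`cluster_density` × area); each cluster is
associated (uniform within the outlines' `assoc_distance_um` = 0.03 µm
reach) with probability `assoc_fraction`, else uniform outside that reach,
so geometric classification recovers the labels exactly. A gold "cluster"
is a single centroid point; silver-enhancement extent is not modeled
because quantification counts clusters, not particles. Default conditions
(41 images, 0.8 clusters/µm², 60% associated) match the published brain
immunogold experiment.

**Fraction profiles**: two profiles of `n_fractions` = 12 lanes (24
gradient fractions probed pairwise) are built from a shared latent
profile z and independent noise w: y = a·z + w with mixing weight
a = r·σ_w/√(1−r²), so the population Pearson correlation equals
`target_r`. With σ_w = 0 the latent profile is shared exactly and |r|
degenerates to 1. The mean sample r at n = 12 is slightly below the
target (≈0.61 at target 0.633) — the well-known small-sample bias of the
correlation coefficient, not a defect of the construction.

**Association studies**: `simulate_association_study` draws per-cell
(observed, randomized) fraction pairs with a shared cell random effect:
means 0.7082/0.4695, between-cell SD 0.20 (the published SEMs × √13) and
paired-difference SD 0.065 (the value implied by the published paired-t
p-value at n = 13). It powers the power/calibration experiments without
re-rendering imagery.

### What the generator does *not* emulate

3D structure and z-sectioning, photobleaching, ER fission/fusion and
reticular loop closure (the ER is a tree, not a mesh with cycles),
organelle deformation (motion is rigid translation), realistic PSFs
(Airy/astigmatism), uneven illumination, and camera-specific noise. Frame
interval is not modeled — motion parameters are per frame, not per second.
Consequently, passing tests demonstrate correctness of the *statistics*
under a controlled, recoverable model; they do not certify segmentation or
detection performance on real micrographs, which fail in ways (clutter,
debris, out-of-focus light) the generator does not produce.

## Statistics module

Pearson correlation p-values use the exact t-transform
t = r·√(n−2)/√(1−r²) with n−2 df; the paired t-test uses the textbook
closed form at n−1 df; both are cross-checked in the tests against
independent implementations. Manders coefficients use the standard
definition, M1 = ΣA over pixels with B > thr_B ÷ ΣA over pixels with
A > thr_A (and symmetrically M2), with thresholds defaulting to 0
(classic Manders); automatic (Costes) thresholding is out of scope.

## Problem sizes

The test suite and acceptance script use 128–256 px cells, 6–10 frames,
12–30 puncta, 2–13 cells per experiment, 50–100 randomization replicates,
10,000 placements for uniformity calibration, and 100–400 simulation
repeats for power and null-calibration checks — sizes chosen so each
statistical check has at least 3-SE resolution on the quantity it
validates while the whole suite remains quick to run on one CPU.

## Known limitations

* The greedy linker can mis-assign identities when puncta pass within the
  displacement gate of each other; distance samples are largely
  insensitive to identity swaps, but track-level statistics would not be.
* The association rule for immunogold ("inside or within 30 nm of an
  outline") is a modeling choice; published counts of associated clusters
  can be reproduced from annotations regardless of the rule.
* With per-frame Otsu segmentation, organelle mask area fluctuates with
  noise; distance samples near the threshold can cross it, which slightly
  smooths the observed fraction relative to ground truth.
* The randomization keeps a trajectory's original placement when no valid
  placement is found; in pathologically small cytoplasm masks this biases
  the null toward the observed value (a warning is emitted).
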