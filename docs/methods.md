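# Methods

`connectotype` implements an individual-specific functional-connectome
analysis on triangulated cortical surface meshes, exercised end-to-end on
synthetic cohorts with planted ground truth.  This note documents the
models, the generator, the numerical choices, and what the passing tests
do and do not establish.

## The analysis model

**Substrate.** A connected triangulated mesh stands in for one cortical
hemisphere.  Geodesic distance is the shortest path over mesh edges with
Euclidean edge weights.  A population atlas assigns every vertex one of
`n_networks` fine functional networks (default 18) and one of `n_rois`
ROIs (default 116), each ROI a connected patch nested in exactly one
network; fine networks map onto 7 canonical networks.

**Signal cleaning** applies, in fixed order:

1. *Censoring.* Frames with FD > 0.2 mm or DVARS > 50 are flagged; flags
   are dilated 1 frame back and 2 forward; kept runs shorter than 5
   frames are also censored; a subject with more than half of frames
   censored is excluded.  All five numbers are config parameters.
2. *Nuisance regression.* OLS on kept frames against 18 columns:
   intercept, linear trend, six motion parameters, mean white-matter and
   ventricle proxies, and the temporal derivatives of those eight.
   Residuals are returned at all frames.
3. *Spectral gap interpolation.* A constant plus sinusoids on the linear
   grid `j/(T·TR)` are fit jointly to kept frames by ridge-regularized
   least squares (ridge 1e-3 relative, DC unpenalized) and synthesized at
   censored times.  The grid is truncated at `n_kept/4` frequencies: a
   denser grid is unidentifiable on the kept frames — both the joint fit
   and independent per-frequency fits then produce unbounded or
   collapsing values in the gaps — while the truncated grid still covers
   the 0.009–0.08 Hz analysis band at the study's series lengths
   (T ≈ 200, TR = 3 s) and reconstructs grid sinusoids to well under 1 %
   error.  Interpolation exists only to make the band-pass well posed:
   censored frames are re-excluded from every downstream correlation,
   including the parcellation step.
4. *Band-pass.* Zero-phase (forward–backward) 4th-order Butterworth,
   0.009–0.08 Hz at TR = 3 s by default.

**Individual parcellation.** Starting from the atlas labels, each
iteration computes one reference series per network (SNR-weighted mean
over its current vertices), scores every vertex against every network as

    score(v, k) = corr(v, ref_k) + α_t · (1 − variability(v)) · (1 − snr(v)) · 1[atlas(v) = k]

and relabels to the arg-max.  α decreases linearly from 1 to 0 over the
iterations (default 10; early stop when < 0.1 % of labels change), so
the final map is data-driven wherever the subject's signal supports it
and atlas-anchored where inter-individual variability is low or SNR is
poor.  The blend formula, the (1−variability)(1−snr) weighting, and the
linear schedule are this package's concrete realization of an
atlas-guided iterative parcellation whose published form is not fully
specified.

**Template matching** assigns each network's connected components
("patches") to that network's atlas ROIs by three rules: (1) a patch
overlapping a single same-network ROI by more than `overlap_min`
vertices inherits it; (2) a patch overlapping several ROIs is split —
overlapping vertices keep their atlas ROI and act as centers, remaining
vertices join the geodesically nearest center (ties to the lower ROI
id); (3) a non-overlapping patch joins the nearest same-network ROI iff
its geodesic distance is below that ROI's internal mean pairwise vertex
distance, else its vertices are labeled unrecognized.  `overlap_min`
defaults to 20 scaled by mesh size (floored at 3): 20 vertices is
calibrated to a 2×2562-vertex mesh.  A patch whose single overlap is
below `overlap_min` falls through to rule 3 (where a genuine overlap
gives distance 0, hence assignment).  Geodesic Gaussian smoothing of the
patch indicator (σ = 1 mesh unit) is computed for matching bookkeeping
but never alters the stored vertex set.

**Connectivity.** ROI series are unweighted vertex means over kept
frames; connectivity is pairwise Pearson correlation (no Fisher z by
default; a flag enables it).  A symmetric n-ROI matrix vectorizes to
n(n−1)/2 upper-triangle features (6670 at n = 116).  Within-network
connectivity of network k averages pairs with both ROIs in k; between-
network connectivity averages pairs with exactly one ROI in k.  The
individual-vs-atlas between-network shift is reported as the percent
change of subject-mean values per network (per-subject ratios are
unstable because single-subject between-network means can be near zero)
with a paired t-test, Bonferroni-corrected over networks.

**Variability.** Size variability is the across-subject sample SD
(ddof = 1) of matched vertex counts (unmatched ROIs count 0); position
variability is the mean geodesic distance between subjects' ROI centers,
a center being the geodesic medoid vertex (deterministic and on-mesh; a
Euclidean-centroid variant is not provided because the medoid dominates
it on closed meshes); vertex-wise variability at v is the mean over
subject pairs of (1 − r) between their length-`n_rois` connectivity
profiles at v (profiles against atlas ROI mean series — a desk-scale
basis standing in for full vertex-to-vertex profiles, flagged as an
approximation); ROI-connectivity variability is the across-subject SD
per connection averaged over each ROI's incident connections.

**Prediction.** Classification: stratified k-fold (default 5) RBF-SVM
(C = 1, kernel width 1/n_features after standardization) with in-fold
residualization of age/sex and two-sample t-test selection at p < 0.001
(uncorrected; empty selections fall back to the 10 smallest-p features).
Regression: leave-one-out linear SVR (L2-regularized L2-loss, C = 1,
ε = 0.1) with in-fold residualization of features and target (training
coefficients applied to the held-out subject) and Pearson-correlation
selection at p < 0.001 Bonferroni-corrected over features (uncorrected
mode available; same fallback).  Per-fold weight vectors are expanded to
the full feature space with zeros at unselected features.  Significance
of the observed-vs-predicted correlation comes from a permutation test
that reshuffles scores and re-runs the entire LOOCV pipeline, selection
included; p uses the add-one estimator (1+exceed)/(1+n_perm) to avoid
p = 0 (raw mode available).  The top connection set holds the
ceil(0.1 × pool) largest |fold-mean weight| over connections selected in
≥ 1 fold — the counting form of the 90th percentile, which never returns
an empty set under sparse selection.  ROI contribution sums |mean
weight| over incident connections; the canonical-network table splits
top-connection weight into within- and between-network parts.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed.

* **Cohort structure**: 235 subjects in six cells — carriers NA/MCI/AD =
  42/39/39, noncarriers 43/39/33 — with ages ~ N(72, 6.5²) and balanced
  sex.  Scaled-down test cohorts keep the three-group × two-genotype
  design.
* **Topography**: each subject's true labels come from stochastic
  boundary shifts of the atlas.  By default only network-boundary
  vertices move, across the network border (`scope="network"`):
  within-network ROI-border shifts are structurally invisible to a
  network-level parcellation (matching rule 2 reassigns by atlas
  overlap), so including them would only add an unrecoverable noise
  floor; shifted network topography is also the phenomenon the analysis
  is designed to capture.  `scope="roi"` enables the fully general
  perturbation.  Moves that would empty or disconnect a source ROI are
  rejected.  `boundary_shift_sd` (edge-length units) sets the per-sweep
  move probability `shift/(2·n_sweeps)` with `n_sweeps = round(shift)`.
* **Signals**: one latent series per ROI with ROI-level correlation
  `network_cov[net_i, net_j]` off the diagonal (defaults: 0.6 within,
  0.1 between networks) and unit variance; a vertex carries its ROI
  latent plus independent white noise (`vertex_noise_sd`, default 0.5 ≈
  SNR 2).  Latents are band-limited to 0.009–0.08 Hz by default:
  resting-state fluctuations concentrate at low frequencies, and white
  latents would forfeit most of their degrees of freedom at the
  band-pass step.  Filtering all latents identically preserves the
  planted zero-lag correlation structure; `latent_band=None` gives white
  latents.
* **Group effects**: clinical severity shifts the planted effect
  connections' generating correlations by `group_effect` (−0.15) per
  severity step (NA 0, MCI 1, AD 2), with eigenvalue clipping to keep
  the ROI covariance PSD.
* **Motion**: baseline FD ~ clipped Gamma below 0.2 mm and DVARS ~
  clipped Normal below 50; a Bernoulli(rate, default 0.05) frame subset
  exceeds the FD and/or DVARS threshold.  Motion-parameter and tissue
  proxies are smoothed random walks — enough structure for a full-rank
  nuisance design, with no claim of physiological realism.
* **Symptoms**: score = intercept + β·Σ coeff·conn + γ_age(age−72) +
  γ_sex·sex + ε, clamped to instrument ranges (MMSE-like 0–30,
  recall-like 0–25).  Defaults (intercepts 27.5/11, β 8/10, noise SD
  1.5/2) put group means and spreads in the ranges the emulated
  instruments show; clamping is rare away from the ceiling.  Each
  genotype carries its own planted between-network effect map — the
  substrate for the cross-genotype dilution analysis.
* **Determinism**: per-subject seeds derive from (config seed, subject
  index), so cohort-size changes do not reshuffle existing subjects.

What the generator does **not** emulate: volumetric/hemodynamic forward
models, realistic artifact spectra, spatial autocorrelation of noise,
atrophy, or multi-session structure.  Passing tests therefore establish
internal consistency of the method under its own assumptions (shared
latents within regions, boundary-shift topography), not performance on
real imaging data.

## Problem sizes in tests and reproduction runs

Meshes are icospheres (12/42/162/642/2562 vertices).  The noise-free
closure and topography-recovery checks use the 642-vertex mesh with the
full 18-network/116-ROI atlas (10 and 20 subjects).  The replicate-
cohort contrast experiments use a 162-vertex mesh with 6 networks and
24 ROIs, 120 subjects per cohort, 196-frame series, shift 1.5 — a
desk-scale version of the study design with the same structure; cohort-
level evidence averages both symptom targets and both genotypes.  The
permutation-calibration study uses 50 replicates of 30 subjects × 45
features at 99 permutations.

## Known limitations

* Under the null, the LOOCV observed-vs-predicted correlation has a
  selection-inflated spread (SD ≈ 0.14–0.22 depending on feature count):
  with Bonferroni selection and the always-active top-10 fallback, every
  fold trains on the strongest chance correlations.  Single-run null |r|
  therefore regularly exceeds 0.25.  The permutation test — which
  re-runs the entire pipeline per permutation and whose p-values are
  verified uniform under the null — is the calibrated significance
  measure, as in the original procedure.
* Matching rule 2 reassigns within-network vertices by atlas overlap, so
  individual within-network ROI borders are inherited from the atlas by
  construction; only network-boundary topography is genuinely
  individualized.
* The vertex-variability basis (atlas ROI mean series) is a low-rank
  stand-in for vertex-to-vertex profiles.
* Tiny ROIs (4–10 vertices on the 642-vertex mesh) make Dice a coarse
  metric; one mislabeled vertex moves Dice by ~0.2.
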