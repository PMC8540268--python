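# Methods

This note documents the models, conventions and design choices behind
`peritex`, in the order the pipeline runs.

## ROI construction

**Peritumoral margin.** "Within 10 mm of the tumour margin" is implemented
as the Euclidean distance transform of the tumour voxel set, computed in
physical millimetres on the native grid (`scipy.ndimage.distance_transform_edt`
with the voxel spacing as sampling). No resampling ever happens: CT slices
are commonly thicker (e.g. 5 mm) than the in-plane spacing, and computing
distances in mm on the anisotropic grid preserves the 10 mm rule exactly.
Membership is always a voxel-centre test; partial-volume fractions are not
modelled.

**Adipose window.** Fat is CT attenuation in [−200, −50] HU. Both bounds are
inclusive; the window is configurable (`ATWindow`).

**Spill-over guard.** Clinically, regions near a hot tumour are scrutinised
by hand for tracer spill-in. The deterministic surrogate here removes
adipose voxels within a guard distance of the tumour surface (default: one
voxel diagonal) and, optionally, voxels above an SUV cap. Both knobs are
explicit configuration because no automated rule can reproduce a reader's
judgement; the defaults err on the side of keeping the region large.

**Contralateral mirror.** The reference region is a pure left–right
reflection of the peritumoral VOI about a plane that maps voxel centres onto
voxel centres (default: the grid's physical centre), then HU-windowed. The
reflection is an exact involution and preserves voxel counts. Quadrant
anatomy is not modelled; the mirrored VOI is windowed by HU only, without
excluding a mirrored "tumour" region (the mirrored tissue is healthy, so the
HU window already excludes non-fat).

**Volume gate.** Regions below a minimum adipose volume (ml) are flagged
invalid rather than silently analysed; texture statistics on a handful of
voxels are meaningless.

## Grey-level discretisation

All matrix features operate on integer levels 1..Ng. Default: **Ng = 64
over an absolute SUV window [0, 20]**, level =
clamp(floor((v − lo)/(hi − lo)·Ng) + 1, 1, Ng), with a value exactly at the
upper bound assigned to level Ng. An ROI min–max mode is available. The
discretisation settings are recorded in every feature vector's provenance
because absolute feature magnitudes (and hence published cutoffs such as a
GLCM entropy of 3.16) are only meaningful relative to these settings.

Entropies (histogram and GLCM) use **log base 2**. The published dynamic
ranges (GLCM entropy ≈ 2.8–4.1, histogram entropy ≈ 1.7–2.5) exceed what
log₁₀ could produce at Ng = 64, so bits are the consistent convention.

## Texture features

* **First order (7):** min, max, mean, population SD, standardised third
  moment (skewness) and plain standardised fourth moment (kurtosis = 3 for
  a normal), and −Σ q log₂ q over the non-empty bins of the Ng-bin
  discretised histogram. Zero variance leaves skewness/kurtosis NaN with a
  warning.
* **GLCM (6):** voxel pairs at Chebyshev distance 1 along the 13 unique 3D
  directions, both endpoints in the mask, accumulated symmetrically, summed
  over directions into a single matrix, then normalised. Homogeneity
  Σ p/(1+|i−j|), energy Σ p², contrast Σ (i−j)² p, correlation
  Σ (i−μ)(j−μ)p/σ² (NaN for a single grey level), entropy −Σ p log₂ p,
  dissimilarity Σ |i−j| p.
* **NGLDM (3):** for each masked voxel, the mean level of its in-mask
  26-neighbours (out-of-mask neighbours excluded, not zero-padded; voxels
  with no in-mask neighbour dropped); s_i accumulates |level − neighbourhood
  mean|. Coarseness = 1/Σ pᵢsᵢ (infinite for a constant region, flagged),
  contrast and busyness follow the classical neighbourhood-difference
  definitions; a single-level region has contrast 0 and busyness 0 (0/0
  convention).
* **GLRLM (11):** maximal collinear same-level runs per direction,
  matrices summed over the 13 directions before feature computation. Run
  percentage divides total runs by total run-covered voxel positions
  (= directions × voxels), so a constant 1-D segment of length L scanned
  along itself has RP = 1/L and LRE = L².
* **GLZLM (11):** 26-connected constant-level zones
  (`scipy.ndimage.label`); zone-size analogues of the run-length features;
  ZP = zones/voxels.

Conservation laws are tested: GLCM probabilities sum to 1, Σ length·runs =
voxels per direction, Σ size·zones = voxels. Every matrix feature is checked
against an independent pure-Python exhaustive-enumeration oracle on random
masks (tolerance 1e−10), and all features are invariant to spatial-axis
permutation on isotropic grids with the full direction set.

Degenerate inputs never produce silent zeros: masks with < 2 voxels are
rejected, regions with no valid co-occurrence pair yield NaN GLCM features,
and undefined statistics are NaN.

## Phantoms

`generate_phantom` emulates only what the pipeline needs: two HU-banded
slabs (HU ~ N(−100, 30), so most but not all slab voxels fall in the adipose
window) on either side of the midsagittal plane inside a soft-tissue
background, a spheroid tumour (SUV ~ N(6, 1)) in the right slab, and an
adipose SUV field N(0.8, 0.25) plus a **spatially correlated heterogeneity
field**: white Gaussian noise smoothed with a fixed 1-voxel-sigma kernel,
standardised, and scaled to amplitude `heterogeneity × at_suv_sd`. One dial
(`heterogeneity ≥ 0`, 0 = homogeneous) controls texture; extracted GLCM
entropy is monotone in it (tested). SUV is clipped at 0. Defaults (grid
40×40×28 at 3 mm, tumour radius 8 mm) put the peritumoral adipose mask at a
few hundred voxels and its GLCM entropy in the 3–5 bit range — the dynamic
range reported for real peritumoral fat. Adipose SUV levels are free
parameters of the simulation: the clinical study reports only texture
statistics of fat, not its SUV distribution, so these values are a realism
choice, stated here once and not tuned.

What the phantoms deliberately do **not** model: scanner acquisition and
reconstruction (PSF, TOF, noise correlations between PET and CT),
attenuation physics, anthropomorphic breast anatomy and quadrants, and
partial-volume effects. Passing end-to-end tests therefore demonstrates that
the pipeline recovers an injected heterogeneity difference, not that it
would achieve any particular AUC on clinical images.

`simulate_feature_cohort` skips the imaging layer entirely and draws a
feature per patient from class-conditional normals over the four visual-read
outcome groups (TN/FN/TP/FP), because that is how the reference cohort's
group statistics are reported; metastatic = TP∪FN and visually positive =
TP∪FP by construction. Defaults are the published sizes/means/SDs. With
those parameters the mixture-binormal closed form gives a mean AUC ≈ 0.816
for the metastasis contrast, consistent with what the simulation reproduces.
LN SUVmax is drawn log-normally per metastasis class around configurable
medians; only a cohort median is published, so these are stated defaults.

`simulate_imaging_cohort` assigns the metastatic class an additive
heterogeneity offset and rounds the positive count to `n × prevalence`.

## Diagnostic statistics

* **AUC:** Mann–Whitney estimator via midranks (ties count ½).
* **DeLong:** variance and paired-test covariance from the structural
  components (placement values) computed with midranks; CI is a normal
  approximation truncated to [0, 1]; perfect separation collapses to a point
  interval. The paired test is two-sided with optional Bonferroni family
  size m (adjusted p = min(1, m·p)); m defaults to the number of comparisons
  actually run in a session. The paired p agrees with a 10⁴-resample
  swap-permutation oracle within Monte-Carlo error (tested at n = 100).
* **Youden cutoff:** the positive rule is strict (`score > cutoff`);
  candidate cutoffs are the observed score values; ties break toward the
  smallest cutoff (maximising sensitivity).
* **Predictive values:** sens = TP/(TP+FN), spec = TN/(TN+FP),
  PPV = TP/(TP+FP), NPV = TN/(TN+FN) as percentages; zero denominators give
  NaN, never 0. Displayed precision follows the field convention (rates to
  1 decimal, AUC to 3).
* **Stratification:** four strata (feature ≤/> cutoff × node finding −/+);
  rows with a missing node finding are excluded from that table only and
  counted in `attrs["n_excluded"]` — matching the convention that patients
  without measurable nodes leave only the node-SUVmax analyses.
* **Group tests:** paired t (peritumoral vs contralateral; identical pairs
  report t = 0, p = 1 rather than NaN), two-sample t, Kruskal–Wallis with a
  hand-rolled tie-corrected Dunn post-hoc (unadjusted by default, optional
  Bonferroni), Spearman, chi-square without continuity correction.

For a binary score the identity AUC = (sens + spec)/2 holds exactly and is
the property tested; published AUCs of binary readings can deviate from this
identity by software-specific tie handling, so such printed values are not
asserted.

## Problem sizes

Defaults are chosen so a full run is interactive: phantoms of 40×40×28
voxels (≈45k), peritumoral adipose masks of a few hundred voxels (~15 ms
per 38-feature extraction), 60-phantom cohorts for signal-recovery checks,
500 replicates for the cohort-level AUC, 10⁴ permutations/2×10³ bootstraps
for the inference oracles. All sizes are arguments, not constants.

## Known limitations

* The phantom is a statistical substrate, not an anthropomorphic model; no
  claim about clinical AUC transfer follows from it.
* Absolute feature magnitudes depend on the discretisation settings, which
  the reference analysis does not publish; published cutoffs (3.16, 1.90)
  are reproduced as configuration defaults for stratification demos, not as
  recomputed truths.
* The spill-over guard is a deterministic stand-in for manual VOI scrutiny.
* Per-direction feature averaging (an alternative GLCM/GLRLM aggregation
  convention) is not implemented; matrices are summed before features.
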