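# Methods

## Scope and data model

The pipeline analyzes baseline PET volumes in SUV units with per-lesion
binary VOI masks on the PET-native grid. Coordinates are 0-based voxel
indices; VOI voxels are always read in a fixed raster order (x fastest,
then y, then z) so every downstream number is reproducible bit-for-bit.
Masks and volumes must share a grid — there is no resampling, registration
or partial-volume correction in scope. Decay correction is assumed to have
been applied upstream of the SUV conversion
(SUV = concentration[Bq/ml] × body weight[g] / injected activity[Bq]).

## Texture features

Quantization uses `ng` equal-width bins (default 64) between the VOI's own
minimum and maximum SUV; the maximum maps to level `ng` and a constant VOI
maps to a single level. Min–max binning makes all co-occurrence features
invariant to affine rescaling of SUVs inside the VOI, which is why the
phantom's absolute SUV band does not matter for texture. The bin count is
exposed (`TextureConfig.ng`) because published entropy cutoffs are
convention-dependent: with `ng = 64` and base-2 logs, entropy lives in
[0, 12] bits, the scale on which a cutoff like 5.15 is meaningful.

Co-occurrences are accumulated at distance 1 over all 13 unique 3D
directions into a single symmetric matrix, counting only pairs with both
voxels in the mask, then normalized — one pooled NGLCM rather than
per-direction feature averaging. Pooling all directions makes features
exactly invariant under axis permutations and flips (property-tested).
Entropy, homogeneity and contrast are the textbook NGLCM functionals.

Two conventions are interpretations, stated here because the source
software's definitions are not public:

- **Size variation** (a third-order, voxel-to-voxel change statistic) is
  implemented as the mean over in-mask voxels (with ≥1 in-mask 26-neighbor)
  of |level − mean level of in-mask neighbors| — a neighborhood
  gray-tone-difference-style quantity. It is 0 for constant lesions and
  grows when intensity alternates voxel to voxel. Whether the original
  workstation used an NGTDM- or run-length-based definition is unknowable;
  connectivity (26 or 6) is configurable.
- **COV** uses the population standard deviation by default
  (`sd_mode="sample"` switches to ddof=1). COV is invariant under pure
  scaling of SUVs but not under shifts.

Degenerate inputs are defined rather than fatal: a constant lesion yields
COV 0, entropy 0, homogeneity 1, contrast 0, size variation 0. A lesion
with only isolated voxels has no co-occurring pair and raises. Lesions
below the configured voxel floor (default 62 voxels, the smallest lesion
volume the analysis was designed around) are flagged and warned about, not
dropped — small VOIs make quantized texture statistics unstable.

Per-patient aggregation is the unweighted arithmetic mean of each feature
over the lesions of each site.

## Response definition

Deltas are post − pre for PSA, AP and bAP; response is a strictly negative
delta, so Δ = 0 counts as non-response (the boundary case is explicit in
tests). ECOG is carried through as a change score only. Summary percentages
are reported with plain 2-decimal rounding *and* as raw fractions, because
published percentages mix rounding conventions.

## Statistics

Spearman correlations use average ranks and the two-sided t-approximation
p-value (SPSS/MedCalc-compatible); constant inputs raise rather than
returning NaN. No multiple-testing correction is applied across the
site × feature × delta screen — matching the screening design — but the
total number of tests performed is part of the results bundle so readers
can judge.

AUC is the Mann–Whitney statistic (ties = ½) with the Hanley–McNeil
standard error and a normal-approximation CI clipped to [0, 1] (clipping
logged). The Youden scan evaluates every midpoint between adjacent distinct
scores plus ±∞; the reported orientation is chosen so AUC ≥ 0.5 and is
recorded as an explicit direction (`greater` / `less_equal`); J-ties break
toward the smallest |cutoff| with all maximizers reported. Both kernels are
verified against exhaustive brute-force enumerators in the test suite.

The positive class defaults to the **non-responder** (risk orientation):
with 28 non-responders and 42 responders, sens = 20/28 and spec = 30/42
give PPV 62.5% and NPV 78.9%, which is the arithmetic the published
predictive values follow. The orientation is configurable.

Two tests are combined with an AND rule under conditional independence:
sens_c = sens₁·sens₂ and spec_c = 1 − (1−spec₁)(1−spec₂). From the printed
inputs (0.714, 0.810) and (0.714, 0.571) this gives 57.83% and 87.73%.

## Synthetic cohort

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 70 | cohort size |
| `voxel_spacing_mm` | (5.3, 5.3, 5.0) | PET-native grid |
| `n_bone` | 3 | bone lesions per patient (all patients) |
| `p_lymph_node` / `p_other` | 33/70, 15/70 | site prevalences |
| `lesion_volume_range_cm3` | (7.8, 82.3) | uniform lesion volumes |
| `heterogeneity_link_rho` | −0.33 | Spearman(h, ΔPSA) target |
| `ap_link_rho` / `bap_link_rho` | −0.20 / −0.15 | weaker marker links |
| `responder_fraction_target` | 0.60 | P(ΔPSA < 0) |
| `ap_responder_fraction` / `bap_responder_fraction` | 41/70, 39/70 | per-marker response rates |
| `background_suv` | 1.0 | non-lesion uptake |
| `lesion_suv_mean_range` | (5, 15) | lesion SUV level |
| `lesion_contrast_fraction` | 0.6 | half-width of the SUV band, relative |
| `noise_sd` | 0.1 | additive white measurement noise (SUV) |
| `seed` | 0 | the single randomness source |

The reported cohort counted 328 VOIs against "about six" per patient; the
generator exposes the per-site counts as configuration instead of fixing
either number (the defaults give ≈4.9 lesions/patient).

**Clinical link.** Each patient has a latent heterogeneity score
h ~ N(0, 1). For each marker, a Gaussian copula z = r·h + √(1−r²)·ε with
r = 2 sin(πρ_s/6) converts the target Spearman link ρ_s into the Pearson
parameter; the marker delta is a strictly monotone quantile transform of
Φ(z) whose negative branch carries exactly the responder-fraction mass and
whose magnitudes are lognormal on both branches (heavy-tailed, as marker
changes are; scales: median |ΔPSA| 30 ng/ml, |ΔAP| 40 U/l, |ΔbAP| 15 µg/l —
chosen as realistic mCRPC magnitudes, the published study reports none).
Pre-therapy values are lognormal (median PSA 100 ng/ml, AP 150 U/l, bAP
40 µg/l) and are raised to 1.1·|Δ| where needed so post values stay
positive — a mild dependence accepted for physical plausibility. ECOG is
drawn once and held fixed pre/post (the study observed no change). Lesion
volume is drawn independently of h. Calibration is verified by test: over
500 cohorts of n = 70 the mean empirical Spearman(h, ΔPSA) is within
±0.02 of the target, mean responder count ≈ 42/70, and a null link fires
the p < 0.05 screen at the nominal rate.

**Lesion images.** The mask takes the `round(volume/voxel volume)` voxels
closest to the center of a mildly anisotropic ellipsoid (axis factors
0.75–1.3, volume-normalized), so realized volume is within one voxel-volume
of the request (7.8 cm³ at 5 mm isotropic spacing → 62 voxels). The texture
field is a Gaussian random field: a coarse component (white noise smoothed
with a σ = 2.0 voxel kernel) plus a fine white component with weight
0.3·e^{0.45h}, so the field's correlation length decreases strictly with h.
The field is *rank-rescaled* onto the lesion's SUV band — a copula-style
rescaling that gives uniform gray-level occupancy, so the quantized GLCM
features read out spatial correlation without a marginal-shape confound;
this is what makes entropy strictly increasing and homogeneity strictly
decreasing across an 8-point h grid for a fixed noise realization (tested
at the cohort's largest lesion volume with `noise_sd = 0`). At h ≤ −4 the
field degenerates to an exactly constant lesion. A fast path
(`generate_fast_cohort`) emits patient-level features directly from the
copula — entropy/homogeneity as deterministic monotone transforms of h,
the other features as h-independent draws — for tests needing hundreds of
replicates.

## What the phantom does and does not establish

Passing tests on synthetic cohorts show that the pipeline recovers planted
rank links at the configured strength, that the screen's type-I error is
nominal, and that every deterministic kernel matches an independent oracle.
They do not validate the biology: real PSMA-PET texture has scanner- and
reconstruction-dependent correlation structure, non-ellipsoidal lesions,
delineation variability, and site-dependent background — none of which the
phantom models. Two further honest gaps:

- Strict monotonicity of quantized entropy in h is only demonstrable for
  large lesions (~590 voxels); at the 62-voxel floor, quantization noise
  swamps the texture signal. This mirrors the clinical caveat that texture
  analysis of small lesions is unreliable.
- Image-path GLCM entropy increases with VOI voxel count (a known
  estimation property), so the phantom does *not* reproduce the near-zero
  feature–volume correlations reported for the clinical cohort; the
  `volume_independence` operation reports whatever the data show. The
  fast path draws volume independently of the features, which is where the
  volume-independence null property is tested.

## Numerical conventions

Entropy uses 0·log 0 ≡ 0 and returns exact 0.0 for single-cell matrices;
COV returns exact 0.0 for constant input. NGLCM validation tolerates 1e−9
in the sum-to-one check (construction is exact to rounding). All
replicate-based tests derive per-replicate generators from one base seed
via `numpy.random.SeedSequence`-style spawning (`rng_for_replicate`), so
suites are fully deterministic. Simulation sizes in the test suite (500
fast-path replicates, 100 oracle trials, 70-patient image cohorts) were
chosen so the whole suite runs in well under a minute while keeping Monte
Carlo error far below the asserted tolerances.
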