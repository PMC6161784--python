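# pethet

Texture-heterogeneity analysis of baseline PSMA-PET for predicting response
to ¹⁷⁷Lu-PSMA radioligand therapy.

In metastatic castration-resistant prostate cancer, roughly a third of
patients do not respond to ¹⁷⁷Lu-PSMA therapy, and identifying them before
treatment matters. One candidate biomarker is the *textural heterogeneity*
of lesions on the pre-therapy ⁶⁸Ga-PSMA PET scan. `pethet` implements that
analysis end to end as a tested, reusable pipeline:

1. **Features.** For each lesion VOI (volume of interest), SUVs are
   quantized to `Ng` gray levels (equal-width min–max bins, default 64) and
   a single symmetric 3D normalized gray-level co-occurrence matrix (NGLCM)
   is accumulated over all 13 unique distance-1 directions. From it:

   - entropy −Σᵢⱼ p(i,j) log₂ p(i,j)
   - homogeneity Σᵢⱼ p(i,j)/(1+|i−j|)
   - contrast Σᵢⱼ (i−j)² p(i,j)

   plus the first-order COV (σ/μ of raw SUVs), a voxel-to-voxel
   "size variation" statistic (mean |level − mean level of in-mask
   26-neighbors|), and SUVmean as the conventional comparator. Features are
   averaged per patient within each lesion site (bone / lymph node / other).
2. **Response.** Clinical deltas are post-therapy minus pre-therapy PSA,
   alkaline phosphatase (AP) and bone-specific AP (bAP); a strictly negative
   ΔPSA labels a responder.
3. **Statistics.** Each (site, feature, delta) pair is screened with
   two-sided Spearman correlation (α = 0.05, no multiplicity correction —
   the number of tests is reported); surviving features get ROC analysis
   against the responder label: Mann–Whitney AUC with the Hanley–McNeil
   standard error, a Youden-index cutoff J = sens + spec − 1, the full
   confusion metrics, and an AND-rule combination of two tests.
4. **Phantom.** Because the underlying clinical cohort is not public, a
   synthetic-cohort generator reproduces its statistical structure — 70
   patients, 3 bone lesions each, lymph-node/other lesions at the observed
   prevalences, lesion volumes 7.8–82.3 cm³ on a 5.3×5.3×5.0 mm grid, and a
   latent per-patient heterogeneity score tied to ΔPSA through a Gaussian
   copula with a configurable Spearman-scale strength (default −0.33) and a
   60/40 responder split.

See `docs/methods.md` for model details, parameter defaults and limitations.

## Worked example

```bash
pethet all --seed 7 --n-patients 70 --outdir out/
```

prints (abridged):

```
simulate: 70 patients, 342 lesions -> out/sim
extract: 342 lesions -> out/features
analyze: 54 correlation tests, 3 ROC analyses -> out/analysis
Patients: 70
  PSA responders: 46/70 (65.71%)
  AP responders: 47/70 (67.14%)
  BAP responders: 39/70 (55.71%)
ROC results:
  bone/homogeneity: AUC 0.720 [0.588, 0.852], cutoff >0.156225
  bone/contrast: AUC 0.730 [0.599, 0.861], cutoff <=286.155
  bone/size_variation: AUC 0.720 [0.588, 0.852], cutoff <=8.88146
Correlation tests performed (no multiplicity correction): 54
```

Reading this: of the 54 Spearman screens, homogeneity (rs = +0.41,
p = 4×10⁻⁴), contrast and size variation of bone lesions correlated with
ΔPSA at this seed and proceeded to ROC analysis; entropy (rs = −0.23,
p = 0.06) narrowly missed at the configured link strength of |ρ| ≈ 0.33 —
screening power at n = 70 is moderate, which is the realistic behavior. The
positive rs for homogeneity means responders (negative ΔPSA) have *lower*
homogeneity, i.e. more heterogeneous lesions respond better. The reported
AUCs use the non-responder as the positive class (risk orientation), with
the cutoff direction stated explicitly.

Stage outputs land in `out/sim` (NIfTI volumes/masks, `clinical.csv`,
`ground_truth.csv`), `out/features` (`features.csv`,
`patient_features.csv`), and `out/analysis` (`table1.csv` correlations,
`table2.csv` ROC, `table3.csv` confusion metrics, `results.json`). Each
stage writes a `metadata.json` with the seed, config hash and package
version; identical seeds give byte-identical outputs.

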