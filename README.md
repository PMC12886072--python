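# nichedose

Radiotherapy dose to the adult neurogenic niches — the subventricular zone
(SVZ) and the hippocampus (HPC, with its subgranular zone) — and its
relationship with overall survival in patients irradiated for brain
metastases.

Stereotactic radiosurgery spares most of the brain, but the dose shoulder
around each target still reaches the neurogenic niches, and both lesion
contact with a niche and the mean dose it absorbs have been reported as
independent negative prognostic factors. `nichedose` packages the full
analysis chain needed to study that question, for radiation-oncology and
neuro-oncology researchers working with co-registered dose maps and atlas
segmentations:

1. **Fractionation correction.** Mixed single- and hypofractionated
   regimens are made comparable through the linear-quadratic model:
   `BED = n·d·(1 + d/(α/β))`, and the single-fraction equivalent dose
   (SFED) is the positive root of `d² + d·(α/β) − BED·(α/β) = 0`, i.e.
   `SFED = (α/β)/2·(√(1 + 4·BED/(α/β)) − 1)`. With α/β = 2 Gy (late brain
   tissue), both 3 × 8 Gy and 5 × 6 Gy convert to 14.52 Gy. The same
   algebra runs voxelwise on whole NIfTI dose maps.
2. **Niche dosimetry.** Lesion–niche contact (≥ 1 voxel of a niche label
   inside the lesion mask, classified none/unilateral/bilateral), mean
   SFED per atlas subregion with lesion-affected labels excluded,
   cumulative dose–volume histograms, and lesion centrality (distance in
   cm from the PTV centre of gravity to the anterior commissure).
3. **Survival modelling.** Kaplan–Meier curves with log-rank tests by
   contact status; nested Cox proportional-hazards models (univariable →
   demographics/histology/niche volume → tumour burden and therapies →
   GTV volume) reporting the per-Gy hazard ratio of the mean niche dose;
   adjusted variance-inflation factors (GVIF^(1/2df)); sensitivity subsets
   (dropping the largest-PTV decile, single-metastasis patients, excluding
   the most central lesion decile); Spearman dose–burden correlations.
4. **Synthetic phantom and cohort.** Patient imaging of this kind cannot
   be shared, so a generator produces a brain phantom with bilateral
   SVZ/HPC labels, spherical GTV→PTV lesions with conformal plans meeting
   stereotactic constraints (≥ 98 % PTV coverage, ≤ 130 % point maximum),
   cohort tables with realistic covariate marginals, and Weibull
   proportional-hazards survival with configurable per-Gy niche effects —
   so every stage, including parameter recovery, runs with no external
   data.

## Worked example

```python
import nichedose as nd

scheme = nd.FractionationScheme(n=3, d=8.0, alpha_beta=2.0)
print(f"BED  = {nd.bed_scalar(scheme):.1f} Gy")
print(f"SFED = {nd.sfed_scheme(scheme):.2f} Gy")

cfg = nd.CohortSimConfig(n_patients=500, seed=7)
cohort = nd.generate_cohort_table(cfg)
print(f"cohort: n={len(cohort)}, events={int(cohort['event'].sum())}, "
      f"median OS = {cohort['os_months'].median():.1f} months")

res = nd.fit_cox(cohort, nd.MODEL_REGISTRY["svz_dose_m3"])
row = res.interest_row
print(f"svz_dose_m3 (n={res.n_used}): HR per Gy = {row['hr']:.3f} "
      f"(95% CI {row['ci_lower']:.3f}-{row['ci_upper']:.3f}, p = {row['p']:.2g})")

km = nd.km_by_group(cohort, "svz_contact")
for label, g in km.groups.items():
    print(f"SVZ contact = {label}: n = {g.n}, median OS = {g.median_months:.1f} months")
print(f"log-rank p = {km.logrank_p:.4f}, contact HR = {km.hr_cox:.2f}")
```

prints

```
BED  = 120.0 Gy
SFED = 14.52 Gy
cohort: n=500, events=480, median OS = 8.1 months
svz_dose_m3 (n=398): HR per Gy = 1.352 (95% CI 1.267-1.443, p = 1.4e-19)
SVZ contact = no: n = 366, median OS = 9.6 months
SVZ contact = yes: n = 134, median OS = 5.3 months
log-rank p = 0.0001, contact HR = 1.49
```

The regimen 3 × 8 Gy has BED 120 Gy and single-fraction equivalent
14.52 Gy. The simulated cohort was generated with a true per-Gy SVZ hazard
ratio of 1.306; the fully adjusted Cox model estimates 1.352 on this one
draw of 500 patients (n = 398 after complete-case exclusion of unknown
covariate levels), with the confidence interval covering the truth. Contact
patients receive more niche dose by construction, so their survival curves
separate: median 5.3 vs 9.6 months.

The same stages are available from the shell:

```bash
nichedose sfed-convert --in dose.nii.gz --out sfed.nii.gz --fractions 3
nichedose extract --dose sfed.nii.gz --labels atlas.nii.gz \
    --lesion lesion.nii.gz --label-scheme scheme.yaml --out features.csv
nichedose fit --cohort features.csv --model svz_dose_m3 --out results.json
nichedose simulate --n 138 --seed 17 --out-dir cohort/ --nifti
```

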