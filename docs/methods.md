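# Methods

This note records the models implemented in `nichedose`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish.

## Fractionation model

Doses are compared across regimens through the linear-quadratic model. A
course of `n` fractions of `d` Gy has biologically effective dose
`BED = n·d·(1 + d/(α/β))`; the single-fraction equivalent dose is the
positive root of `d² + d·(α/β) − BED·(α/β) = 0`,

    SFED = (α/β)/2 · (√(1 + 4·BED/(α/β)) − 1),

which reduces to `√(1 + 2·BED) − 1` at α/β = 2. The voxelwise variant
assumes each voxel received its total dose in `n` equal fractions
(`d_voxel = D/n`); heterogeneous per-voxel fraction counts are out of
scope. α/β is a parameter with default 2.0 Gy — the common choice for
late-responding brain tissue — not a constant, because different
organs-at-risk call for different ratios. Negative input voxels (possible
upstream interpolation artifacts) are clamped to zero before conversion,
with the count logged: the model has no physical meaning below zero dose.
The transform is strictly increasing, so voxel ordering and therefore DVH
shape ranks are preserved. No LQ extensions (repopulation, repair
kinetics) are modelled.

## Spatial data model

All volumes are NIfTI-1 with a trusted 4×4 affine (voxel indices are
0-based; world coordinates are mm; no RAS/LPS assumption is made beyond
the affine itself). Volumes interact only when aligned — equal shapes and
affines within 1e-6 — and misalignment is an error, never a silent
resample: registration belongs upstream of this pipeline. Dose maps are
stored as float32, labels as uint16. Voxel volume is |det| of the 3×3
affine block; structure volumes are reported in cm³.

## Niche dosimetry

Contact between a lesion and a niche is defined as ≥ 1 voxel of that
niche's atlas labels lying inside the lesion mask; per-side overlap counts
are retained so stricter thresholds remain testable, and sidedness yields
none/unilateral/bilateral status. Mean dose per atlas subregion is
computed over the subregion's voxels outside the lesion mask; subregions
fully swallowed by the lesion are reported as excluded rather than
dropped, and a structure with no surviving voxels has an explicitly
undefined (NaN) mean, never zero. The per-structure pooled mean is
voxel-count weighted by default (a simple average of subregion means is
available as an option; whether pooling should weight by volume is a
genuinely open choice, and voxel weighting is the one consistent with "the
mean over all included voxels"). DVHs are cumulative ("fraction of voxels
receiving ≥ t"), evaluated on a uniform grid with default bin width
0.1 Gy, in fractional volume. Centrality is the Euclidean distance in cm
from the unweighted PTV centre of gravity (affine-mapped voxel centres) to
the anterior commissure, which is taken as configurable world coordinates
with default (0, 0, 0) mm — the origin of the template frame.

## Survival analysis

Overall survival is months from radiotherapy to death, with a 0/1 event
flag. Kaplan–Meier medians are the smallest time at which the
product-limit curve reaches ≤ 0.5 and are reported with an explicit
not-reached sentinel, never infinity. Two hazard-ratio variants accompany
the log-rank test: the univariable Cox estimate (the primary one) and the
coarser O/E ratio from the log-rank table, since which of the two a KM
panel reports is often ambiguous.

Cox models use the Efron tie correction (the less biased of the common
defaults; event times in the synthetic data are continuous, so ties only
matter for degenerate inputs such as duplicated rows). Categorical
covariates are treatment-coded against fixed documented reference levels
(female, WHO 0, LUAD, single metastasis, no extracranial metastases, no
chemo/systemic therapy, no resection). Missingness follows a complete-case
policy per model — rows with an `unknown` level in any required
categorical are dropped and the n actually used is reported — mirroring
how nested analyses shrink as adjustment sets grow. Dose hazard ratios are
per Gy of mean niche SFED; the pooled bilateral mean is the default
exposure (per-side values remain accessible through the dosimetry
summary).

The four nested specs per niche and exposure are registered as
`{svz,hpc}_{dose,contact}_{m0..m3}`: m0 = exposure alone; m1 adds age,
sex, WHO performance status, histology and the niche's own volume; m2 adds
number of brain metastases, extracranial metastases, chemotherapy, other
systemic therapy and resection extent; m3 adds GTV volume.

Collinearity is assessed on each model's design matrix: single-column
covariates report the classical VIF `1/(1 − R²)`; multi-level categoricals
report the generalized VIF raised to `1/(2·df)` so magnitudes are
comparable across covariates. A rank-deficient design raises an error
naming the collinear columns. Correlations between niche dose and tumour
burden use Spearman rank (the relations are monotone, not linear), with
the metastasis count as an ordinal and centrality restricted to
single-metastasis patients. No multiple-testing correction is applied;
significance is read at p < 0.05, matching the analysis plan this package
implements. The three sensitivity subsets remove ⌈10 %⌉ of rows by largest
PTV, keep single-metastasis patients, or remove the most central ⌈10 %⌉ of
single-metastasis lesions; the fraction-based filters necessarily act on
whatever table they receive, so only the subgroup filter is idempotent.

## Synthetic phantom and cohort

The phantom is an ellipsoidal brain (semi-axes 66 × 82 × 60 mm, ≈1.5 L) on
a 49 × 59 × 49 lattice of 3 mm voxels with the anterior commissure at the
world origin. The SVZ is modelled as one-voxel-thick parasagittal sheets
at x = ±15 mm (three subregions along the anterior–posterior axis per
side; 10.8 cm³ total) and the HPC as mirrored ellipsoidal blobs
(head/tail subregions; ≈2.1 cm³ total), matching typical niche volumes.
The geometry is deterministic and left/right mirror symmetric.

Lesions are spheres of the requested GTV volume, dilated by a fixed 2 mm
margin to the PTV (a typical LINAC-SRS margin; configurable). Placement
policies guarantee the drawn contact status exactly: a contact lesion is
centred where the nearest niche voxel lies strictly inside the sphere, a
non-contact lesion keeps more than a voxel diagonal of clearance. Dose is
the prescription at the PTV surface, rising to a bounded core boost of at
most +25 % (plus small clipped positive noise, ≤ +2 %), and falling off
outside as an isotropic Gaussian with 5 mm scale. By construction every
plan achieves 100 % PTV coverage at prescription and ≤ ~128 % point
maximum, inside the stereotactic constraints (≥ 98 %, ≤ 130 %) the
validator checks. Multiple lesions of one patient share a prescription;
their doses combine by voxelwise maximum and their masks by union.
Prescription schemes are sampled from a realistic frequency mix
(dominated by 1 × 21 and 1 × 24 Gy, with 3 × 8 Gy the main
hypofractionated scheme) independent of lesion size.

Covariate marginals default to a published brain-metastasis series: median
age 67 (sd 10.4, clipped to 18–95), balanced sex, WHO 0/1/2/3 ≈
22/62/8/3 %, LUAD:LUSC ≈ 74:15, 51.4 % single metastasis, 32.6 %
extracranial disease, log-normal GTV (median 6.4 cm³) and niche volumes
(medians 10.8 / 1.6 cm³), 24.6 % SVZ and 3.6 % HPC contact. Missingness
is applied completely at random after survival is drawn (WHO 5.1 %,
histology 10.9 %, chemotherapy 2.2 %, other systemic therapy 3.6 %), so
complete-case fits remain consistent.

Survival follows a Weibull proportional-hazards model,
`S(t|x) = exp(−(t/λ)^k · e^{x'β})`, with shape k = 1.1 (mildly increasing
hazard) and the β vector applied to exactly the design coding the Cox fits
use; continuous covariates are centred at cohort medians inside the linear
predictor (which leaves hazard ratios untouched) so λ describes a
reference patient. Default effects include per-Gy hazard ratios of 1.306
(SVZ) and 1.222 (HPC) — the magnitudes the analysis is designed to
detect — plus modest clinically-signed effects for performance status,
burden and therapies. λ = 39 months calibrates the population median OS to
≈ 8.4 months under the default effect sizes; administrative censoring is
uniform over 26–90 months, the follow-up window implied by staggered
accrual with a fixed censoring date.

Two cohort routes share this survival model. The **tabular route** samples
mean niche doses directly from a log-normal model whose location rises
with log-GTV and metastasis count and jumps for contact lesions (shared
noise factor between the two niches reproduces their correlation);
intercepts are set so population median doses land at ≈ 1.50 Gy (SVZ) and
≈ 1.22 Gy (HPC). It is used for large simulation studies. The **imaging
route** runs the full voxel pipeline per patient — placement, plan
synthesis, SFED conversion, feature extraction — before the identical
survival draw, exercising every stage end to end; it uses one master seed
with deterministic per-patient substreams, so individual patients can be
regenerated in isolation.

### Parameter-recovery design

The nested Cox models include one niche's mean dose but never both, while
the two doses are correlated through shared plan geometry. A recovery
experiment — "does the fitted model return the configured hazard ratio?" —
is therefore only well-posed when the generating truth matches the fitted
model: the recovery configuration (`recovery_config`) keeps the studied
niche's per-Gy effect and switches the other niche's direct dose effect
off. With both effects active the single-dose models are confounded by the
omitted correlated exposure (the recovered SVZ HR rises to ≈ 1.32 and the
HPC HR to ≈ 1.29 in our measurements) — a genuine feature of
single-exposure modelling under correlated doses, and a property of the
model, not a failure of the estimator. Recovery runs use cohorts of
n = 2000 over ≥ 20 replicates, sizes at which the Monte-Carlo standard
error of the mean recovered HR is ≈ 0.003–0.007.

## What the synthetic data do not show

* The phantom's niches are geometric idealisations; real SVZ/HPC
  segmentations are thin, curved and individually variable, and real
  inter-subject registration error is absent here.
* The dose model has no low-dose bath from arc entry/exit, so niche doses
  in the *imaging* route are lower than clinical values whenever the
  lesion is far from the niche (median well under 1 Gy); the tabular route
  is calibrated to clinical dose levels and is the one used for
  statistical claims.
* Survival is exactly proportional-hazards by construction, the event
  fraction (≈ 95 %) is higher than in referral cohorts (≈ 78 %), and the
  prescription mix ignores the size-dependence of real dose prescriptions.
  Passing recovery tests therefore demonstrates correctness of the
  estimation machinery under the assumed model, not robustness to
  violations of it.
* Cohort-specific clinical results (median OS by contact group, contact
  hazard ratios) depend on the unshareable patient data and are not
  reproduction targets; the package reproduces the published *worked
  conversions* exactly and the *effect-size magnitudes* as configured
  truths.

## Numerical and degenerate-input conventions

Alignment tolerance is 1e-6 on affines. The BED inversion is evaluated in
closed form (no iteration); round-trip accuracy is 1e-9 relative over
d ∈ [0, 100] Gy. DVHs use `searchsorted` on sorted doses, exact against a
sort-and-count oracle. Empty masks, empty groups, zero-event models,
negative BED and rank-deficient designs are errors; non-convergence of a
Cox fit is flagged on the result rather than raised. Sensitivity filters
use stable ordering so ties break by original row order. Problem sizes in
the test suite (8³ voxel maps, 50 plans, 20–40 recovery replicates of
n = 2000, 500 null cohorts for log-rank calibration) are chosen to give
sub-minute feedback per module while keeping Monte-Carlo bands tight
enough to be meaningful.
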