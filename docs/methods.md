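# Methods

`petlymph` implements the quantitative reading of baseline FDG-PET in
aggressive lymphoma (mantle cell lymphoma is the motivating setting), the
end-of-treatment response assessment, and the survival analysis that links
the two. This note records the models, the defaults and why they are what
they are, and what the synthetic data do and do not establish.

## Image quantification

**SUV normalizations.** Activity concentration C (kBq/mL) is normalized by
injected dose over body weight (SUVbw, grams), lean body mass (SUVlbm,
James 1976 equations; the Janmahasatian 2005 fat-free-mass model is a
config alternative) or Du Bois body surface area
(BSA = 0.007184·H^0.725·W^0.425 m², H in cm, W in kg). SUVbsa has no
universal unit convention: we report the value with BSA expressed in cm²
(C/(ID/BSA_cm²)), which places it in the low single digits for adults
(SUVbw 10 → SUVbsa ≈ 2.5), the convention clinical software prints; the
raw m² value is also exposed. Injected activity is taken as already
decay-corrected to scan start.

**Lesion segmentation.** Hypermetabolic foci are found as connected
components (26-connectivity default; 6/18 configurable) of voxels at or
above a fixed seed threshold (SUV 2.5 default). This automated seeding
stands in for the reader's manual focus selection and assumes the volume
contains no physiologic structures above the seed threshold — phantoms
satisfy this; patient data would need organ masks. Each seed then grows a
per-lesion isocontour at 41% of its own SUVmax (the EANM-recommended
relative threshold), restricted to the connected piece containing the
seed's hottest voxel within the seed's bounding box dilated by 10 voxels.
Components below `min_voxels` (default 2; 1 for phantom work) are
discarded as noise. MTV sums lesion volumes; TLG sums volume × SUVmean
with SUVmean in body-weight units (the prevailing convention). Centroids
are intensity-weighted in physical mm.

**Dissemination.** Dmax is the largest pairwise Euclidean distance between
lesion reference points, reported in cm; intensity-weighted centroids are
the default reference (the hottest voxel is an alternative — the
literature uses both, and on compact lesions they differ by less than a
voxel). Dmax-bsa = Dmax / BSA. The simple quotient is the only convention
consistent with typical adult numbers (population means 54.6 cm and
29.5 cm/m² imply BSA ≈ 1.85 m²).

**Response.** Deauville 1–5 from the hottest residual focus against
mediastinal blood pool and liver: ≤ mediastinum → 2, ≤ liver → 3 (equality
with the liver scores 3, standard Deauville semantics), ≤ k·liver → 4,
else 5, with k = 2 by default ("moderately" vs "markedly" above liver is a
qualitative boundary; 2–3× liver is the accepted range and 2 is the
conservative choice). New lesions force score 5 and a non-complete call.
Lugano: complete metabolic response ⇔ score 1–3 and no new lesions.

## Survival statistics

Kaplan-Meier product-limit curves with the median defined as the earliest
event time where S(t) ≤ 0.5 (undefined, "not reached", if the curve never
crosses). Two-group comparisons use the two-sided log-rank test (1 df).
Effect sizes come from Cox proportional-hazards regression, maximized by
Newton-Raphson with step-halving on the partial likelihood; Efron tie
handling is the default (Breslow available, since SPSS-era analyses used
it), Wald 95% CIs as exp(β ± 1.96·se). Non-convergence and monotone
likelihood (|β| > 20, perfect separation) are flagged on the results
object, never silently returned. The implementation is cross-checked in
the test suite against lifelines (Efron) and statsmodels PHReg (Breslow)
to 1e-5 and 1e-8 respectively.

Continuous PET features are dichotomized at the ROC cutoff maximizing
Youden's J against the endpoint's event indicator, scanning midpoints of
consecutive sorted unique values, ties resolved to the lowest threshold;
AUC is the trapezoidal area. Using the event flag and ignoring censoring
time is a deliberate simplification (time-dependent ROC is out of scope);
it also means a null feature cut at its "optimal" threshold is
optimistically biased, so null-calibration checks use fixed median splits.
Multivariate models take the univariately significant covariates
(p < 0.05, two-sided, no multiplicity correction) with no stepwise
refinement. The combined stratification crosses the baseline-MTV dichotomy
(strictly above cutoff = high) with the binary metabolic response into
four groups; patients with no response assessment are excluded with a
logged count.

## Synthetic data

**Phantoms** are uniform-background grids with non-overlapping ellipsoidal
lesions of uniform interior SUV; a voxel belongs to a lesion when its
center falls inside the ellipsoid. Ground truth stores the analytic volume
(4/3·π·r₁r₂r₃) and exact center, so segmentation accuracy is measured
against mathematics, not against another rasterization. Overlap checking
uses enclosing spheres — conservative, but it keeps the ground truth
unambiguous. Optional Gaussian noise (SD in SUV units) is truncated at
zero. Scanner physics — scatter, partial-volume blur, reconstruction — is
deliberately absent, so passing phantom tests shows geometric correctness
of the pipeline, not robustness to real acquisition effects. At
radius/voxel ratios ≥ 5 the voxel-center rasterization itself deviates
from the analytic volume by under ~2%, which is why the phantom acceptance
checks use radii ≥ 10 mm at 2 mm voxels.

**Cohorts** are feature-level simulations of an advanced-MCL population
(n = 120 default, matching the motivating study size): ≥ 2 lesions per
patient (2 + Poisson(3)), log-normal SUVbw (median 9.8, σ_log 0.33,
clipped 3.5–14.5) and MTV (median 358 cm³, σ_log 0.794, clipped
2–4000 cm³), TLG from a Dirichlet split of MTV across lesions with
SUVmean/SUVmax = 0.7, lesion centers scattered over an axial span of
0.47 × height with 5 cm transaxial jitter (giving Dmax ≈ 55 ± 18 cm), and
clinical covariate marginals matching the published frequencies. Only the
marginals are constrained by published tables; the joint law is a modeling
choice and is documented entirely by these defaults. Incomplete response
follows a logistic model in age (+0.04/year) and high Ki-67 (+1.0 logit),
calibrated to a ~30% marginal rate.

**Survival generation.** Latent progression and death times are Weibull
proportional hazards given the covariates: progression with shape 1.1,
scale 85 months and log-HRs ln 2.7 (high MTV) and ln 3.5 (incomplete
response); death with shape 1.1, scale 112 months and log-HR ln 1.75
(high Dmax-bsa); administrative censoring at 120 months. "High" is the
within-cohort median split, recorded in `df.attrs`. The two latent times
are conditionally independent; a death before progression right-censors
PFS at the death time. This coupling guarantees observed PFS ≤ OS for
every patient while keeping both endpoints exactly proportional-hazards in
their generating covariates — the alternative coupling (OS = progression
time plus a post-progression exponential) destroys the PH structure of OS
and would make hazard-ratio recovery tests systematically fail for reasons
unrelated to the estimator. A consequence of the chosen effect pattern is
that the four combined strata order as low-MTV/CMR > high-MTV/CMR >
low-MTV/nonCMR > high-MTV/nonCMR in median PFS: with a response HR (3.5)
larger than the MTV HR (2.7) and independent features, high-burden
complete responders must outlive low-burden non-responders under any
main-effects PH model, even though some clinical series report the middle
pair the other way around (which would require an interaction or
correlated features). The extremes — low-burden complete responders best,
high-burden non-responders worst — are robust.

Under these defaults the simulated cohort lands near the motivating
clinical numbers without further adjustment: at n = 120 the KM median PFS
is ≈ 21–33 months and median OS ≈ 56–61 months across seeds, and the
best/worst strata medians at large n are ≈ 58 and ≈ 8 months.

## Numerical choices and degenerate inputs

- Dmax with < 2 lesions returns 0 with a `degenerate` flag, not an error.
- Single-voxel seed components segment to single-voxel lesions.
- KM median is `None` when the curve never reaches 0.5; tables report
  "not reached".
- ROC ties in Youden's J resolve to the lowest threshold; Dmax ties to the
  lexicographically smallest lesion pair.
- Cox Newton iterations stop at |Δ log-likelihood| < 1e-10 with gradient
  sup-norm < 1e-7; the linear predictor is max-shifted before
  exponentiation to avoid overflow.
- All generators draw from a single `numpy` Generator seeded explicitly;
  outputs are bit-reproducible for a fixed seed and the seed is recorded
  in output metadata.

## Known limitations

- No physiologic-uptake handling: real scans would need organ masks before
  seeding; the automated fixed-SUV seeding replaces a manual step the
  original workflow leaves undescribed.
- The ROC cutoff ignores censoring time.
- The simulator's joint feature law is a stated convention, not an
  estimate; MTV, Dmax and SUV are drawn independently, so analyses of
  their collinearity are out of reach.
- No partial-volume correction, no interim-PET response, no competing
  risks.
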