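# petlymph

Quantitative FDG-PET tumor burden, dissemination and survival prognostics
for aggressive lymphoma.

In mantle cell lymphoma and related aggressive B-cell lymphomas, the
baseline PET scan carries prognostic information beyond staging: the
**metabolic tumor volume** (MTV, the summed volume of all lesion voxels
above a per-lesion 41%-of-SUVmax isocontour), the **total lesion
glycolysis** (TLG = Σᵢ MTVᵢ·SUVmeanᵢ), and the **maximum tumor
dissemination** (Dmax, the largest Euclidean distance between any two
lesions, optionally normalized by Du Bois body surface area as
Dmax/BSA). After therapy, the **Deauville five-point scale** grades
residual uptake against mediastinal blood pool and liver, and the
**Lugano classification** collapses it to complete (scores 1–3) vs
non-complete (4–5) metabolic response. Prognostic value is assessed the
standard way: ROC-derived cutoffs dichotomize the continuous features,
Kaplan–Meier curves and two-sided log-rank tests compare groups, and Cox
proportional-hazards regression reports hazard ratios
HR = exp(β) with 95% Wald intervals for progression-free and overall
survival.

`petlymph` implements this whole chain as a tested library: SUV
normalizations (body weight, James lean body mass, Du Bois BSA),
automated lesion detection and 41%-isocontour segmentation on NIfTI
volumes, dissemination metrics, response scoring, the survival
statistics (Kaplan–Meier, log-rank, and an Efron/Breslow Cox partial
likelihood with a statsmodels-style `CoxPH` → `CoxResults.summary()`
API), plus synthetic PET phantoms with exact analytic ground truth and
cohort simulators with known hazard structure so every stage is
verifiable without patient data.

## Worked example

```python
import numpy as np
from petlymph import (PhantomSpec, PhantomLesion, generate_phantom,
                      segment_lesions, dmax, dmax_bsa, du_bois_bsa)

spec = PhantomSpec(
    grid_shape=(60, 60, 80), voxel_spacing_mm=(2, 2, 2), background_suv=0.5,
    lesions=[PhantomLesion((60.3, 60.7, 40.1), (10, 10, 10), 8.0),
             PhantomLesion((30.2, 30.9, 120.4), (8, 8, 8), 6.0)])
vol, truth = generate_phantom(spec)

lesions = segment_lesions(vol, min_voxels=1)
print(len(lesions), lesions.total_mtv_cm3, lesions.total_tlg)
d = dmax(lesions)
bsa = du_bois_bsa(weight_kg=78, height_cm=174)
print(d.dmax_cm, bsa, dmax_bsa(d.dmax_cm, bsa))
```

prints (rounded):

```
2 lesions, MTV 6.34 cm^3, TLG 46.5
Dmax 9.08 cm, BSA 1.927 m^2, Dmax-bsa 4.71 cm/m^2
```

The two segmented volumes (4.21 and 2.14 cm³) sit within 1% of the
analytic ellipsoid volumes (4.19 and 2.14 cm³) — the phantom stores the
exact 4/3·π·r₁r₂r₃ truth, so the 41% isocontour is checked against
mathematics rather than another rasterization. Dmax is the centroid
distance of the two spheres; dividing by the Du Bois BSA gives the
body-size-corrected dissemination.

On the survival side, a simulated 120-patient cohort (the generator's
defaults encode HR 2.7 for high MTV and 3.5 for non-complete response on
progression) fits in one line:

```python
from petlymph import CohortSimConfig, CoxPH, generate_cohort

df = generate_cohort(CohortSimConfig(n_patients=120, seed=1))
fit = CoxPH.from_dataframe(df, "pfs_months", "pfs_event",
                           ["high_mtv_true", "non_complete_response"]).fit()
print(fit.summary().round(3))
```

```
                        coef     HR  HR 95% CI low  HR 95% CI high      z      p
high_mtv_true          0.678  1.970          1.204           3.224  2.700  0.007
non_complete_response  1.119  3.061          1.768           5.299  3.997  0.000
```

At n = 120 the point estimates scatter around the generating values; the
acceptance script below shows they concentrate there as replicates
accumulate.

A CLI wraps the same machinery:

```bash
petlymph simulate --n-patients 200 --seed 1 --out run/
petlymph survival --cohort run/cohort.csv --out run/analysis/
petlymph report   --cohort run/cohort.csv --out run/report/
```

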