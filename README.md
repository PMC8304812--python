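# radstab

Stability of 3D CT texture features to lesion delineation and intensity
quantisation.

Radiomics models built on CT texture features are only portable across
institutions if the features are robust to the two knobs that vary most in
practice: *who drew the lesion contour* and *how the HU signal was
discretised*. `radstab` implements a complete, reproducible desk-scale
version of that stability analysis for lung-nodule-like regions of
interest: 88 IBSI-style texture features from six classes — first-order
(13), grey-level co-occurrence matrix (24), grey-level dependence matrix
(14), grey-level run-length matrix (16), grey-level size-zone matrix (16)
and neighbouring grey-tone difference matrix (5) — evaluated under two
experimental scenarios on synthetic nodule phantoms with simulated
multi-rater delineations.

## The statistic

For one nodule *i* with readings *x*<sub>*i*1</sub> … *x*<sub>*iJ*</sub> of
one feature (one per rater, or one per quantisation level *N*<sub>g</sub>),
the per-nodule stability is the average pairwise symmetric MAPE,

&nbsp;&nbsp;&nbsp;&nbsp;*S*<sub>*i*</sub> = mean over pairs (*f*, *t*) of
100·|*x*<sub>*if*</sub> − *x*<sub>*it*</sub>| / (|*x*<sub>*if*</sub>| + |*x*<sub>*it*</sub>|),

with the customary halving of the denominator omitted so *S*<sub>*i*</sub> ∈
[0, 100]. The population statistic *S* is the mean of *S*<sub>*i*</sub>
over nodules, graded **excellent** (*S* ≤ 5), **good** (5 < *S* ≤ 10),
**moderate** (10 < *S* ≤ 20) or **poor** (20 < *S* ≤ 100).

Two scenarios are provided:

* **A — delineation**: fixed *N*<sub>g</sub> = 256, one reading per rater
  mask (J = 4 simulated observers per nodule);
* **B — quantisation**: one 50%-agreement consensus mask per nodule, one
  reading per *N*<sub>g</sub> ∈ {32, 64, 128, 256}, the quantisation levels
  playing the role of raters.

Preprocessing clips HU values to an absolute window (default −583 … 137 HU,
i.e. level −223 HU / width 720 HU, derivable from any cohort as
μ<sub>d</sub> ± 2σ<sub>d</sub> of the per-nodule mean densities) and
quantises them into *N*<sub>g</sub> equal bins.

## Worked example

```python
from radstab import *

# a textured spherical phantom and four simulated rater contours
vol, mask = generate_phantom(PhantomSpec(seed=5))
raters = simulate_raters(mask, RaterModel(n_raters=4, boundary_jitter_sigma=1.0, seed=6))
print("dice:", [round(dice(r, mask), 3) for r in raters])

fv = extract_all(vol, mask, WindowSettings(), QuantisationConfig(64))
for k in ("firstorder_Max", "firstorder_Entropy", "glcm_Contr", "ngtdm_Coarseness"):
    print(k, "=", round(fv[k], 4))

readings = [extract_all(vol, r, WindowSettings(), QuantisationConfig(64))["firstorder_Mean"]
            for r in raters]
print("mean HU per rater:", [round(x, 2) for x in readings])
s = nodule_smape(readings)
print("S_i =", round(s, 3), "grade:", grade(s))
```

prints

```
dice: [0.969, 0.902, 0.931, 0.9]
firstorder_Max = 29.4427
firstorder_Entropy = 5.1836
glcm_Contr = 34.8319
ngtdm_Coarseness = 0.02
mean HU per rater: [-257.69, -302.06, -272.16, -273.3]
S_i = 4.002 grade: excellent
```

The four rater masks overlap the base contour at Dice 0.90–0.97; the mean
in-mask density varies by a few percent across them, giving this nodule an
*excellent* per-nodule stability of 4.0% for the Mean feature.

The same pipeline runs from the shell:

```
radstab run-all --n-nodules 20 --seed 0 --out runs/demo
```

which generates a 20-nodule cohort (volumes and masks as NRRD, manifest as
CSV) and writes both per-feature stability tables
(`stability_scenario_A.csv`, `stability_scenario_B.csv`, 88 rows each with
columns feature, class, S, grade, n_nodules_used, n_excluded).

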