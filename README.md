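# rtimagerisk

Radiobiological analysis of the dose delivered by **daily MV-CBCT setup
imaging** in radiotherapy. Daily megavoltage cone-beam CT (e.g. on ring
gantry linacs) uses the treatment beam itself, so every fraction adds a
small but non-negligible dose — several centigray — to organs at risk. Over
a 25–35 fraction course this accumulates to tenths of a gray or more, and
the clinically interesting question is whether the higher-quality 10 MU
imaging protocol carries a meaningfully larger long-term risk than the 5 MU
one, and for whom.

`rtimagerisk` answers that question quantitatively for a cohort of DICOM-RT
datasets. For patients it computes, per contoured organ at risk:

* **mean dose** over the accumulated course
  (treatment beam + per-fraction imaging dose × number of fractions, with
  imaging dose scaled linearly in monitor units),
* **NTCP**, the normal-tissue complication probability, via the logistic
  model on mean dose

  $$\mathrm{NTCP} = \frac{1}{1 + e^{\gamma\,(D_{50} - D)}}$$

  or the Lyman–Kutcher–Burman probit model
  $\mathrm{NTCP} = \Phi\!\big((\mathrm{gEUD} - D_{50}) / (m\,D_{50})\big)$
  on the generalized equivalent uniform dose
  $\mathrm{gEUD} = (\sum_i v_i D_i^{1/n})^n$,
* **OED**, Schneider's organ equivalent dose with linear-exponential cell
  sterilization, from the differential DVH:

  $$\mathrm{OED} = \sum_i v_i\, D_i\, e^{-\alpha' D_i}, \qquad \alpha' = 0.085\ \mathrm{Gy}^{-1}$$

* **EAR**, the excess absolute risk of a radiation-induced second cancer in
  cases per 10 000 person-years:

  $$\mathrm{EAR} = \mathrm{EAR}_0 \cdot \mathrm{OED} \cdot \mu(e, a), \qquad
  \mu(e,a) = e^{\gamma_e (e - e_0)} \left(\frac{a}{a_0}\right)^{\gamma_a}$$

  with $e$ the age at exposure, $a$ the attained age (fixed at 70), and
  organ-specific coefficients from a citable parameter registry.

Cohorts are compared between imaging protocols with two-tailed paired
t-tests per organ and metric, and EAR is stratified into three
age-at-exposure groups (< 40, 40–60, > 60 years).

Because clinical DICOM cannot be redistributed, the package ships a seeded
**synthetic phantom-cohort generator** (`rtimagerisk.synthdata`) producing
standard RTSTRUCT/RTDOSE files for breast, pelvic and head & neck
phantoms, with per-ROI course doses calibrated to the magnitudes typical of
those treatments. Everything downstream of the generator treats its output
as ordinary DICOM-RT.

## Worked example

```bash
# 1. generate a 10-patient synthetic breast cohort
rtimagerisk synth --site breast --n 10 --seed 42 --out phantoms/
# 2. compare the 5 MU and 10 MU daily imaging protocols, course-total dose
rtimagerisk run --manifest phantoms/manifest.csv --out results/
```

The same analysis from Python:

```python
from rtimagerisk import (AnalysisConfig, ProtocolSpec, CohortSpec,
                         generate_cohort, load_manifest, compare_protocols)

manifest = generate_cohort(CohortSpec(site="breast", n_patients=10, seed=42), "phantoms")
records = load_manifest(manifest)
report = compare_protocols(records,
                           ProtocolSpec("5MU", 5, 25),
                           ProtocolSpec("10MU", 10, 25),
                           AnalysisConfig())
s = report.summaries
lung = s[(s.roi == "Lung_IPSI") & (s.metric == "mean_dose_gy")]
print(lung[["protocol", "mean", "sd"]].to_string(index=False))
comp = report.comparisons
print(comp[(comp.roi == "Lung_IPSI") & (comp.metric == "mean_dose_gy")]
      [["metric", "p_value", "significant"]].to_string(index=False))
```

prints

```
protocol      mean       sd
    10MU 21.041338 2.676440
     5MU 20.313766 2.677016
      metric      p_value  significant
mean_dose_gy 2.227275e-18         True
```

i.e. on this phantom cohort the ipsilateral lung receives a course-total
mean dose of 20.3 ± 2.7 Gy under daily 5 MU imaging and 21.0 ± 2.7 Gy under
10 MU — the ~0.75 Gy difference is pure imaging dose, detected by the
paired t-test at p ≪ 0.001 even though it is small against the treatment
dose. `report.strata` further shows mean EAR falling monotonically from the
< 40 to the > 60 age group for every organ, the inverse age dependence that
motivates age-stratified imaging protocols.

Organ parameters ($D_{50}$, $\gamma$, $m$, $n$, $\mathrm{EAR}_0$,
$\gamma_e$, $\gamma_a$, …) live in a JSON registry with a citation on every
record; pass `registry_path=` (or a user file merged over the defaults) to
swap in institutional values without code changes. A sensitivity sweep
(`rtimagerisk sweep --param alpha_prime --values 0,0.085,0.2 ...`) shows how
any single model parameter moves the results.

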