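# ambicox

Weighted Cox analysis for **ambispective** cohort designs — cohorts that
combine retrospectively ascertained pre-inclusion events with prospectively
collected follow-up.

## The problem

In registries of patients with a first venous thromboembolism (VT), many
first recurrences happen *before* the patient is ever enrolled.  For
time-fixed risk factors (sex, genotype, characteristics of the first
event), those pre-inclusion recurrences carry real information, and
discarding them — as a standard prospective analysis does — can waste the
majority of events.  But using them naively introduces survivorship bias:
a patient is only observed if they lived long enough to be included and,
for post-inclusion follow-up, to be recontacted.  Patients at high risk of
death are under-represented, and any covariate associated with mortality
picks up a spurious association with recurrence.

`ambicox` implements an inverse-probability-of-selection weighting scheme
for this design.  The recurrence model is a Cox proportional-hazards model
on the delay-since-first-VT time scale,

λ(t, Z) = λ₀(t) · exp(βᵀZ),

fitted with per-subject weights

wᵢ = N · (1/sᵢ) / Σⱼ (1/sⱼ),

where sᵢ is the estimated probability that patient *i* survived from the
first VT to the time their recurrence information was collected — the
recontact date for responders, the inclusion date for everyone else — and
N is the analysed sample size.  The sᵢ come from a **delayed-entry Cox
model for death on the age time scale** (patients enter the death risk set
at their age of inclusion), so the age effect on mortality is handled
non-parametrically.  Because the weights induce within-subject correlation,
coefficient variances use the robust sandwich estimator
I⁻¹ (Σᵢ UᵢUᵢᵀ) I⁻¹ built from per-subject weighted score residuals.

The package also provides:

* **ABO diplotype inference** from best-guess dosages at five tag
  polymorphisms (rs8176719-delG → O1, rs41302905-T → O2, rs2519093-T → A1,
  rs1053878-A → A2, rs8176743-T → B), with additive O1-reference coding —
  the motivating application is the association of ABO blood groups with
  VT recurrence;
* **fixed-effect meta-analysis** of study-level hazard ratios on the
  log scale with inverse-variance weights;
* a **Monte-Carlo sensitivity analysis** that propagates death-model
  uncertainty through the weights;
* a **synthetic ambispective cohort simulator** with latent truth, used by
  the test-suite to check estimator calibration and the bias-reduction
  property.

## Worked example

```python
from ambicox import (SimConfig, generate_cohort, fit_death_model,
                     compute_weights, fit_recurrence, meta_fixed)

cfg = SimConfig(n_subjects=1500, seed=42, gompertz_rate=2e-4)
sim = generate_cohort(cfg)
print(f"{len(sim.records)} patients observed; {sim.n_excluded_dead} died before inclusion")
print("case counts:", sim.case_counts)

death_fit = fit_death_model(sim.records)
weights = compute_weights(death_fit, sim.records)
d = weights.diagnostics
print(f"weights in [{d['min_weight']:.2f}, {d['max_weight']:.2f}], "
      f"effective sample size {d['effective_sample_size']:.0f}")

fit = fit_recurrence(sim.records, "ambispective", weights=weights)
lo, hi = fit.confidence_intervals(robust=True)
for name, hr, l, h in zip(fit.covariate_names, fit.hazard_ratios(), lo, hi):
    print(f"{name:9s} HR {hr:5.2f} ({l:.2f}-{h:.2f})")

meta = meta_fixed([(1.65, 1.36, 2.01), (1.81, 1.46, 2.25)])
mlo, mhi = meta.ci
print(f"combined HR {meta.hr:.2f} ({mlo:.2f}-{mhi:.2f}), p = {meta.p:.1e}")
```

prints

```
1444 patients observed; 56 died before inclusion
case counts: {'CASE4': 453, 'CASE3': 279, 'CASE2': 257, 'CASE1': 455}
weights in [0.94, 3.70], effective sample size 1402
A1        HR  1.16 (1.03-1.31)
A2        HR  1.13 (0.86-1.49)
B         HR  1.17 (0.97-1.42)
O2        HR  0.68 (0.40-1.14)
sex       HR  1.64 (1.41-1.91)
provoked  HR  0.99 (0.85-1.17)
age10     HR  1.09 (1.03-1.15)
dvt       HR  1.19 (0.97-1.46)
pc1       HR  0.98 (0.91-1.06)
pc2       HR  1.03 (0.96-1.11)
pc3       HR  1.03 (0.95-1.11)
pc4       HR  0.96 (0.90-1.04)
combined HR 1.72 (1.49-1.99), p = 2.2e-13
```

Reading the output: of 1,500 simulated VT patients, 56 died before their
inclusion visit and are never observed (the survivorship the weights
correct).  The four case counts are the design configurations of the
observed patients — no pre-inclusion recurrence with (Case 1) or without
(Case 2) an event during follow-up, lost to follow-up (Case 3), recurrence
before inclusion (Case 4).  The weighted ambispective fit recovers hazard
ratios close to the generating values (e.g. sex 1.64 vs a true 1.65; A1
1.16 vs 1.15), with robust confidence intervals.  The final line combines
two study-level sex hazard ratios into a fixed-effect summary.

The same workflow is available from the shell:

```
ambicox simulate -n 1500 --seed 42 -o simdir
ambicox fit-death simdir/cohort.csv -o death.json
ambicox weights simdir/cohort.csv --death-fit death.json -o weights.csv
ambicox fit-recurrence simdir/cohort.csv --design ambispective \
    --weights weights.csv -o fit.json
ambicox meta studies.csv -o meta.json
ambicox sensitivity simdir/cohort.csv --B 100 --seed 1 -o sens.csv
```

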