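# nodulegrowth

Growth kinetics of early-stage lung adenocarcinoma on serial CT follow-up,
and their use in predicting lymph-node (LN) metastasis.

Pulmonary nodules found on screening CT are followed over months; how fast a
nodule grows carries prognostic information that a single scan cannot.  This
package implements, as a tested and reusable pipeline, the standard
growth-kinetics analysis for such cohorts: per-nodule relative change and
doubling times, explicit eligibility filtering, and the statistical battery
relating growth to pathologic nodal status — plus a calibrated synthetic
cohort generator so every stage is exercisable without access to patient
data.  It is aimed at thoracic-imaging and clinical-epidemiology researchers
working with tabular follow-up measurements (no DICOM or segmentation here;
volumes and attenuations are inputs).

## The model

Assuming exponential growth, two measurements `V0` (baseline) and `Vt`
(follow-up) separated by `ΔT` days give the **volume doubling time** by the
modified Schwartz formula:

    VDT = ln(2) · ΔT / ln(Vt / V0)

Mean CT attenuation in Hounsfield units converts to physical density as
`ρ = HU + 1000` (mg/mL), nodule mass is `M = V · ρ · 10⁻⁶` (g), and the
**mass doubling time** MDT applies the same formula to `(M0, Mt)`.  Both are
computed for the whole nodule (suffix `t`) and for the solid component
(suffix `c`; identical for fully solid nodules, whose consolidation/tumour
ratio C/T is 1).  Doubling times are only defined for growing lesions; the
conventional inclusion rule is a relative volume change of at least 25%.

Downstream, nodal status (N0 vs N1/2) is analysed with group comparisons
(Welch t / Mann-Whitney / chi-square, Pearson contingency coefficient
`C = √(χ²/(χ²+n))`), a univariable screen, multivariable logistic regression
(odds ratios with Wald 95% CIs), and ROC analysis with the AUC computed by
the rank construction, a DeLong 95% CI, and the operating threshold chosen
by maximising Youden's J — with the *lower-is-positive* direction, since a
shorter doubling time means faster growth and higher metastatic risk.

## Worked example

The doubling-time primitive on a published-style vignette — a part-solid
nodule whose volume grew 108.28% over 540 days:

```python
>>> from nodulegrowth import GrowthPair, doubling_time
>>> round(doubling_time(GrowthPair(1000, 2082.8, 540)))
510
```

i.e. this nodule doubles its volume roughly every 510 days.  A full cohort
analysis on simulated data:

```python
import nodulegrowth as ng

measurements, patients, truth = ng.simulate_cohort(
    ng.SimulationConfig(n_patients=144, seed=7))
results = ng.NoduleCohortModel(measurements, patients).fit(
    covariates="doubling_time", roc_on=("vdt_t",))
print(results.summary())
```

```
Nodule growth-kinetics cohort analysis
================================================
records: 144   included: 137   growth analysis set (>=25% volume): 91
exclusions: shrinkage=6, follow_up_window=1

mean doubling times (days) over growth set:
             vdt_t  mdt_t  vdt_c  mdt_c
nodule_type
SN           331.0  292.0  331.0  292.0
pSN          347.0  312.0  308.0  280.0

ROC vdt_t vs LN metastasis (lower-is-positive): AUC 0.814 (95% CI 0.714-0.914), threshold 255 d, sensitivity 76.7%, specificity 78.7%

multivariable logistic model (odds ratios, Wald 95% CI):
            variable      or_   ci_low  ci_high        p p_formatted
baseline_diameter_mm 1.106085 0.970741 1.260299 0.130014       0.130
               vdt_t 0.991462 0.986604 0.996343 0.000622      <0.001
```

Reading this: of 144 simulated patients, 137 pass eligibility (6 shrank, 1
fell outside the 3–12-month follow-up window) and 91 grew by ≥25% in volume.
Solid nodules double faster than part-solid ones, mass doubling outpaces
volume doubling (density rises as lesions consolidate), and a short VDT
discriminates nodal metastasis (AUC 0.814 at this small n; each day of VDT
multiplies the metastasis odds by 0.991, p < 0.001).  Every intermediate
table (`results.kinetics`, `results.growers`, `results.univariable`,
`results.filter_report`, …) is a pandas DataFrame; `results.plot_roc()`
draws the ROC curves.

The same pipeline is scriptable from the shell:

```sh
nodulegrowth simulate --n 144 --seed 7 --out-dir sim
nodulegrowth analyze --measurements sim/measurements.csv \
    --patients sim/patients.csv --out-dir analysis
nodulegrowth run --simulate --n 144 --seed 7 --out-dir full_run
```

Input schemas (CSV, one header row) are documented in
`src/nodulegrowth/io.py`: a measurement table with one row per CT exam per
nodule, and a patient table with demographics, pathology (AIS/MIA/IA) and
nodal status.

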