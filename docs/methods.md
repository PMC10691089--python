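# Methods

## Growth model and measurement conventions

The package models nodule growth as exponential between two CT
examinations: `V(t) = V0 · 2^(t/VDT)`.  The modified Schwartz formula is
the exact inverse of this model from two measurements, so the estimator and
the generative model agree by construction; no growth-model fitting beyond
the two-point exponential is attempted.  When a series holds more than two
examinations, kinetics default to the first-vs-last pair (the design
targets two-visit follow-up); `compute_kinetics(..., pairing="consecutive")`
yields one result per successive visit pair instead.

Units are fixed throughout: days (integer offsets from the first exam, with
calendar dates converted at the I/O boundary), millimetres, cubic
millimetres, Hounsfield units.  Density is `HU + 1000` in mg/mL — water at
0 HU maps to 1000 mg/mL — and mass is `V·ρ·10⁻⁶` grams (1 mL = 1000 mm³,
mg → g).  A mean attenuation at or below −1000 HU would imply non-positive
density and is rejected as non-physical.

Doubling times are kept at full floating precision internally and rounded
to whole days only for presentation.  Worked-example checks accept ±1 day
because published vignette inputs are themselves rounded.  The
direction-of-time convention is explicit: `V0` is the *initial* and `Vt`
the *follow-up* value, which is the only orientation that produces positive
doubling times for growing lesions.

Growth flags use a relative change of ≥ 25% — inclusively: 25.0% grows,
24.9% does not.  The volume flag gates both whole-nodule doubling times
(VDTt, MDTt); the solid-component flag, on solid-component volume, gates
VDTc/MDTc.  Diameter- and mass-growth flags at the same 25% threshold are
reported separately; the counts of volume growers and mass growers need
not agree and the package exposes both rather than reconciling them.  For
fully solid nodules the solid component *is* the nodule, so component
metrics are defined identical to whole-nodule metrics.  Solid-component
mass uses a separately recorded solid-component attenuation when present
and otherwise falls back to the whole-nodule attenuation.

## Eligibility filtering

Filters operate on tabular records only (image-level exclusions such as
multiplicity or benignity are assumed applied upstream).  Defaults: baseline
whole diameter ≤ 30 mm; follow-up interval strictly inside (90, 365) days —
the strict reading of "3 months to 12 months", configurable because
legitimate vignettes lie outside it; shrinking nodules (any volume decrease
first-to-last) excluded; pathology restricted to AIS/MIA/IA.  Each excluded
record carries exactly one primary reason, evaluated in a fixed precedence:
malformed → diameter → pathology → follow-up window → shrinkage.  The
precedence is a package convention (no external ordering exists); single
reasons keep flowchart-style accounting exact, and the report conserves
records: every input appears once as included or excluded.  T-size
categories partition (0, 30] mm as T1a < 10 ≤ T1b < 20 ≤ T1c ≤ 30, with the
boundary values assigned to the larger class.

## Statistical battery

Standard tests delegate to scipy and statsmodels: Welch t (default for
continuous comparisons), asymptotic tie-corrected Mann-Whitney, and Pearson
chi-square without continuity correction (a correction flag exists for 2×2
tables).  Two identical all-tied samples short-circuit to p = 1 — the
asymptotic rank test's tie-corrected variance is zero there and the only
defensible answer is "no evidence of difference".  Degenerate contingency
tables (an all-zero row or column) raise rather than return a meaningless
statistic.  p-values are presented to three decimals with "<0.001"
flooring; table percentages round one-decimal half-up (the convention of
clinical tables, not banker's rounding).

Logistic regression is a statsmodels `Logit` maximum-likelihood fit; odds
ratios are exponentiated coefficients with Wald 95% intervals.  Complete or
quasi-complete separation is detected by fitted probabilities pinned to 0/1
(or an optimizer failure) and flags the fit unreliable instead of raising
or silently returning; non-convergence likewise.  The multivariable
covariate list is user-specified by preset: `"reported"` mirrors the full
clinical variable list (baseline diameter, solid/volume/mass increases,
VDTt, MDTt — deliberately collinear, as reported in practice) and
`"doubling_time"` is a parsimonious alternative.  No variable selection,
regularisation, or multiplicity correction is applied anywhere.

The ROC machinery is implemented in-package.  The AUC uses the rank
(Mann-Whitney) construction with midrank ties — provably equal to
exhaustive pair counting, which the tests verify by brute force.  The 95%
CI is DeLong's (structural components per observation; the implementation
reproduces an established reference implementation to ten decimals on fixed
inputs, including ties).  The operating threshold maximises Youden's
J = sensitivity + specificity − 1 over observed score values, with ties on
J broken toward higher sensitivity and then the lower threshold; for
doubling times the direction is lower-is-positive ("predict metastasis when
VDT ≤ threshold"), handled by internal score negation so that jointly
flipping score sign and direction leaves every summary invariant (the
threshold maps to its negative).  One-class inputs raise an undefined-AUC
error.  DeLong-plus-Youden is a deliberate default pair — the common choice
when the originating software is unstated — and both are confined to
`roc_analysis` so alternatives can be swapped in.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not any real patient series.  Per patient: texture (part-solid with
probability 25/144), log-normal baseline volume matched to the observed
means/SDs (pSN 1562 ± 2626 mm³, SN 1663 ± 2015 mm³), normal baseline
attenuation (pSN −160 ± 80 HU, SN −45 ± 50 HU — the latter consistent with
the observed solid-nodule mass/volume ratio of ≈956 mg/mL), exponential
volume growth with a true VDT drawn from a two-component log-normal mixture
(growing component medians: SN 300 d, pSN 500 d, log-SD 0.5; indolent
component medians 1800/2500 d with fractions 0.32/0.55), follow-up uniform
on [90, 365] days, and a density drift of +10% per volume doubling so mass
doubles strictly faster than volume.  Diameters are sphere-equivalent,
`d = (6V/π)^(1/3)` — a package invention, needed only because it is
monotone in volume.  The part-solid solid core starts at volume `V0·(C/T)³`
with C/T ~ Beta(3, 2) and doubles 0.9× as slowly as the whole nodule
(slightly faster growth, capped at the whole-nodule volume).

Measurement noise is multiplicative log-normal, CV 5% by default, applied
independently per examination *to the volumetric measurements only*; mean
attenuation is carried over exactly.  This reflects the relative stability
of a three-level attenuation average against slice-wise segmented volume,
and it is what makes the ordering MDT < VDT hold per-nodule rather than
only in the mean.  Nodal metastasis follows a logistic model on baseline
diameter and growth rate — `365/VDT`, chosen over VDT itself so the
covariate is well-defined for non-growing lesions — with large negative
penalties forcing risk to ≈0 for part-solid and non-invasive (AIS/MIA)
lesions, matching the observed absence of nodal disease in those strata;
setting all coefficients to zero recovers an intercept-only prevalence
model.  The mixture fractions and the logistic coefficients (intercept
−6.8, 0.10 per mm, 3.4 per doubling-per-year) were calibrated once so that
cohort-level summaries (grower fraction near 80/144, solid-nodule
metastatic fraction near 23%, discrimination in the 0.80–0.92 AUC band)
land near their clinical anchors, then frozen; they are defaults, not
fitted claims.

What the generator does *not* emulate: inter-reader measurement
variability, nodules appearing or developing new solid components,
attenuation measurement error, correlated noise between whole and solid
volumetry, more than two examinations, competing histologies, or any
survival process.  Passing tests therefore demonstrate that the pipeline
recovers the structure of data generated under its own assumptions — they
say nothing about segmentation quality or cohorts violating exponential
growth.

## Numerical and degenerate-input choices

Validation reports violations as strings instead of raising, so malformed
records become an explicit exclusion category.  Derived fields (density,
mass) are recomputed from raw fields and checked at 1e-9 relative
tolerance.  Doubling-time requests for non-growing pairs raise inside the
primitive but are represented as missing values (empty CSV cells) at the
pipeline level.  The simulation validates its configuration before drawing
any sample, and all randomness flows from one integer seed through a single
`numpy` generator — identical seeds give byte-identical cohorts, and the
pipeline never reads system entropy.

## Known limitations

Two-point kinetics discard intermediate examinations by default; the
eligibility window and 25% rule are conventions, configurable but not
validated here against alternatives; the Wald intervals and asymptotic
p-values inherit their small-sample behaviour from the underlying
libraries; and the logistic "reported" preset is collinear by design, so
its coefficient table should be read as a reproduction of practice, not as
a recommended model.
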