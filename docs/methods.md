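# Methods

## Region grey-matter density

A region's GMD is the probabilistic-mask-weighted mean of a grey-matter map:
`GMD = Σᵥ gm[v]·w[v] / Σᵥ w[v]`, where `gm` is a spatially normalized,
modulated GM volume (fraction or mm³ per voxel) and `w` is the region's
voxelwise probability/weight (for Ch4, a histology-derived basal-forebrain
map).  Dividing by the total mask weight standardizes the value onto the
map's own scale and makes it invariant to rescaling the mask.  The package
consumes already-preprocessed volumes; the VBM chain itself (registration,
segmentation, modulation, smoothing) is out of scope.  Maps and masks must
share the voxel grid: affines are compared elementwise with absolute
tolerance 1e-4 (enough for float serialization noise, nothing more) and any
mismatch raises instead of resampling, because silent interpolation changes
GMD irreproducibly.  Mask voxels outside any brain mask are used as-is.
Whether the supplied GM map is smoothed is the caller's choice; the source
path is carried into the result for provenance.  TIV is computed as the
voxel-volume-weighted sum of GM+WM+CSF fractions (in mL); it exists for
self-contained synthetic runs, and in real analyses TIV normally arrives as
a covariate column from the segmentation tool.

## Regression-based norming

Reference (healthy-control) GMD values are converted to scaled scores by the
affine map `scaled = 10 + 3·(raw − mean_HC)/sd_HC` (sample SD, ddof 1), so
the reference sample has mean 10 and SD 3 exactly.  The conversion is linear
by default — invertible and exactly testable; a rank-based (Blom normal
scores) alternative sits behind `scaling="rank"` for heavy-tailed
references.  Scaled scores are regressed (OLS) on age (years), sex (male =
1), scanner indicators for GE and Philips (Siemens is the reference level)
and TIV (mL).  The model RMSE is the residual SD with denominator
`n − p − 1`, `p = 5` predictors; the choice is recorded in the serialized
model so a denominator-`n` variant is distinguishable.  A subject's
adjusted z is `(scaled_actual − scaled_predicted)/RMSE`, and the low-Ch4
label applies at `z ≤ −1` (boundary inclusive; the threshold is
config-exposed).  Missing covariates raise rather than impute — norming
validity depends on complete covariates — and a rank-deficient design
(e.g. a single scanner type) raises a collinearity error naming the
degenerate columns.  On the reference itself the z-scores average exactly 0
(OLS residuals with an intercept) with SD `√((n−p−1)/(n−1))`.

## Data-driven subtypes

Each subject sits on four burden axes: composite motor (MDS-UPDRS II + III),
SCOPA-AUT, RBDSQ, and cognitive burden `30 − MoCA`.  The cognitive axis is
inverted deliberately: the subtype rules say "above the 75th percentile" for
all three non-motor scores, but a *low* MoCA is the worse outcome, so the
burden transform makes exceedance mean worse cognition (equivalently, MoCA
below its 25th percentile).  Thresholds are the 75th percentiles
(linear-interpolation quantiles, recorded in the threshold metadata) within
disease-duration bins — by default the cohort's duration tertiles, with a
minimum of 20 subjects per bin to keep the percentiles stable; bins are
config-overridable.  Labels use strict inequalities, read literally from the
defining criteria: diffuse malignant iff motor above threshold with at least
one non-motor exceedance, or all three non-motor axes above; mild motor
predominant iff motor and all three non-motor axes strictly below;
intermediate otherwise, so exact ties land in intermediate.  The table path
is vectorized and property-tested against the scalar rule.

## Cognitive milestones and survival

Six milestones are screened at every visit: MoCA < 21, MDS-UPDRS items 1.1,
1.2, 1.5 at response ≥ 3, clinician-diagnosed dementia, and a composite
dementia categorization.  The per-domain composite dementia thresholds are
not operationalized here; that milestone is consumed as a precomputed
boolean column.  The event time is the first visit month at which any
criterion holds — a single qualifying visit suffices (no persistence
requirement) — and subjects never qualifying are censored at their last
visit.  A milestone already present at baseline gives time 0, is kept, and
is flagged rather than dropped.  Kaplan-Meier estimation, the log-rank test
and the Cox model come from lifelines; Cox tie handling is Efron by default
(ties are guaranteed by the 6-month visit grid), with Breslow available via
statsmodels' PHReg.  The MoCA adjustment covariate is baseline MoCA.  Wald
95% intervals; two-sided p-values at α = 0.05.

## Group statistics

Continuous variables: median and 25th/75th percentiles
(linear-interpolation), compared with the tie-corrected Kruskal-Wallis test
(used even for two groups so every continuous contrast shares one method).
Categorical variables: items binarized at score ≥ 1, compared with the
Pearson chi-square **without** continuity correction and without a Fisher
fallback at small counts — the package's tables are built on the
uncorrected statistic, which is the only variant that reproduces the
published borderline p-values from 0-vs-1 cells; Fisher's exact is an
explicit alternative, and no multiplicity correction is applied (also
deliberate, available behind the caller's own adjustment).  Power for a
two-sided two-sample t-test uses the exact noncentral-t tails at
noncentrality `d/√(1/n₁+1/n₂)` with `df = n₁+n₂−2`.

## Synthetic cohort generator

The generator emulates the study conditions the analyses were designed for:
171 healthy controls (age truncated-normal, mean 60.6, SD 11.6, minimum 30
per the study entry criterion; 61.4% male; scanner mix 0.6/0.2/0.2
Siemens/GE/Philips — the source gives no site mix, so a Siemens-weighted
mix typical of multicenter MRI was fixed once; TIV normal 1450 ± 130 mL)
and 148 PD-MCI patients of whom round(32/148·n) form a latent low-Ch4
subgroup.  Control GMD follows
`0.55 − 0.0015·age − 0.005·sex − 0.010·GE − 0.008·Philips + 2e−5·TIV + ε`,
`ε ~ N(0, 0.03)` — coefficients chosen so GMD sits in a plausible
grey-matter-fraction range (~0.45–0.50) with mild age decline and scanner
offsets smaller than the residual SD.  `residual_sd = 0` is allowed as the
noise-free limit used by exactness tests.  The latent low group's GMD is
shifted by −0.075 (−2.5 residual SDs), which puts ~90% of them past the
z ≤ −1 cutoff while the normal group contributes the expected ~16%
false-positive tail — classification noise the downstream contrasts see, as
they would on real data.  Clinical scores are rounded, range-clipped
normals loosely matched to the published PD-MCI medians (MoCA clipped to
the 21–26 inclusion window), with additive burden shifts for the latent low
group; part-1 items are Bernoulli-present (probabilities per group matched
to the published symptom frequencies) with severity 1–2 at baseline.

Milestone times are exponential with hazard
`0.0144·exp(0.668·low + 0.02·(age−65) + 0.10·sex − 0.10·(MoCA−24))` per
month: baseline rate set for a ~48-month median, and the low-group log
hazard ratio `ln 1.95` as an emulation default, not a reproduction claim.
Events are interval-detected at the first 6-month visit after the latent
time, under random censoring (rate 0.005/month) and administrative
censoring at 60 months; the visit table plants a qualifying score at the
event visit and unremarkable scores before it, so milestone detection on
the visits reproduces the cohort's observed times exactly (the continuous
latent times stay in the truth object, which no analysis stage reads).

What the generator does **not** emulate: real anatomy or scanner artifacts,
longitudinal drift in clinical scores before the milestone, correlated
missingness, non-proportional hazards, or subtype-dependent progression.
Passing tests therefore demonstrate that the analysis chain is correct and
calibrated under its own model assumptions, not that those assumptions hold
in PPMI.

## Problem sizes and numerical choices

Calibration experiments use sizes at which the estimators' asymptotics are
informative but runs stay cheap: OLS recovery at n = 5000 (each coefficient
within 3 SE), null classification rate at n = 20000 against Φ(−1) — with
the reference model also fitted on a large sample, since a reference of
171 leaves intercept noise that dominates a ±1% band on the tail rate —
and Cox recovery at n = 2000 over 500 replicates (mean log-HR within 0.05,
CI coverage 93–97%), fit on the interval-detected grid times, whose
discretization attenuates the estimate by well under the band.  Tiny-instance
oracles pin the statistics themselves: loop-based weighted means to 1e-10,
observed-minus-expected log-rank tabulation, grid-search partial-likelihood
maximization to 1e-3, and full permutation enumeration for Kruskal-Wallis
(where the chi-square p is only compared loosely near the null, the
approximation's known weak spot).  All randomness flows through
`numpy.random.default_rng` seeded from the config, and reruns with one seed
are byte-identical.
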