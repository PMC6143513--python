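# Methods

This note records the models, conventions and numerical choices behind
`cytonet`, and what the synthetic-data generator does and does not emulate.

## Cohort model and simulator

The simulator produces the data structure the analysis assumes: a sepsis arm
of `n_patients` (default 31) sampled on days 1, 2, 4, 6, 8, 11, 15 (at most
7 samples each; the day-1 sample is always present, taken within 24 h of
diagnosis) and `n_controls` healthy controls (default 13) sampled once.

**Latent severity.** One scalar latent severity s per patient-day follows a
stationary AR(1) process with coefficient 0.8 and standard-normal marginals.
This single hidden variable is the minimal structure that makes the three
downstream findings reproducible in kind: it elevates the planted mediator
cluster, generates the integer severity scores, and drives the death hazard.
Nothing mechanistic is claimed for it.

**Mediators.** Concentrations are log-normal. For a planted-cluster member
the standardised log10 value is √ρ·s + √(1−ρ)·ε, so any two members
correlate at exactly ρ (default 0.7) on the log10 scale and each member
correlates √ρ with severity; non-members are independent noise. Location
parameters (log10 means for controls and sepsis, SD 0.45 throughout) are
stated defaults chosen for clinical plausibility — e.g. control IL-6 around
5 pg/mL versus septic 200 pg/mL, control PAI-1 10 ng/mL versus septic
80 ng/mL — and are **not** fitted to any real cohort. Cluster members are
strongly elevated (log2 fold change ≫ 1.5), IL-1β moderately (≈1.8, so its
network membership fluctuates at n = 31, as small cohorts behave), the
remaining six mediators only marginally (≪ 1.5).

**Detection limits.** Cytokine draws are clipped to the assay range
9.77–3000 pg/mL and flagged below/above-limit; PAI-1 (ELISA, ng/mL) has only
the lower limit 0.014 ng/mL. Flagged values enter analysis at the limit
value (clipping): the flags are carried through I/O but not modelled
statistically. Censored-likelihood treatment of non-detects is a known
limitation, accepted because the downstream analyses are rank- or
correlation-based and the planted cluster sits well inside the range.

**Severity scores.** SOFA = clip(round(9 + 3.5·s + N(0,1)), 0, 24);
JAAM = clip(round(3 + 1.5·s + N(0,0.7)), 0, 8);
ISTH = clip(round(2 + 1.5·s + N(0,0.7)), 0, 8). The loadings are per-score
config parameters; offsets and noise SDs are fixed. With these defaults
roughly a quarter of patients are critical (SOFA ≥ 12) on day 1.

**Survival and attrition.** Death time is exponential with rate
0.01·exp(0.8·s₁) per day (s₁ = day-1 latent severity), giving ≈30% 28-day
mortality; survivors are censored at day 28. After every completed visit
there is an independent 0.15 probability of ICU discharge, which truncates
later visits but not outcome ascertainment. Competing risks are deliberately
not modelled. Each randomness source (latent process, each mediator's noise,
severity noise, survival, discharge) draws from its own named child stream
of the single seed, so adding a mediator never perturbs the survival draws.

**What the simulator does not emulate.** Real cytokine pharmacodynamics
(secretion bursts, half-lives), treatment effects, inter-assay drift,
informative missingness beyond death/discharge, and any data-dependent
numbers of a real cohort (medians, observed AUCs). Passing recovery tests
therefore shows the *pipeline* detects structure it is designed to detect —
not that any particular clinical dataset contains that structure.

## Preprocessing

All mediator analyses operate on common logarithms; raw-scale values are
retained only for fold changes, which are defined on raw-scale arithmetic
means. Missing cells are never imputed: correlation work is pairwise-
complete, scoring/Cox/ROC work is listwise per analysis day. PAI-1 is kept
in ng/mL; correlation, rank and quantile-indicator analyses are invariant to
the unit choice, so no conversion to pg/mL is performed.

## Group comparisons

Dunnett's many-to-one test with equal variances: the pooled SD across all
compared groups (including controls), two-sided adjusted p-values from the
multivariate-t distribution of max|t| (quasi-Monte-Carlo evaluated with a
fixed stream for run-to-run reproducibility; the adjusted p is floored at
the unadjusted pooled-t p to keep the family inequality exact under QMC
error). The critical/non-critical/control comparison uses the three-group
pooled variance in a single family. Groups that are entirely at a detection
limit have zero variance; they are compared with the pooled variance and a
warning is attached. α = 0.05 two-sided throughout.

## Correlation network and clustering

Pearson correlations with two-sided t-distribution p-values, pairwise-
complete; pairs with n < 3 or a zero-variance marker are reported
unavailable with a reason. Ward clustering runs on d = 1 − r (not 1 − |r|:
the clusters of interest group *positively* co-varying mediators; the
distance is configurable). The linkage is the Ward.D2-style squared-update
Lance–Williams recurrence; merge ties resolve by panel order, making output
independent of subject order. The flat-cluster cut height defaults to 0.9,
calibrated once in simulation: within-cluster merges complete below ≈0.5
and unrelated markers first attach above ≈1.0, so 0.9 lies mid-plateau.
Network nodes require log2 fold change strictly > 1.5, computed against the
once-sampled controls (hence day-independent control means); edges are
unadjusted p < 0.05 correlations between included nodes — no multiplicity
correction is applied to edges, stated as a design choice. Node classes
(sepsis-significant / critical-only-significant / neither) mirror the
red/yellow/grey colouring convention.

## Combined scores and severity associations

Quantiles use linear interpolation between order statistics (the common
default of mainstream statistics environments), recorded in output metadata
because the boundary rule — a value exactly at the 75th percentile scores
1 — makes the definition consequential. Cut points are computed per
analysis day among the subjects measured that day. Spearman ρ is
tie-corrected; band boundaries (0.8, 0.5, 0.3, 0.1) fall to the lower band,
classification uses |ρ| with the sign reported separately.

## Time-dependent Cox model

The acute-phase covariate is the running maximum over update days 1, 2, 4
(missing intermediate days carry the previous maximum forward; subjects
without a day-1 value are excluded and reported). For combined-score
covariates the 75th-percentile cut points are recomputed on each update
day's running-max distribution. Counting-process intervals are (0,2],
(2,4], (4, min(T,28)], each carrying the covariate of its opening update.
Ties are certain with integer event days, so the Efron approximation is
used. Hazard ratios are scaled Q1→Q3 with quartiles from the final
(day-4) running-max distribution across subjects — configurable, since the
quartile-source convention is genuinely open. Adjusted models add baseline
(day-1) severity one adjuster at a time; time-updated adjustment is not
implemented beyond the config switch point. Monotone-likelihood separation
triggers a flagged ridge-penalised (0.1) refit.

## Penalized ROC

Ridge logistic regression maximises loglik − (λ/2)‖β_slopes‖² on internally
standardised features with an unpenalised intercept (Newton trust-region
from the zero vector; deterministic). λ is selected by corrected AIC over a
log-spaced grid 10⁻²…10³ with effective degrees of freedom
tr[(X′WX + λP)⁻¹X′WX]. AUC is the Mann–Whitney estimator with half credit
for ties, reported in-sample (no cross-validation — a stated limitation
matching the small-cohort workflow this mirrors). The paired comparison of
correlated ROC curves is DeLong's z-test on structural components; a
stratified-bootstrap alternative is available behind a flag since the
choice of paired test is genuinely open.

## Problem sizes used in the shipped checks

The test-suite recovery checks use 100 simulated cohorts at n = 200 for
cluster/network/association recovery and 100 cohorts at n = 500 for the
Cox planted-effect detection; null calibrations use 2000 simulated Dunnett
families and 200 Cox null replicates at n = 1000. These sizes give binomial
standard errors comfortably inside the asserted bands while keeping the
default test run quick.

## Known limitations

- Detection-limited values are clipped, not treated as censored likelihood
  contributions.
- In-sample AUC overstates discrimination; no optimism correction.
- The Dunnett adjusted p carries ~10⁻⁴ quasi-Monte-Carlo error.
- Fold changes use day-specific sepsis means against once-sampled control
  means; with per-day control sampling the convention would need revisiting.
- The simulator's single latent severity cannot generate mediators that
  decouple from severity while remaining mutually correlated.
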