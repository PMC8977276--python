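# Methods

This note records the statistical conventions, default parameters and
design choices behind `prognosig`, and what the synthetic-cohort tests
do and do not demonstrate about real data.

## Survival model and endpoint

All analyses treat overall survival — time in months to death from any
cause — as the endpoint, with right-censoring for patients alive at
last follow-up. Survival times must be strictly positive; the event
indicator is strictly binary. Median follow-up is reported by the
reverse Kaplan–Meier method (censoring treated as the event), which is
undefined when too few patients are censored for the flipped curve to
reach 0.5 — mirroring the usual rule that a Kaplan–Meier median cannot
be calculated while the curve stays above 0.5.

## Cox fitting

`cox_fit` maximises the partial likelihood by Newton–Raphson with
analytic gradient and Hessian, step-halving whenever a full step would
decrease the likelihood, convergence when the largest coefficient
update is below 1e-9, and a cap of 100 iterations (non-convergence is
flagged with a warning rather than raised, except inside the search,
where an unconverged candidate is treated as unfit and skipped).

* **Ties**: the Breslow approximation is the default — the convention
  of the major commercial survival packages and therefore the one that
  reproduces published coefficient tables computed with them; Efron is
  available via `ties="efron"`. Both agree with statsmodels `PHReg` to
  ≤1e-6 in the test suite.
* **Inference**: Wald statistics ((β/se)², 1 df) and log-scale 95%
  confidence limits for hazard ratios, matching how multivariate
  prognostic-factor tables are conventionally printed. The full
  covariance matrix is retained so joint (multi-df) Wald tests on group
  dummies can be formed.
* **Degeneracy**: constant columns and exactly collinear designs raise
  a `DegenerateDesignError` before any iteration.

Kaplan–Meier curves, the k-sample log-rank test and Harrell's
concordance index are delegated to lifelines; Greenwood variances are
computed from the event table, and the median confidence interval uses
the log-log (exponential Greenwood) band construction. Harrell's c
counts tied risk scores in comparable pairs as 1/2, and a death is
ordered before a censoring recorded at the same time.

## Screening

The optimal cut-off for a marker is found by exhaustive scan: every
distinct observed score value is tried as a `high = score ≥ value`
threshold, thresholds leaving either group below `min_group_fraction`
(default 0.1) of the marker's analyzable patients are inadmissible, and
the admissible threshold with the smallest log-rank p wins (ties to the
smaller value). Each marker is screened complete-case on its own
non-missing patients. Retention requires p ≤ α (default 0.05) with
**no multiplicity correction by default**: the scan is intentionally
liberal at this stage, because downstream subset assembly and
combinatorial search provide the real selection pressure. The cost is
optimism — scanning cutpoints inflates the per-marker type-I error
well above α — which the test suite measures on pure-noise cohorts
rather than hides. A Benjamini–Hochberg option (`fdr=True`) exists for
users who want a conservative screen.

Direction of association is read off the hazard ratio of the
high-score group at the optimal cut-off (HR < 1 → higher expression is
protective). Correlation subsets use Spearman correlation (scores are
ordinal) on pairwise-complete observations, average linkage on
1 − |ρ|, and a dissimilarity cut at 0.5 by default; singleton clusters
are dropped. Biological subsets are annotation-driven (a marker may
carry several pathway tags and then appears in several subsets);
subsets with identical member sets are deduplicated.

## Combinatorial search

Candidate combinations are enumerated lazily in lexicographic order;
counts come from the binomial coefficient C(n, r). Per candidate, the
composite weights are the multivariate Cox coefficients of exactly the
combination's markers (no clinical covariates at this step), and the
fitness model is a second Cox fit on the composite plus the configured
clinical covariates.

* The composite is **standardized** (zero mean, unit SD over the
  analyzable patients) before the fitness fit, so the hazard-ratio
  metric is per SD and invariant to arbitrary score scaling; the raw
  scale (`standardize=False`) is retained for reproducing published
  per-score-unit equations.
* Fitness metrics and orientation: `hr` (compared by |log HR|),
  `coefficient` (|β|), `p_value` (lower better), `concordance` (higher
  better). One metric per run; the full fitness-model summary is kept
  on every score for inspection, so the other metrics are recoverable.
* Tie-breaking: candidates are visited in increasing size then
  lexicographic order, and a strictly larger fitness key is required to
  displace the incumbent — so ties resolve to fewer markers, then
  lexicographically, and results are deterministic.
* Gradient mode starts from the full subset and evaluates all
  size-(m−1) eliminations per iteration, moving only on strict
  improvement; this guarantees termination within n − r_min iterations
  and can be dominated by global mode, never the reverse (asserted in
  the tests).
* Missing scores: `complete_case` per candidate fit (default) or
  `impute_mode` (per-marker modal score). Candidates whose fit is
  degenerate or does not converge are skipped and counted in the trace.
* The exhaustive cap is 20 markers (≈10⁶ combinations); larger subsets
  must use gradient mode.

## Risk groups and independence

Percentile groups cut the composite at the 1/k … (k−1)/k quantiles
(linear interpolation between order statistics, right-closed
intervals, identical to the quartile-binning convention used for
recoding expression data); k defaults to 5, the value that produces
four cut-off points of equal percentiles. Because the composite is a
Cox linear predictor, higher score means higher hazard, so labels 1..k
are ordered by increasing risk. Cluster groups use Ward linkage on
Euclidean distances between per-marker standardized scores — compact,
deterministic, and the standard choice for expression-profile
dendrograms — relabeled 1..k by increasing mean composite risk (which
groups the tree by outcome rather than raw staining intensity, a
deliberate choice where either ordering would be defensible).

Independence testing fits Cox on first-level-reference dummy-coded
group labels plus an encoded clinical model. Four named models are
built in: age + T + N + EMVI; age + UICC + EMVI; age + pathological
risk (derived on the fly from T/grade/EMVI/N when absent: low iff
T1–T3 and G1/G2 and V0 and N0); and age + site + differentiation.
Categorical covariates are dummy-coded by default (ordinal trend
encoding available), levels validated against a declared vocabulary.
The reference group's HR is 1 by construction and never estimated; the
joint group effect is a (k−1)-df Wald test using the fitted covariance.

## Synthetic cohorts

The generator emulates a colorectal-cancer discovery cohort: ordinal
scores 0–15 (configurable, uniform marginals by default, arbitrary
level probabilities supported), drawn through a Gaussian copula so
block correlations are imposed on the latent scale and marginals stay
exact; exponential survival with hazard `baseline · exp(lp − mean lp)`
where lp is the planted weighted score sum plus optional ordinal
covariate effects; and censoring as the minimum of an administrative
cutoff and exponential dropout. Defaults — baseline 0.007/month
(median ≈ 99 months), cutoff 120 months, dropout 0.002/month — yield
roughly half the patients with an observed event, the regime typical
of long-follow-up surgical cohorts. The default planted signature is
three markers with weights (−0.15, −0.16, +0.14) among five noise
markers.

What the simulations do **not** emulate: the joint distribution of
real clinicopathological covariates (and their correlation with marker
expression), non-proportional hazards, informative censoring,
batch/staining artefacts, and skewed real-world score distributions.
Passing the planted-recovery and calibration tests therefore shows the
machinery is correct and well-calibrated under proportional hazards
with independent censoring — not that any particular signature will
validate clinically.

## Problem sizes and numerical checks

The test suite sizes its simulations for a desk-scale run: calibration
of the weight-estimator CIs uses 200 cohorts of n = 1000 (coverage
band 93–97% on the rate pooled over the three planted weights, whose
Monte Carlo standard error ≈0.85% is small against the band);
planted-signature recovery uses 50 cohorts of n = 400 with 8 markers
(winner must contain the planted trio in ≥80% of seeds); exhaustive
search is checked against an independent brute-force enumeration of
all 2⁷ − 1 combinations under every fitness metric; and the Cox /
log-rank core is compared with statsmodels and scikit-survival on 20
random small cohorts at 1e-6 / 1e-8.

## Known limitations

* No time-varying covariates, frailty terms or competing risks.
* The optimal-cutpoint screen is optimistic by construction; its
  retained set should be read as a candidate pool, not as a list of
  validated prognostic markers.
* Cluster-based grouping cannot label new patients (no centroid
  model); refit or use percentile groups for deployment.
* Only the two search modes described (exhaustive and one-marker
  backward elimination) are provided; no metaheuristics.
* Expression tables are consumed as local files; probe-to-gene mapping
  and remote retrieval are out of scope.
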