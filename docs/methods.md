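# Methods

This note documents the statistical model, the numerical choices, and the
design of the synthetic cohort generator, including what passing tests do
and do not demonstrate about real data.

## Survival model and estimand

For one gene with expression x and a cutoff c, the covariate is
z = 1{x > c}. The Cox proportional-hazards model h(t | z) = h0(t) exp(βz)
is fitted by maximizing the partial likelihood for this single binary
covariate. The reported quantities are:

- **β / HR = exp(β)** — maximizer of the partial likelihood with the Efron
  tie correction (Breslow available via `ties="breslow"`). Newton–Raphson
  from β = 0 with step-halving, convergence at |Δβ| < 1e-8, at most 50
  iterations. The negative curvature has the stable form Σ a(1−a) with
  a ∈ [0, 1], so iterations are well-conditioned away from monotone
  likelihood.
- **SE(β)** — inverse square root of the observed information at β̂.
- **p-value** — score test at β = 0, which for a binary covariate is the
  classical log-rank test; implemented with the hypergeometric variance
  Σ d(n−d)/(n−1) · π(1−π) over distinct event times (risk sets of size one
  contribute zero). A Wald test is available via `test="wald"`. The choice
  of the score test as default makes the per-cutoff p computable in closed
  form during the scan, and it agrees with `lifelines.statistics.
  logrank_test` to floating precision (verified in the tests).
- **95% CI** — exp(β̂ ± 1.96·SE).

**Non-estimable fits.** When all events fall in one arm the partial
likelihood is monotone in β; such fits (and Newton runs that leave
|β| > 50, the same pathology approached gradually) are flagged
non-estimable, excluded from cutoff selection and from the FDR vector, and
reported separately.

## The best-cutoff scan

Candidate cutoffs are the distinct observed expression values c with
Q1 ≤ c < Q3 (quartiles by linear interpolation between order statistics).
Observed values are the only points where group membership changes, so
this grid is exhaustive; the half-open interval resolves the unstated
boundary convention. "High" is strictly greater than the cutoff. Both arms
therefore always hold at least ⌈n/4⌉ − 1 samples.

Selection: smallest score-test p; exact floating-point p ties are broken
by the largest absolute HR max(HR, 1/HR), remaining ties by the smallest
cutoff. The per-cutoff score statistics are computed vectorized across the
whole candidate grid (suffix sums of the group indicator matrix over the
time-sorted samples), with a reduction order arranged to be independent of
the grid width so that a single-cutoff re-evaluation reproduces the grid
values bitwise — the scan is exactly equivalent to exhaustive
re-evaluation, and is tested against an independent brute-force oracle.

Genes with fewer than two distinct interquartile values, or no estimable
candidate fit, are reported as unscannable.

**Minimum-p inflation.** The best p per gene is the minimum over ~n/2
correlated tests, so it is anti-conservative, and the BH correction across
genes inherits this optimism. This matches the published screening
procedure and is intentionally left uncorrected. The tests therefore
distinguish two properties: the *base* test is calibrated (under the
global null, a fixed median split rejects at 5%), while the scanned
minimum-p is only checked for oracle equivalence, never for calibration.

## FDR and the filter cascade

Benjamini–Hochberg q-values (step-up, `statsmodels` implementation) are
computed per cohort analysis over the best p-values of all scanned
gene-mapped probes — unmapped probes are excluded *before* the correction,
and the FDR filter precedes the expression filters. The cascade is: gene
mapped → q ≤ 0.05 → max expression strictly over 1000 (the
post-normalization mean intensity, i.e. robust expression in at least one
sample) → best cutoff strictly over 100 (above background noise) → the
designated best probe per gene. The best-probe stage is an identity
filter: the flagged probe is kept even when a sibling probe of the same
gene shows a stronger HR. Survivors are ranked by absolute HR descending
(ties: ascending p, then probe id, for determinism). Overlap percentages
between gene lists are rounded half-up to one decimal to match report
formatting.

## Preprocessing

- **Scaling normalization** multiplies each array by
  `target_mean / mean(reference probes)`; with the default reference (all
  probes) and target 1000. Idempotent; removes any per-array multiplicative
  factor exactly, which is precisely the batch effect it models. It does
  not address additive or non-linear batch effects.
- **QC**: the "central 95% range" is the closed interval between the 2.5th
  and 97.5th percentiles (linear interpolation) computed over all arrays
  including the one under test; values must also be strictly positive. The
  spike flag fails when absent. One failure → outlier (retained, flagged);
  two or more → biased (excluded).
- **Redundancy removal** compares expression vectors after rounding to six
  significant digits (guarding against serialization noise) and keeps the
  copy from the dataset with the smallest publication order, ties broken
  by sample id. Preferably applied to pre-normalization values; exact
  duplicates remain exact under scaling, so the order relative to
  normalization does not affect the result.

## Receptor calls and cohorts

ER status: `205225_at` (ESR1) with cutoff 500; ERBB2: `216836_s_at` with
cutoff 4800, both on post-normalization intensities. *Positive* means
strictly above the cutoff; a value exactly at the cutoff is negative (the
boundary convention is configurable). Progesterone receptor is not
assessed. Treatment rules act only on documented systemic therapy;
`unknown` never satisfies a rule, and samples without relapse-free
survival follow-up are always dropped. Radiation therapy is ignored.

## Synthetic cohort generator

The generator emulates a pooled multi-series microarray database. Defaults
define the reference recovery experiment: 2 datasets × 200 samples, 1000
probes, 20 planted prognostic genes at |log HR| = log 2.5, exponential
baseline with 60-month median relapse-free survival (a plausible figure
for breast-cancer RFS cohorts whose pooled follow-up averages ~5–6 years),
30% censoring, batch scales uniform on (0.7, 1.4), 75% ER-positive / 17%
ERBB2-positive, half the samples with documented treatment and a quarter
documented untreated; five duplicate arrays, five outlier and three biased
arrays in the default cohort.

- **Expression**: per-probe log-normal intensities (log-median ~
  N(log 400, 1), within-probe σ = 0.6), then a per-dataset multiplicative
  batch scale. This imitates MAS5-like skewed non-negative data; it does
  not reproduce MAS5's exact distributional form, probe-level effects, or
  intensity-dependent variance.
- **Planted effects** form a single shared prognostic program: a latent
  binary risk factor (prevalence 1 − effect_quantile, default one half)
  multiplies the hazard by exp(|log HR|), and each planted gene expresses
  the program up- or down-regulated (sign random) with a log-scale shift
  of ±2.2, giving ~2% discordance between the gene's own median
  dichotomization and the risk factor. A shared program keeps each gene's
  *marginal* dichotomized hazard ratio equal to the planted value, which
  makes parameter recovery well-defined; independent per-gene hazards
  would attenuate every marginal estimate through the frailty induced by
  the other planted genes (hazard-ratio non-collapsibility). It also
  mirrors real prognostic signatures, which are strongly co-expressed
  gene programs. Planted probes draw their baseline from the robustly
  expressed range (log-median ~ N(log 1200, 0.3)): the filter cascade is
  designed to retain exactly such genes, and weakly expressed planted
  effects would be removed by construction, testing nothing.
- **Survival**: Weibull proportional hazards (shape 1 = exponential by
  default) with the rate set so the baseline median equals the configured
  value. Censoring is independent Uniform(0, c), with c calibrated by
  Brent root finding on the closed-form expected censored fraction
  (Gauss–Legendre for non-unit shapes); a target of 0 disables censoring.
- **Markers**: ER/ERBB2 probe intensities are strongly bimodal (ER+
  median 4000 vs ER− 80; ERBB2+ 20000 vs ERBB2− 1000) so the planted
  receptor status is recoverable through the fixed 500/4800 cutoffs after
  rescaling.
- **QC metrics** are drawn from a coarse seven-point grid around typical
  operating values, with designated failures placed 25 grid steps outside.
  The discreteness is deliberate: every grid atom holds far more than 2.5%
  of arrays, so no clean array falls strictly outside the empirical
  central 95% band and recovery of planted failures is exact. Real QC
  metrics are continuous, and the 95%-range rule then flags roughly 5% of
  clean arrays per metric — as the large outlier counts of real pooled
  databases show. Exact-recovery tests demonstrate correctness of the
  classification logic, not the false-positive behaviour expected on real
  data.
- **Duplicates** are bitwise column copies assigned to the last dataset;
  one RNG stream per generation stage (spawned from the master seed) keeps
  every stage's draws stable when another stage's configuration changes.

## Problem sizes used in validation

The recovery experiment runs 25 replicate cohorts of n = 400 with 1000
probes; the null-calibration check uses one 200-sample, 1000-probe cohort;
Cox oracle equivalence uses 100 random 8–20-subject datasets and scan
oracle equivalence 50 random genes. These sizes give Monte-Carlo error
comfortably inside the asserted bounds while keeping the default test run
fast.

## Known limitations

- Only multiplicative batch effects are modelled and removed; real
  cross-platform effects are richer.
- The generator's clinical table has complete follow-up; real cohorts have
  missing survival and treatment fields in dataset-specific patterns, and
  per-dataset follow-up distributions are not matched.
- Single-covariate models only: no covariate adjustment, time-dependent
  effects, or proportional-hazards diagnostics.
- The minimum-p selection bias is reproduced, not corrected; reported
  per-gene p-values and q-values are optimistic by design.
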