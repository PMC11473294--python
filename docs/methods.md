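# Methods

`ineqdecomp` measures and decomposes socioeconomic inequality in binary
health-service outcomes from pooled cross-sectional survey cohorts of
middle-aged and older adults with disabilities. This note records the
statistical model, the defaults and the design choices behind them, and
what the synthetic cohorts do and do not establish.

## The inequality model

Let `h_i ∈ {0,1}` indicate use of a service (outpatient care in the last
month, inpatient care in the last year, or self-treatment in the last
month) and let `x_i > 0` be annual per-capita household expenditure, the
living-standard variable. The **fractional rank** `r_i` is the cumulative
population share at the midpoint of record *i*'s rank block after sorting
by expenditure: `r_i = (W_<i + w_i/2) / W`, with tied expenditures sharing
their block's midpoint rank and `W` the total weight (weights default to
1). The weighted mean of `r` is exactly 1/2.

The **concentration index** is

    C = 2 cov(h, r) / μ,        μ = mean(h),

using the population (divide-by-`W`) covariance. `C ∈ [−1, 1]`; for a
binary outcome the attainable range is tighter, `|C| ≤ 1 − μ + 1/n`,
which the implementation asserts. Positive `C` means utilization is
concentrated among the better-off. The **concentration curve** plots the
cumulative share of `h` against the cumulative population share in rank
order; twice the signed area between the diagonal and the curve
approximates `C` to `O(1/n)`.

**Standard errors** come from the convenient-regression device: the OLS
slope of `2 σ_r² h_i / μ` on `r_i` equals `C` algebraically (with matching
population variance conventions), and its heteroskedasticity-robust HC1
standard error is reported. Significance stars use 0.05/0.01/0.001. This
SE ignores the sampling variation of the ranks and of `μ`; simulation
under a null data-generating process (below) shows rejection rates close
to nominal (≈0.04–0.06 at α=0.05, n=3,000), which we consider adequate
for descriptive inequality reporting.

**Decomposition.** A probit model `P(h=1|x) = Φ(x'β)` over the need and
non-need covariates yields average marginal effects
`AME_j = mean(φ(x'β̂)) β̂_j` (the calculus form; a discrete-change variant
that switches each factor from its reference level is available via
`marginal_mode="discrete"`). Each design column contributes

    contribution_j = AME_j · x̄_j / μ · c_j,

where `c_j` is the concentration index of the column itself over `r`. The
residual `GC_ε/μ = C − Σ_j contribution_j` absorbs whatever the linear
index and the linearization leave unexplained; it is always reported.
Contribution rates are `100 · contribution_j / C`. Multi-level factors
are reported per dummy and aggregated per factor (the expenditure-quintile
block in particular is read as one "household expenditure" contribution).

The **horizontal inequity index** subtracts the legitimate, need-driven
part: `HI = C − Σ_{j∈need} contribution_j`. Need variables default to
gender, age band (45–59 / 60–74 / ≥75), self-rated health, chronic
disease, ADL and IADL limitation; non-need variables to expenditure
quintile, smoking, drinking, marital status, education (4 ordered
levels), social activity, child financial support, region (western /
central / eastern) and basic medical insurance. Both sets are overridable
through `VariableSpec` lists.

Because contributions and the residual are defined on the same
complete-case sample as the probit fit, the adding-up identity
`Σ contributions + residual = C` and `HI = C − need terms` hold to
floating-point error on every fit; the test suite asserts ≤1e-10.

## Cohort preparation

* **Inclusion**: age ≥ 45 and a known disability type. Records reporting
  two or more of the five disability problems (physical, intellectual,
  vision, hearing, speech) are labelled *multiple*; the six types are
  mutually exclusive.
* **Trimming**: expenditure outliers are removed at both tails. The
  default trims 2% in total (1% per tail), read as cut points at the
  1st/99th within-wave empirical quantiles (inclusive linear
  interpolation); records strictly outside the open interval are dropped,
  so an all-tied sample loses nothing. Whether a published "2 per cent"
  threshold means 2% total or per tail is genuinely ambiguous; 2% total
  is the default and the fraction is a parameter. Note that two-sided
  quantile trimming is not idempotent on continuous data — re-trimming a
  trimmed sample removes a further ~2% because the new cuts lie inside
  the retained range; pipelines therefore trim exactly once and record
  the stage counts in the manifest.
* **Quintiles**: expenditure quintiles are cut at the within-wave
  20/40/60/80th percentiles so that secular price drift does not move
  records across quintiles; ties at a cut point go to the lower quintile.
  Fewer than five distinct values trigger a degenerate-quintile warning.
* Records with missing expenditure stay in descriptive tables but are
  excluded from ranking, quintiles, and all index/decomposition work;
  per-table denominators therefore differ, as in the survey tables this
  layout mirrors.

Ranks are always computed on the continuous trimmed expenditure, never on
the quintile labels; the quintiles exist only as regression covariates.
For pooled multi-wave samples both pooled ranks (default) and within-wave
ranks (`rank_scope="within_wave"`) are implemented, since either reading
is defensible for a pooled index.

## Regressions

Reporting models are pooled cross-sectional logits with wave dummies
first (reference 2011): odds ratios with Wald 95% intervals on the link
scale, McFadden pseudo-R² (labelled as such), complete-case estimation
with `n_used` logged. The decomposition uses the probit link. Both links
are maximum likelihood via `statsmodels`; non-convergence, perfect
separation and rank deficiency raise typed errors (rank deficiency names
the collinear columns; dummy levels unobserved in the estimation sample
are dropped rather than reported as collinear). No survey weights,
clustering or imputation — the estimand is the equal-weight descriptive
association.

The binary-outcome concentration index is reported unnormalized by
default; Wagstaff (`C/(1−μ)`) and Erreygers (`4μC`) normalizations are
available behind a flag for sensitivity analysis.

## The synthetic data-generating process

`DGPConfig` emulates a four-wave ageing-survey cohort: default per-wave
sizes 3,088 / 2,388 / 2,634 / 2,425 (pre-trim); covariate marginals set
to realistic first-wave frequencies (e.g. 52% male, 79% chronic disease,
six disability types with hearing most common); log-normal expenditure
(log-mean 9.0 ≈ 8,100 currency units/year, log-sd 0.85); 2% of records
replaced by extreme draws (×10 upper tail, ×0.1 lower tail) so the
trimming stage has real work; item-level missingness MCAR at 2% per
variable so per-table denominators differ. Outcomes are Bernoulli draws
from a probit index over wave, need and non-need dummies whose
expenditure-quintile block has a monotone pro-rich gradient (probit
coefficients 0.23–0.85 for inpatient, weaker for outpatient and
self-treatment); constants are calibrated so pooled prevalences land near
outpatient 0.24, inpatient 0.20, self-treatment 0.62. Fixing the seed
fixes the cohort bit for bit.

Because coefficients are known, the generator supports three kinds of
ground-truth checks: `oracle_ci` runs the full estimation pipeline on a
~10⁶-record sample to give a pseudo-true index for recovery tests;
`with_zero_gradient()` gives an exact null for size calibration; and
`expected_prevalence` recomputes mean Φ(x'β) without the Bernoulli step.

What the generator does **not** emulate: survey weights, household
clustering, panel attrition (waves are independent draws), secular trends
in covariate prevalences, correlation between covariates (covariates are
drawn independently, so need variables are uncorrelated with expenditure
rank by construction — which is exactly what makes `HI ≈ C` under the
default DGP a prediction rather than an artifact), or informative
missingness. Passing tests therefore establish the correctness of the
estimators and identities, not the behaviour of the pipeline under
real-survey complications.

## Numerical and problem-size choices

* Oracle-equivalence checks compare the covariance-form index with an
  O(n²) pairwise double sum `C = Σ_ij (h_i−h_j) sign(r_i−r_j) / (2n²μ)`
  on 500 instances of n ≤ 12 at 1e-12.
* Adding-up is checked on 100 generated cohorts of n = 2,000 at 1e-10.
* Recovery compares the mean of 200 estimates at n = 3,000 with the
  n = 10⁶ oracle. Both are Monte Carlo, so the tolerance is twice the
  standard error of the *difference* (replicate-mean SE combined with the
  oracle SE, the latter scaled by √(3000/10⁶)). There is a measured
  ≈−0.001 finite-sample offset at n = 3,000 traceable to the interaction
  of tail-outlier injection with quantile trimming; it sits well inside
  the Monte-Carlo tolerance but is visible with enough replicates.
* Null size is estimated from 500 zero-gradient replicates at n = 3,000.
* Directional checks (monotone fitted inpatient odds-ratio gradient) use
  a 30,000-record cohort so the fitted ordering reflects the generating
  gradient rather than sampling noise; contribution-dominance checks run
  at the default cohort size (~10,000).
* Subgroup panels report NaN for groups with fewer than 30 complete cases
  (configurable), mirroring how sparse subgroup estimates are published.
* Quantiles everywhere use NumPy's inclusive linear interpolation;
  tie-breaks are documented at each site (rank midpoints; lower quintile
  at cut points).

## Known limitations

* The convenient-regression SE is approximate (see above); no dominance
  tests between concentration curves are provided.
* The decomposition is descriptive, not causal; the residual includes
  linearization error of the probit and any omitted structure.
* Horizontal-inequity estimates inherit the probit's complete-case
  sample, so `c_j` values can differ slightly between outcomes analysed
  on different complete-case subsets; this is logged, not reconciled.
* Real restricted-access survey data (with weights, clustering and
  attrition) are out of scope; the package analyses any CSV that follows
  the documented column dictionary.
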