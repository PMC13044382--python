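# Methods

This note documents the statistical procedures panelnet implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
determine the exact outputs.

## Cross-sectional networks

One wave of 20 ordinal symptom scores is summarized by a Pearson
correlation matrix (Spearman optional; polychoric input is not
implemented). Zero-variance items are an error naming the symptom; a
numerically indefinite matrix is repaired by eigenvalue clipping with the
repair logged. The Gaussian graphical model is estimated by graphical
lasso — penalized objective −log det Θ + tr(SΘ) + λ‖Θ‖₁ on the
off-diagonal, diagonal unpenalized — solved by block coordinate descent
(numba-compiled, warm-started along the path). The penalty grid has 100
log-spaced points from λ_max (the smallest penalty giving an empty graph,
i.e. max |S_ij|) down to λ_max/100.

Selection uses the extended BIC with γ = 0.5:
EBIC(λ) = −2ℓ(Θ̂) + E log n + 4γE log p. Two variants are offered:

* `refit=True` (default): the EBIC of each candidate support is computed
  on the unpenalized maximum likelihood constrained to that support
  (solved by the same block-coordinate scheme with zero penalty), and the
  refit partial correlations are returned. This is the form the EBIC
  selection theory is stated for; scoring the shrunken estimate instead
  biases the selection toward dense models because heavily shrunk large
  edges leave likelihood on the table that spurious small edges then
  recover. On synthetic panels (n = 2000, p = 20, density .15) the refit
  rule attains sensitivity ≈ .97 with false-discovery proportion ≈ .01,
  versus FDP ≈ .25 for penalized scoring.
* `refit=False`: classic penalized scoring and shrunken weights. Its edge
  weights vary continuously in λ, which makes it the right choice where
  smooth bootstrap behaviour matters more than support recovery.

Ties in EBIC go to the larger penalty (sparser model). Weights below
1e-10 are snapped to exact zero so edge counts are well defined.

## Expected influence

One-step signed EI for undirected networks; out-EI (row sums) and in-EI
(column sums) for the lagged network, excluding the autoregressive
diagonal — in/out influence is read as symptom-to-*other*-symptom
influence. z-scores use the population (n-denominator) standard deviation
across the 20 nodes; the z > 1 rule flags core symptoms. An all-equal
centrality vector (e.g. empty network) yields zeros with a warning rather
than an error.

## Resampling

Edge accuracy: nonparametric subject bootstrap (default 1,000 draws),
re-estimating the complete network per draw; 2.5/97.5 percentile CIs per
edge, with the mean and SD of CI widths as summary accuracy measures.
Bootstrapped difference tests for two edges or two EI values call a
difference significant when the 95% percentile CI of the difference
excludes zero. Draw-level random streams derive from (master seed, draw
index), so results are reproducible and independent of execution order.
Failed draws (e.g. a zero-variance resampled column) are skipped and
counted; more than 5% failures aborts.

Stability: case-dropping bootstrap over the proportion grid .05–.75 (step
.05). For each proportion, subsets are drawn without replacement, the
network (or CLPN) re-estimated, and subset centrality Pearson-correlated
with the full-sample vector (zero-variance vectors contribute 0). The
CS-coefficient is the largest grid proportion at which ≥ 95% of draws
reach correlation ≥ .7. Note one boundary fact found while testing: a
percentile CI can exclude its own bootstrap mean when an edge appears in
fewer than 2.5% of draws (point mass at zero plus a rare tail), so the
mean-inside-CI property is only guaranteed for intervals of positive
width.

## Network comparison test

Structure statistic M = max_{i<j} |w¹_ij − w²_ij|; strength statistic
S = |Σ|w¹| − Σ|w²||. Both are recomputed under full re-estimation in
every permutation — never on fixed networks. The paired scheme swaps each
subject's wave labels independently with probability ½ (the
within-subject exchangeability null); the independent scheme permutes
group labels over pooled subjects. p-values use the add-one rule
(1 + #{perm ≥ obs})/(1 + n_perm), which keeps p in (0, 1] and makes the
degenerate identical-input case return exactly p = 1. A Bonferroni helper
provides the family-wise adjusted α for multiple comparisons. Calibration
under a no-change generator (both waves i.i.d. from one GGM; 100
datasets of n = 250 at p = 10, 200 permutations, a 12-point penalty grid)
gives type-I error ≈ .03 for both statistics at α = .05; those
Monte-Carlo sizes are the package's calibration-study conditions.

## Cross-lagged panel network

Node-wise LASSO of each standardized wave-2 symptom on all 20
standardized wave-1 symptoms, penalty by k-fold (default 10)
cross-validated MSE at the CV-minimum rule — the convention of the
descriptive CLPN literature; the one-standard-error rule is not used.
Standardization uses full-sample means and SDs computed before the CV
split: deterministic and simple, at the price of a slight optimism in
fold errors (harmless for point estimation, documented here). One fold
assignment, derived from the seed with subjects as the unit, is shared by
all 20 regressions. Covariates, when requested, enter the penalized
design matrix alongside the symptoms (a single design matrix) but never
the network or the EI sums; `penalize_covariates=False` instead partials
them out by OLS first. The autoregressive-vs-cross-lagged contrast is a
paired t-test across the 20 symptoms of (autoregressive_i − mean outgoing
cross-lagged coefficient of symptom i), df = 19; outgoing (row) means are
used because the directional reading of "a symptom's cross-lagged
effects" is its effects on others. A zero-variance difference vector is
flagged degenerate (t reported as ±∞ with p = 0, or 0/1 for the all-zero
matrix).

## Clinical linkage

Paired Cohen's d uses the pooled pre/post SD of the totals,
d = (mean_pre − mean_post)/√((s²_pre + s²_post)/2); the formula is
recorded in the output since several conventions exist. Within-person
variability is each subject's SD across the 20 item scores, compared
between waves by paired t-test.

The symptom-importance index for symptom s is the Pearson correlation
across subjects between s's change score and the *sum* of the other 19
change scores (the sum composite; a mean composite differs only by a
constant and leaves the correlation unchanged). Importance is regressed
by OLS on one centrality measure plus baseline severity across the 20
symptom rows; the zero-order centrality–severity correlation is reported
alongside as the usual confounding check.

The outcome regression predicts the post outcome from the pre outcome,
baseline symptom total, age, sex, race, maltreatment indicator, mean
peripheral change and mean core change (core = symptoms flagged central).
Two estimators: listwise-complete OLS, and EM for the mean and covariance
of the joint multivariate normal over all nine variables, with regression
coefficients derived from the converged moments and standard errors from
a nonparametric subject bootstrap (EM per draw). The EM route gives the
maximum-likelihood point estimates under MAR — identical to OLS when no
data are missing, which the implementation verifies internally — while
avoiding the information-matrix algebra; binary covariates enter the
normal model as numeric variables, the standard practical compromise and
a known approximation. EM convergence is a relative observed-data
log-likelihood change below 1e-8 (max 500 iterations; failure raises).

Little's MCAR test compares each missingness pattern's observed-variable
means against the EM estimates: χ² = Σ_k n_k (ȳ_k − μ̂_k)ᵀ Σ̂_k⁻¹
(ȳ_k − μ̂_k) with df = Σ_k p_k − p; singular pattern submatrices get a
ridge repair with a warning. Calibration: type-I error ≈ .06 over 200
MCAR replicates at α = .05; power ≈ 1 against strong
missingness-on-the-masked-value at n = 1000.

No multiple-testing correction is applied inside the clinical module;
Bonferroni adjustment is provided (and intended) for the network
comparison family only.

## Synthetic-data generator

The generator is first-class, tested code, and its defaults are the study
conditions the rest of the package is verified under.

* **Wave-1 structure**: a sparse precision matrix with unit diagonal,
  Bernoulli(edge_density) support, partial correlations drawn uniform
  .15–.40 with 80% positive signs. If the smallest eigenvalue falls below
  0.3 the off-diagonal is shrunk by 10% steps; the floor keeps implied
  latent correlations in the moderate range of real symptom inventories
  (a near-singular precision implies inter-item correlations near 1 and
  grossly distorts the discretized scale).
* **Transition**: the lagged matrix has diagonal ~ N(.15, .07²) and, on a
  50%-density off-diagonal support, entries ~ N(.01, .01²);
  `crosslag_sd = 0` switches cross-lagged paths off entirely. The
  transition acts on the standardized *observed* wave-1 scores, because
  the lagged coefficients emulate the estimand of the node-wise
  regressions (standardized effects of observed scores); coupling through
  the latents would define a different, attenuated estimand.
* **Wave 2**: transition prediction plus innovations from a second,
  independently drawn sparse GGM (so the post network is estimable and
  genuinely different in wiring), residual variances completing each
  variable to unit variance, minus a mean shift of 0.29 latent SD —
  calibrated so the paired d on totals is ≈ 1.0 at n = 652, the scale of
  improvement treatment panels of this kind report.
* **Discretization**: common cutpoints (−.5, .3, 1.0, 1.8) produce
  right-skewed five-category items (≈ .31/.31/.20/.13/.04), matching the
  floor-heavy look of clinical symptom data; configurable per item.
* **Covariates**: age truncated-normal 12.47 ± 3.12 on [7, 18], 57.5%
  girls, 21.9% racial minority, 50% maltreatment index trauma (the
  maltreatment margin is a round default; the cohort tables it emulates
  do not pin it down).
* **Outcome**: 0–40 integer total; post outcome = linear function of the
  pre outcome (β = .6), baseline severity, age, mean change in the
  generating network's central symptoms (β = 1.0 — the recovery target of
  the outcome-regression tests), mean peripheral change (β = .3), plus
  N(0, 3²) noise, rounded and clipped.
* **Missingness**: two-stage logistic MAR. The post outcome goes missing
  as a function of standardized wave-1 severity and age (intercept
  root-solved so the sample rate hits the target, default 50%); the pre
  outcome then goes missing as a function of the *observed* post value
  plus severity (default 25%). Both stages condition only on observed
  quantities, so the mechanism is MAR by construction — but the second
  stage makes listwise deletion select on an outcome-correlated variable,
  which is the regime where likelihood-based estimation genuinely beats
  complete-case analysis (measured core-coefficient bias ≈ −.02 vs −.13).
  A one-stage severity-only mechanism leaves complete-case OLS consistent
  and would make the FIML-vs-listwise comparison vacuous.

What the generator does *not* emulate: item-level (31-item) structure and
any item→symptom collapsing (real data are mapped by a user-supplied
table, max aggregation by default, since published instruments rarely
document the collapsing); dissociative-subtype screening items;
therapist, session or dosage structure; informant effects in the outcome;
ordinal measurement error beyond thresholding. Passing recovery tests on
these panels therefore demonstrates correctness of the estimators under a
faithful-but-idealized data-generating process, not performance on any
particular clinical dataset.

## Pipeline

The master seed fans out to per-stage seeds by SHA-256 hashing of
(master_seed, stage name), so adding a stage never perturbs earlier
stages' randomness and every artifact is re-derivable from config + seed.
Bundles contain no timestamps; two runs with one config are
byte-identical. Stages communicate only through declared files. The
`cs_n_boot` setting lets the case-dropping stage (whose CLPN re-fits
dominate runtime) use fewer draws than the edge bootstrap. Defaults
follow the standard reporting conventions throughout: γ = .5, 1,000
bootstrap draws, 1,000 permutations, 10 folds, z > 1 centrality flags,
.10 display threshold for lagged edges, CS correlation .7.

## Test-suite problem sizes

Recovery and calibration suites run at the sizes stated above (support
recovery n = 2000 × 20 seeds; CLPN recovery n = 2000 × 20 seeds; NCT
calibration 100 datasets × 200 permutations at p = 10, n = 250; FIML
comparison 50 seeds; MCAR calibration 200 replicates). The end-to-end
determinism check runs the full pipeline twice on an n = 652 panel with
reduced resampling (100 bootstrap draws, 25 permutations, 6 case-drop
draws on a 2-point grid), which exercises every stage while keeping the
suite inside a routine CI budget; `scripts/acceptance.py` runs the
moderate-resampling version.

## Known limitations

Pearson correlations on 5-point items attenuate latent associations
(≈ 10–15% here); polychoric input would remove this but is deliberately
out of scope. The CLPN inherits all caveats of two-wave cross-lagged
models — coefficients describe prediction, not causation, and CV-minimum
LASSO shrinks coefficients toward zero (the mean recovered autoregressive
effect is ≈ .11 for a generating .15 at n = 2000). EM assumes joint
multivariate normality over variables that are actually bounded counts
and binaries; the induced bias is small in the tested regimes but not
zero. The CS-coefficient convention takes the largest passing grid
proportion; profiles that dip and recover (rare, noisy data) read
optimistically.
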