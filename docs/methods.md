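# Statistical methods

This note records the model, the estimators as implemented (including every
default and the reason for it), the synthetic-data designs used to validate
them, and known limitations.

## 1. Lifetime smoking index

For duration `dur`, time since cessation `tsc` and cigarettes per day `cpd`:

```
score = (1 − 0.5^(dur/τ)) · 0.5^(tsc/τ) · f(cpd),   f(cpd) = ln(cpd + 1)
```

* τ (half-life, years) controls both accumulation and decay; default **18**.
* Never smokers score 0 (`dur = 0`; `tsc` undefined and irrelevant).
* The score is strictly increasing in `dur` and `cpd`, strictly decreasing
  in `tsc`, bounded by `ln(cpd + 1)`, and invariant to rescaling all three
  time quantities (`dur`, `tsc`, τ) by a common factor.
* Exposure times derive from ages: `dur = age_cess − age_init` (former) or
  `age_assess − age_init` (current); `tsc = age_assess − age_cess` (former)
  or 0 (current). Former smokers missing `age_cess` cannot be scored and are
  excluded with a logged count.
* `cpd` is validated to [1, 150] for ever-smokers — values outside this are
  almost certainly data errors, and `ln(cpd+1)` grows slowly enough that the
  cap is conservative.

### Half-life calibration

`calibrate_half_life` scores the cohort at each τ on a grid (default 2–40 in
steps of 2 — spanning implausibly fast to implausibly slow decay at a
resolution finer than the data can distinguish) and picks the τ maximising
the log-likelihood of an outcome model with the score as sole covariate:

* `criterion="logistic"` (default): binomial GLM, suited to binary
  disease status;
* `criterion="cox"`: Cox proportional hazards on (time, event), via
  lifelines.

Ties and near-flat profiles (range < `flat_tol`) resolve toward the smallest
τ and raise a `RuntimeWarning`, because a flat profile means the outcome
carries no information about the half-life and the choice is arbitrary.
Degenerate inputs (no events, no exposure variance) raise `CalibrationError`
rather than returning a meaningless optimum.

## 2. Instrument selection and harmonisation

* Selection: p < 5×10⁻⁸ (genome-wide significance), then greedy clumping
  keeping the smallest-p SNP and removing neighbours within 10 Mb on the
  same chromosome with r² ≥ 0.001 when a pairwise LD table is supplied.
  Without one, pruning is distance-only and the instrument set records
  `"distance-only"` provenance with a warning — approximate, but the only
  option offline.
* Harmonisation handles four allele configurations (direct, swap,
  strand-complement, complement-swap). Swapped alignments negate the
  outcome beta and reflect the frequency. Palindromic SNPs (A/T, C/G) carry
  no strand information in their letters, so they are aligned purely by
  whether each study's effect-allele frequency falls on the same side of
  0.5, and retained only when **both** frequencies are below 0.3 (MAF rule):
  near 0.5 the frequency comparison itself becomes unreliable.
* Every input SNP is either retained or appears in the drop log with a
  machine-readable reason (allele mismatch, ambiguous palindrome, missing
  from outcome, duplicate). Missing SNPs can be replaced from a user-supplied
  proxy table (best available proxy with r² ≥ 0.8).

## 3. Estimators

All operate on harmonised per-SNP pairs (γ̂ⱼ, σγⱼ) exposure and (Γ̂ⱼ, σΓⱼ)
outcome.

* **Wald ratio** (single SNP): Γ̂/γ̂ with first-order delta SE (optional
  second-order term).
* **IVW**: through-origin WLS with weights 1/σΓⱼ²; multiplicative
  random-effects SE inflation by max(1, √(Q/(J−1))) (default on — smoking
  instruments are heterogeneous); p-values from t with J−1 df.
* **MR-Egger**: WLS with intercept after orienting all SNPs to γ̂ⱼ ≥ 0;
  t with J−2 df; the intercept estimates directional pleiotropy.
* **Weighted median**: ratio estimates ordered, cumulative midpoint weights
  (cumsum(w) − w/2)/Σw with w = γ̂²/σΓ², linear interpolation to 0.5;
  SE by parametric bootstrap (default 1000 draws). Consistent when ≥ 50% of
  the weight is on valid instruments.
* **Weighted mode**: mode of an IVW-weighted normal KDE of the ratios,
  bandwidth 0.9·min(sd, IQR/1.349)·J^(−1/5)·factor (modified Silverman;
  factor 1 by default), evaluated on a 512-point grid augmented with the
  ratio points themselves so the bandwidth→0 limit is exact; bootstrap SE.
* **MR-RAPS**: profile likelihood over residuals
  tⱼ = (Γ̂ⱼ − βγ̂ⱼ)/√(σΓⱼ² + β²σγⱼ² + τ²); squared or Huber (c = 1.345)
  loss; overdispersion τ² by joint minimisation of Σρ(t) + ½·δ·Σlog(v) with
  δ = E[ψ(Z)Z] (1 for squared loss, P(|Z| < c) for Huber); sandwich SE.
  Non-convergence raises `ConvergenceError` with the optimiser trace.
* **Diagnostics**: Cochran's Q against the IVW slope;
  I²GX = max(0, (Q_GX − (J−1))/Q_GX) measuring regression-dilution of the
  Egger slope; mean F̄ = mean(γ̂²/σγ²); Steiger filtering removes SNPs whose
  outcome r² exceeds exposure r² significantly (reverse-causal instruments),
  with r² = 2β²f(1−f) and a Fisher-z overall direction test.
* **SIMEX-corrected Egger**: run when I²GX < 0.9 (the conventional
  reliability threshold below which the naive Egger slope is diluted by
  > 10%). Noise with variance λσγⱼ² is added for λ = 0, 0.25, …, 2; the
  unweighted Egger slope as a function of λ is fit with a quadratic and
  extrapolated to λ = −1 (zero measurement error); SE by SNP bootstrap.

`run_mr` emits one row per method; a failing method yields a
`"failed: ..."` note row rather than aborting the battery, and for binary
outcomes betas are exponentiated to ORs.

## 4. Synthetic data designs

### Summary statistics

γⱼ ~ N(0, γ_sd²) (optionally oriented positive — the exposure-increasing
allele convention, required for directional-pleiotropy bias to survive
averaging), αⱼ pleiotropic effects (none / balanced mean-0 / directional /
correlated "inside-violating"), Γⱼ = θγⱼ + αⱼ, and standard errors from the
GWAS approximation σ ≈ 1/√(2nf(1−f)) with f uniform on the configured
frequency range. Allele bookkeeping (palindromic SNPs, strand flips, allele
swaps) is injected at configurable rates to exercise harmonisation. Truth is
returned alongside.

### Cohort

Smoking status mix matches the UK-Biobank-style proportions
(249318 never / 164649 former / 48723 current out of 462690); cpd lognormal
(ln 15, 0.5) clipped to [1, 150]; assessment age N(56.7, 8) clipped to
40–69; initiation age N(17, 3); binary outcome from a logistic model on the
true score with τ_true = 18.

### Study conditions in the acceptance suite (fixed a priori)

* **Recovery/coverage**: J = 100, θ = ln 2, γ_sd = 0.2, n = 1,232,091
  (consortium scale, chosen because weak-instrument attenuation of ratio
  estimators is ≈ θ/F̄ — at small n this bias is real, not a bug, and would
  dominate the Monte-Carlo error gate). Gate: |mean − θ| < 4·SE_MC per
  estimator over 500 replicates; IVW 95% CI coverage in [93%, 97%] over
  1000.
* **Type-I error**: θ = 0, balanced pleiotropy α_sd = 0.002; IVW and
  Egger-intercept rejection within the 99% binomial band of 0.05 over 2000
  replicates.
* **Median robustness**: 30% invalid instruments with directional pleiotropy
  α ~ N(0.1, 0.02), positive-oriented γ; median bias < 0.05 while IVW bias
  exceeds 0.05 and 3× the median's.
* **SIMEX**: deliberate dilution (J = 50, γ_sd = 0.02, n_exp = 10,000,
  n_out = 500,000 so I²GX is low); corrected beats naive unweighted Egger in
  ≥ 80% of 200 replicates.
* **Half-life recovery**: N = 20,000 cohorts, grid 2–40 step 2; τ* within
  one grid step of 18 in ≥ 9 of 10 seeds.

All thresholds and seeds were fixed from pre-registered prototype runs
before the tests were written, not tuned afterwards.

## 5. Numerical choices

* Closed-form WLS lines (no iterative fitting) for IVW/Egger; verified
  against statsmodels WLS to 1e-10 in the test suite.
* RAPS optimises log τ² to keep the overdispersion parameter positive;
  the β profile uses Brent within bracketed bounds.
* SIMEX λ = 0 uses the exact (noise-free) slope; quadratic extrapolation via
  `np.polyfit`, with a rank-degenerate fit falling back to the naive slope
  with a note.
* All randomness flows through `numpy.random.default_rng` seeded from
  configs; pipeline outputs are byte-identical across reruns of the same
  config.

## 6. Limitations and open decisions

* Distance-only clumping without an LD table is approximate; supplying
  pairwise r² is strongly recommended for real data.
* The logistic calibration criterion treats the outcome as cross-sectional;
  for incident-disease cohorts the Cox criterion is more appropriate but
  requires follow-up times.
* The σ ≈ 1/√(2nf(1−f)) generator approximation assumes a standardised
  continuous trait and ignores case-control ascertainment; it is adequate
  for validating estimator behaviour, not for power calculations.
* MR assumptions (no confounding of the SNP-outcome path, gene-environment
  equivalence of the index) are untestable from summary data; the battery of
  pleiotropy-robust estimators probes, but cannot prove, their violation.
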