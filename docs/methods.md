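# Methods

## The measurement model

δ and g′ form an orthogonal two-factor ("bifactor") model over five
Wave-2 indicators: four cognitive tests (delayed logical memory LMII,
visual reproduction VRI, verbal fluency COWA, digit span DST) and the
summed informant-rated IADL (eight items scored 0–3, total 0–24). δ
loads on all five — IADL is what distinguishes it — while g′ loads on
the four cognitive tests only. cov(δ, g′) is fixed at zero by
definition: g′ is the residual of general cognitive ability orthogonal
to the dementia-relevant variance, so a request to free that covariance
is rejected rather than honoured. Identification is by unit factor
variance (not a fixed first loading), which keeps loadings comparable
across groups in multigroup fits. Indicators are standardized before
fitting; the standardization constants are stored on the fitted
`DeltaModel` and reused when scoring new rows.

Composites ("d-scores") are regression-method factor scores,
`W = C Σ⁻¹` with `C` the implied factor–indicator covariance: a
subject's δ composite (dEQ) is `W` applied to their standardized
indicator vector. Subjects missing any indicator get a missing score —
partial weighted sums would put subjects on different scales. Factor
quality is summarised by Grice's determinacy, the model-implied
correlation between composite and factor; for a standardized single
factor this is √(λ′Σ⁻¹λ). A CFA factor's global sign is arbitrary, so
`DeltaModel` orients each factor so the first cognitive test loads
positively (higher composite = better cognition); ROC results record
the orientation actually used.

## The estimation engine

Models are specified in a compact text syntax (`factor =~ i1 + i2`,
`y ~ x [tag]`, `e1 ~~ e2`, numeric prefixes fix values, `[tag]`
suffixes name parameters for cross-group equality) and compiled to a
RAM parameterisation: directed paths in `A`, symmetric (co)variances in
`S`, means in `m`, implied moments `Σ = F(I−A)⁻¹S(I−A)⁻ᵀF′` and
`μ = F(I−A)⁻¹m`. Residual variances, saturated exogenous covariance
blocks and (under a mean structure) free means are auto-completed.
Residual covariances are opt-in via the syntax, never searched for
automatically: modification-index hunting is not reproducible.

Two discrepancies are implemented:

* **listwise** — complete rows; Wishart ML discrepancy
  `F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p`, `χ² = (N−1)·F`; a `likelihood="normal"`
  option uses the N-divisor covariance instead, which makes the optimum
  coincide exactly with FIML on complete data (the two conventions
  otherwise differ at order 1/n).
* **fiml** — full-information ML: the casewise Gaussian log-likelihood
  over each row's observed subset, rows grouped by missingness pattern
  into sufficient statistics. χ² is the likelihood-ratio statistic
  against the saturated model (itself fitted by FIML); the CFI baseline
  is the independence model.

Gradients are analytic in both modes (chain rule through the RAM
matrices; the mean channel enters through `(I−A)⁻¹m`). Optimization is
L-BFGS-B (variance parameters bounded below at 1e−8, ftol 1e−12, gtol
1e−9, max 500 iterations) followed by a Newton polish on the gradient —
finite differences of the analytic gradient give the Hessian — so
closed-form oracles are matched to ~1e−10 rather than line-search
tolerance. Standard errors come from the inverse observed information.
Convergence requires the max absolute gradient below 1e−3·max(1, N); a
failed fit triggers up to three deterministic jittered restarts and is
flagged, never returned silently. Non-positive-definite implied
covariances are handled by a finite penalty that pushes the optimizer
back into the feasible region. Loading start values are staggered
across factors (0.7, 0.35, …): identical starts for two overlapping
factors sit on an exchange-symmetry saddle.

Fit indices follow the standard formulas: CMIN/DF = χ²/df,
CFI = 1 − max(χ²−df, 0)/max(χ²₀−df₀, 0),
RMSEA = √(max(χ²−df, 0)/(df·(N−1))); df = 0 reports CMIN/DF and RMSEA
as not applicable.

## The QC cascade

Raw multiplex immunoassay panels arrive as duplicate reads per subject
× analyte with LOW flags, a least-detectable dose (LDD) per analyte and
batch labels. The cascade runs in a fixed order:

1. **Duplicates** — relative difference |x₁−x₂|/mean > 5% discards the
   observation (the mean is retained otherwise). The denominator is the
   pair mean: symmetric and scale-free. Pairs with both reads LOW
   bypass the rule (their values are below quantification) and carry
   forward as LOW.
2. **LOW** — an analyte whose LOW fraction among usable samples
   strictly exceeds 50% is dropped entirely; at exactly 50% it is
   retained (the drop rule is a strict inequality). Remaining LOW
   readings are imputed at LDD/2.
3. **Outliers** — a single pass deletes values beyond 3 sample SDs of
   the analyte mean, both computed once on the input; no iterative
   re-screening, and a zero-SD analyte is left alone.
4. **Normalize/standardize** — natural log iff |bias-corrected sample
   skewness| > 1.0 (configurable; the threshold for "highly skewed" is
   a package choice), then z-scoring with the n−1 denominator.
5. **Batch** — least-squares residualisation on an intercept plus k−1
   batch dummies, then re-standardization to unit variance. Batch means
   of the output are zero to numerical tolerance; a singleton batch is
   retained with residual zero and a warning.

Standardization before and after batch adjustment keeps every analyte
on the same scale regardless of how much variance batch absorbed. The
QC report accounts for every reading (retained + discarded = input) and
serializes to JSON.

## The mediation screen

Each protein is fitted in its own recursive two-equation system with
the exposure (GDS) standardized in-sample, the seven covariates (age,
education, ethnicity, gender, APOE ε4 count, homocysteine, HbA1c) in
both equations, and the Wave-2 dEQ composite as the observed outcome.
The system is estimated simultaneously by ML (optionally FIML over
incomplete rows); on complete data the path estimates provably equal
equation-by-equation least squares, which the tests exploit as an
independent oracle. The a-path is re-estimated inside every protein's
model rather than frozen from the base model, so each row of the output
table reports its own adjusted direct effect.

Inference on the indirect effect uses the first-order product-of-
coefficients standard error √(b²se_c² + c²se_b²) (the second-order
se_c²se_b² term is available behind a flag, default off). The screen
threshold is a fixed α = 0.001 — a Bonferroni-style cap applied as a
constant, not recomputed as α/m — and Class-1 (mediator) status
requires significant b and c paths *and* a MacKinnon p below α. Percent
mediated is 100·|indirect|/(|indirect| + |direct|); the formula is a
package convention (several exist in the literature) and is
configurable in principle via the reported signed components. The
four-class taxonomy (mediator / GDS-only / δ-only / unrelated) is the
b×c significance cross-tabulation and partitions any panel.

At moderate effect-to-SE ratios the product statistic is detectably
sub-normal; its α-level calibration is therefore checked in the
asymptotic (small-SE) regime where the normal reference applies, using
draws from the estimators' asymptotic Gaussian sampling laws.

## Split-half replication

`split_half` partitions the cohort into ⌊n/2⌋/⌈n/2⌉ halves from a
seeded permutation (a Bernoulli(½) option reproduces slightly unequal
subset sizes). `constrained_comparison` fits the mediation spec to both
groups jointly, once with the chosen tags (default a, b, c) shared and
once fully group-specific; Δχ² on Δdf = number of constraints tests
generalizability at α = 0.05 (configurable; the criterion is
non-significance). Mediation effects are then read from the Group-1
parameters of the constrained model. Nesting guarantees
χ²_constrained ≥ χ²_unconstrained up to optimizer tolerance.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with every generating parameter retained:

* **Covariates** from a Gaussian copula (exchangeable correlation 0.25
  by default — the covariates are intercorrelated but no cohort
  publishes the matrix) with realistic marginals: age ≈ N(70.9, 9.5²),
  education rounded years, dichotomous ethnicity (36%) and gender
  (39%), APOE ε4 count 0–2, log-normal homocysteine and HbA1c.
* **GDS** as a negative-binomial quantile transform (mean 5.6, size
  1.43 → SD ≈ 5.25, right-skewed, integer 0–30) of a latent Gaussian
  tied to the covariates. Structural equations use the in-sample
  z-scored GDS, so path coefficients are in standardized-exposure
  units and the analysis standardization matches the generator's
  exactly.
* **Proteins** `p_j = c_j·z_GDS + covariate effects + noise` on an
  approximately unit-variance scale. The default 115-protein panel
  realises the four classes: 10 mediators (c = 0.5, b = −0.3), 3
  GDS-only, 5 δ-only, 97 null.
* **δ** `= a·z_GDS + Σ b_j p_j + covariate effects + disturbance`
  (a = −0.10 by default), oriented so higher δ = better cognition; an
  independent standard-normal g′. A standardized copy of each factor
  drives the indicators; the structural-scale δ is what recovery
  checks regress on.
* **Indicators** from the bifactor loadings (defaults below), then
  mapped to observed scales: integer cognitive scores with Table-1-like
  means/SDs, IADL as the sum of eight discretized 0–3 items, CDR-SB as
  a deterministic monotone decreasing transform of δ rounded to halves
  (0–18), diagnosis by δ quantile thresholds (37% AD / 20% MCI / 43%
  NC by default — published cohorts print counts, not a rule). Default
  loadings (δ; g′): LMII 0.55; 0.40, VRI 0.50; 0.30, COWA 0.30; 0.65,
  DST 0.25; 0.55, IADL −0.80; 0. The δ/g′ loading *ratios* differ
  across tests deliberately: near-proportional ratios leave the
  bifactor model empirically under-identified (two loading patterns
  reproduce the same Σ), which is a property of bifactor models, not of
  this implementation.
* **Raw panel artefacts**: exponential link (right skew), additive
  log-scale batch shifts over 4 batches, duplicate reads with relative
  error `duplicate_cv` (default 2%), LDD censoring at the 5% quantile
  of each analyte's raw distribution, and 0.5% gross-error outliers.
* **Missingness** injected per block at per-column rates (GDS 0.112,
  covariates 0.01, indicators 0.02 by default), missing at random,
  ground truth untouched.

All randomness flows from one integer seed; identical configs give
byte-identical tables.

What the generator does **not** emulate: measurement non-invariance
across ethnicity (the indicators behave identically for everyone),
informant bias in IADL, floor/ceiling effects beyond simple clipping,
plate-level assay drift within batch, missingness that depends on
disease severity (MNAR), and any longitudinal structure beyond the
baseline-exposure / Wave-2-outcome design. Passing tests therefore
demonstrate that the pipeline's statistics behave as designed under the
assumed data-generating process — correct calibration, power and
recovery — not that real cohort effects of a given size exist.

## Problem sizes used in the checks

Recovery uses 200 replicates at n = 20000 (one protein); the MacKinnon
null calibration uses 10⁵ draws; the screen operating characteristics
use 50 seeds of the full 115-protein panel at n = 3400 on the QC-ideal
protein values (the QC cascade's own behaviour is verified separately
on the distorted duplicate panels); the invariance null uses 500
replicates of 300-per-group fits. Recovery regresses on the generator's
structural δ: any factor-score composite attenuates the b (and a)
paths by the factor determinacy, so composite-outcome runs measure
screening power, not unbiased path recovery — both views are reported
by the pipeline when truth is available.

## Known limitations

Categorical indicators are treated as continuous (no polychoric
estimation), standard errors are information-based (no robust/sandwich
corrections), there are no modification indices, no multivariate
multi-mediator models or interactions, and no bootstrap CIs for the
indirect effect. FIML assumes multivariate normality and missingness at
random; the ROC analyses use complete cases by construction.
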