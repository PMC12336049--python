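# Methods

This note documents the models, the numerical machinery, the synthetic
cohort generator, and the design choices behind `rri`, in the spirit of a
statistical-software methods appendix. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The estimation problem

The scientific question is whether the *residual reserve index* — the part
of episodic-memory performance not explained by structural brain measures
or demographics — protects executive function (EF) against low brain
integrity differently in women and men. Statistically this is a
constrained SEM in three connected parts:

1. a measurement-constrained decomposition of the memory composite into
   orthogonal components MEMB (brain), MEMD (demographic) and MEMR
   (reserve);
2. a latent growth curve for EF over up to seven 18-month visits; and
3. structural regressions of the growth factors on the memory components,
   sex, APOE ε4 count, centred age, and their products — including the
   latent-by-latent product MEMR×MEMB and the three-way MEMR×MEMB×sex.

Missing longitudinal data are handled by casewise (full-information)
maximum likelihood; products of latent variables make the marginal
likelihood non-normal and require numerical integration.

## 2. Engine: conditionally linear SEM with Gauss–Hermite marginalization

Every model is compiled to a *conditionally linear Gaussian* form. Product
terms are linearized by conditioning on a minimal set of exogenous
"quadrature latents" — here MEMR alone suffices, because each product
contains at most one other latent (MEMB) once sex (observed) is known.
Given MEMR = r and the covariates x, the model is

    eta = (I − B(r, x))⁻¹ (a(r, x) + zeta),    zeta ~ N(0, Psi)
    y   = nu + K x + Lambda_Q r + Lambda eta + eps,   eps ~ N(0, Theta)

and the casewise likelihood integrates the conditional normal density of
each subject's observed subvector over r with Gauss–Hermite quadrature.
The rule is *adaptive*: each subject's integrand is scanned on a grid, the
mode and local curvature recentre and rescale the nodes. A frozen rule is
used within each optimization pass and refreshed until the likelihood is
stable; with all product coefficients at zero the quadrature is exact
(machine precision), which the tests verify, along with node-refinement
stability (~1e-6 change on doubling) and an exact two-group oracle for
latent-by-binary products.

Exogenous covariates are conditioned on (fixed-x), never modelled; they
must be complete. Endogenous observed variables may be missing arbitrarily;
with subject-specific conditional covariances the missingness patterns are
handled in one flat batch by identity-padding (exact for the likelihood and
all score terms), otherwise pattern-by-pattern.

**Gradients and optimization.** Gradients are analytic: posterior node
weights times casewise normal score terms, chained through the parameter
placements and the unconstrained internal scale (log for variances,
Cholesky factors for covariance blocks, so implied matrices stay PSD
without clamping). Optimization is dense BFGS on a diagonally
preconditioned scale (the preconditioner is the square-root diagonal of the
outer-product-of-scores information at the start values), run to a loose
gradient tolerance and finished by Newton steps using the finite-difference
observed information — which is then reused for standard errors. Default
convergence: gradient max-norm below 1e-5 (absolute) or below 2e-7·|LL|
(relative), both overridable; non-convergence is always flagged, never
silent. If a variance dives to zero (degenerate data), the likelihood is
unbounded; the fit is re-solved with log-variances floored at 1e-6 and the
boundary is reported with a warning.

**Starting values.** The decomposition and growth stages are fitted first;
growth starts come from casewise OLS of EF on the time bases (the growth
surface has stationary points with collapsed slope variance that default
starts can reach — the data-driven starts avoid them, and a regression
test keeps it that way). The joint model starts from the two-stage
factor-score regression (attenuated, but in the right basin).

**Standard errors** are the inverse observed information (delta-method to
the natural scale); the outer-product (BHHH) estimator is available as an
option. Identification is checked at the start values by the rank of the
outer-product information, naming the aliased parameters.

**Standardization** uses model-implied variances throughout: latent
variances propagate through the structural equations; product-term
variances follow closed moment rules (quadrature latents independent of
everything; latents in products zero-mean normal and independent of the
covariates — the code warns if a model violates this); covariate moments
come from the sample. Binary covariates are standardized by their sample
SD by default (the STDYX convention); `std_binary="stdy"` leaves them raw.
Standardized SEs scale the raw SE by the same factor, so est/SE is
preserved. Tests confirm invariance of standardized estimates under
indicator rescaling (×10, refit, agreement to 1e-6).

**Factor scores** (linear models): regression (posterior mean) and
Bartlett (GLS, conditionally unbiased); derived composites (MEMB, MEMD)
propagate deterministically. Bartlett and regression scores of *different*
orthogonal latents share estimation error — for this decomposition the
memory measurement error couples the MEMR and MEMB scores with a
theoretical correlation near −0.07 even though the latents are exactly
orthogonal. Because the reserve index is defined as a residual, the
decomposition stage removes this artifact by projecting the MEMR score
onto the span of the MEMB/MEMD scores in-sample (conditional unbiasedness
is unaffected — regression of the score on the true latent keeps slope ~1,
which is tested); `orthogonalize=False` yields the raw scores.

## 3. Fit battery

Chi-square is the likelihood-ratio statistic against the saturated
mean/covariance model, fitted under missingness by EM; the CFI/TLI baseline
is the independence model (free means/variances), whose FIML solution is
closed-form. With exogenous covariates both sides of each comparison are
augmented by the same saturated covariate block, so the statistic measures
only the structured part. TLI is reported uncapped. RMSEA uses denominator
n by default (`n-1` available); its 90 % CI inverts the noncentral-χ² CDF
in the noncentrality parameter (Brent's method to 1e-8), verified against
Monte-Carlo noncentral-χ² quantiles. SRMR is the RMS of standardized
residuals over unique (co)variance elements. aBIC substitutes (n + 2)/24
for n. An external SEM package is not part of the environment, so the
cross-checks are closed-form cases, χ² calibration against its df under
the true model, and the CI simulation — not a package-vs-package diff.

## 4. Synthetic cohort generator

The generator draws cohorts with the exact statistical structure the
analysis assumes, plus realistic marginals:

- n = 997, 55.4 % female; APOE ε4 counts (65.1/29.2/5.7 %); age
  N(72.79, 6.60²); education normal with sex-specific means (13.33/12.63,
  SDs 3.18/2.95), which plants the education sex gap (SMD ≈ 0.23).
- Prior-assessment count Poisson(1.34); prior interval = 18 months per
  prior visit with mean-one lognormal jitter (SD 0.4 on the log scale);
  their product is the practice-exposure interaction. Subjects with k
  prior assessments contribute min(k, 3) pre-baseline EF visits, tying the
  enrolment covariates to the EF grid.
- Brain true scores: trivariate normal with reliability 0.90 per
  standardized indicator (the fixed 0.10 error) and correlations
  (0.50, −0.30, −0.25); raw scales via affine back-transform — except WMH,
  which is mapped through a lognormal so its raw marginal is right-skewed
  (mean 9.36 < SD 13.41) while the estimator consumes it untransformed.
  The skew slightly attenuates the WMH indicator's effective loading; the
  planted brain weights put the least weight on WMH (direction 0.45, 0.55,
  −0.15), consistent with hippocampal volume being the strongest memory
  predictor, and the decomposition recovery tests confirm the residual
  bias is well inside tolerance.
- Memory = MEMB + MEMD + MEMR + error with variances 0.40, 0.1635, 0.30,
  0.1365 on the standardized scale (summing to 1, so the standardized
  decomposition recovers them directly); output rescaled to mean 0.50,
  SD 0.91. A `memr_sex_shift` option plants a female reserve advantage
  (default 0, because the fitted model treats MEMR as sex-independent and
  planting a shift would make every recovery experiment measure
  misspecification instead of estimation error; the option exists for the
  sex-difference demonstrations).
- EF intercept/slope: every published standardized structural coefficient
  is planted; raw generator coefficients are obtained by closed-form
  population moments of the predictor terms (cross-checked against Monte
  Carlo) and the outcome-variance fixed point V = resid/(1 − βᵀRβ).
  Residual variances 0.22 (intercept) and 0.0117 (slope), residual
  covariance 0.010, EF visit noise 0.127 — chosen so the EF baseline
  marginal matches mean 0.82, SD 0.87 and slope heterogeneity is a
  realistic ~0.11 per 18 months.
- Attrition: death is Bernoulli (3.4 % female, ×2.32 male); the remainder
  face a per-visit post-baseline hazard 0.098·exp(−0.25·z(EF at T=0)
  −0.25·z(observed change)), targeting ~29 % withdrawn. Dropout depends
  only on *observed* values, so missingness is MAR given the modelled data
  and FIML stays consistent — a latent-dependent hazard would be MNAR and
  would bias every downstream recovery. Monotone dropout; intermittent
  missingness is a config option, default off. Centiloid is drawn normal
  (28.78, 42.83) and independent by default; missingness supported,
  default 0.

What the generator does *not* emulate: item-level tests, non-normal
composite distributions (other than WMH), diagnosis strata, tau or
longitudinal amyloid, and real AIBL dependence between amyloid and
APOE/age. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## 5. Simulation experiments and problem sizes

The recovery experiment refits the full joint model on 50 independent
cohorts of n = 997 with all published standardized effects planted,
tabulating raw and standardized bias, empirical SD vs mean SE, and 95 % CI
coverage per structural parameter. The type-I calibration plants all
interactions at zero and Wald-tests the three-way slope term over 400
cohorts of n = 250 — the largest size that keeps the loop tractable. This
is still a small-sample regime for a 48-parameter model: ML variance
estimates run low by roughly p/(2n) ≈ 10 %, which inflates the Wald
rejection rate to about 2Φ(−1.96/1.1) ≈ 0.07–0.08 (at n ≈ 150 the
distortion is far worse, with outer-product and observed-information SEs
disagreeing by >15 %). At the study size n = 997 the same SEs match the
empirical sampling SD to about 1.5 % and coverage is nominal; the residual
reduced-n inflation is a property of the Wald test, not of the
implementation. The Monte-Carlo loops use 5 adaptive quadrature nodes: with
mode-and-curvature recentring the likelihood change from further node
refinement (~1e-6) is orders of magnitude below estimate noise, which the
refinement tests verify; one-off fits default to 15 nodes.

A note on coverage bands: with 50 replicates, a per-parameter binomial
count cannot distinguish 0.99 from 1.00 coverage, and a perfectly
calibrated interval lands on 50/50 for some of the 44 structural
parameters almost surely. The acceptance test therefore applies the
[0.88, 0.99] band to the *pooled* coverage across parameters and guards
each parameter at ≥ 0.80 (more than four binomial SDs below 0.95).

## 6. Known limitations

- Quadrature latents must be structurally exogenous with zero mean; models
  whose products cannot be linearized by conditioning on such latents are
  rejected at compile time. Adaptive recentring is implemented for one
  quadrature dimension (all models here need exactly one).
- Factor scores are defined for the linear part only; the joint
  interaction model is scored through the two-stage path.
- Standardization's product-moment rules assume latents in products are
  independent of the covariates; a warning is emitted otherwise.
- The four-way amyloid extension is implemented and tested structurally
  (predictor counts, fitting path), but its tiny published raw-scale
  coefficients (|β| ≤ 0.004) are not a recovery target at desk scale.
- p-values are two-sided normal on est/SE with no multiplicity adjustment,
  matching the reporting convention of the substantive tables.
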