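# rri — residual reserve index pipeline

`rri` implements, as a tested and reusable Python pipeline, a
cognitive-reserve analysis for longitudinal ageing cohorts: it decomposes an
episodic-memory composite into orthogonal brain, demographic and *residual
reserve* components under fixed measurement-error constraints, models
executive-function (EF) change with latent growth curves, and estimates
whether the protective effect of reserve against low brain integrity on EF
level and change differs by sex — a three-way latent interaction — with
full-information maximum likelihood (FIML) for missing longitudinal data.

It is aimed at biostatisticians and cognitive-ageing researchers who want
the full estimation chain — constrained SEM, latent-interaction
marginalization, fit indices, factor scores, simple-slopes probing — in one
place, with a synthetic-cohort generator that plants known truth so every
stage can be validated without access-controlled participant data.

## The model

**Stage 1 — memory decomposition.** Three ICV-adjusted brain volumes
(grey matter, hippocampus, white-matter hyperintensities) are single
indicators of latent brain factors with measurement error fixed at 0.10 on
the standardized scale. The memory composite is regressed (unit loadings)
on their freely weighted combination MEMB, on a demographic combination
MEMD (education plus methodological covariates: prior assessments, prior
interval, their product, withdrawn and deceased status), and on a residual
latent MEMR whose variance is free; the memory error variance is fixed at
0.1365 and cov(MEMR, MEMB) = cov(MEMR, MEMD) = cov(MEMB, MEMD) = 0. MEMR
is the *residual reserve index*. Sex is deliberately not residualized out.

**Stage 2 — EF growth.** EF composites at up to seven 18-month visits
(T = −3…+3 around the first MRI) load on a latent intercept (EF at the
first MRI) and slope; linear, quadratic and logarithmic bases are compared
with the full fit battery (χ², CFI, TLI, RMSEA + 90 % CI, SRMR, AIC, BIC,
aBIC) and the most parsimonious adequate form is selected.

**Stage 3 — moderation.** In one joint SEM, the EF intercept and slope are
regressed on MEMR, MEMB, MEMD, sex, APOE ε4 count, age (centred at 70),
sex×APOE, and all two- and three-way interactions up to MEMR×MEMB×sex
(optionally the four-way Centiloid extension). Latent products make the
marginal likelihood non-normal; the engine conditions on MEMR, under which
the model is linear Gaussian, and integrates with adaptive Gauss–Hermite
quadrature (mode-and-curvature recentring) — analytic gradients included.
Significant interactions are probed with simple slopes and model-predicted
trajectories over sex × brain × reserve cells.

## Worked example

```python
from rri.config import GeneratorConfig
from rri.synthetic import generate_cohort
from rri.decomposition import decompose
from rri.analytical import fit_analytical, test_threeway

cohort = generate_cohort(GeneratorConfig(seed=42))   # n = 997
dec = decompose(cohort)
print(dec.variance_table().round(3))

res = fit_analytical(cohort)
for t in test_threeway(res):
    print(f"{t.outcome}: std = {t.std:.3f}, p = {t.p:.4f}")
```

Output (seed 42):

```
  component  variance  share
0      MEMB     0.444  0.451
1      MEMD     0.129  0.131
2      MEMR     0.276  0.280
3     error     0.136  0.139
intercept: std = -0.183, p = 0.0000
slope: std = -0.044, p = 0.5974
```

The decomposition splits the (standardized) memory variance into the brain,
demographic, reserve and fixed-error components — the generator plants
shares 0.40 / 0.16 / 0.30 / 0.1365, and a single cohort of n = 997 recovers
them to sampling precision. The intercept moderation recovers the planted
standardized −0.190 and is clearly significant; the slope moderation
(planted −0.069) points the right way but is not significant in this single
draw — its standardized sampling error at n = 997 is of the same order as
the effect, which is exactly what the 50-replicate recovery experiment
quantifies.

The same stages are available from the command line
(`rri simulate | describe | decompose | growth | fit | probe | recover | run`);
`rri run --config config.yaml --out-dir results/` executes the whole chain
and renders a markdown report from the result bundle.

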