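"""Synthetic cohort generator with planted ground truth.

Generates cohorts with the exact statistical structure the analysis
assumes: three ICV-adjusted brain volumes as error-contaminated indicators
of latent brain integrity (10 % unreliability on the standardized scale), a
memory composite decomposed as MEMB + MEMD + MEMR plus fixed measurement
error (0.1365), executive-function trajectories driven by latent intercept
and slope with planted standardized structural effects (including the
three-way reserve x brain x sex moderation), and attrition linked to
cognitive level and change.

Planted standardized coefficients are converted to raw generator
coefficients through the closed-form population moments of the predictor
terms, so the truth is expressed on exactly the scale the estimator
reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, MONTHS_PER_VISIT, TIME_CODES
from .config import (AttritionConfig, ConfigError, GeneratorConfig,
                     PlantedTruth, MAIN_MODEL_BETAS, AMYLOID_MODEL_BETAS)
from .moments import Term, term_cov_matrix, term_means

DEMO_COLS = ("edu", "n_prior", "interval", "npa_x_interval")

# canonical structural terms, keyed by the labels used for planted betas
_TERM_DEFS: dict[str, Term] = {
    "MEMR": Term((1,), None, ()),
    "MEMB": Term((0,), "MEMB", ()),
    "MEMD": Term((0,), None, ("MEMD",)),
    "female": Term((0,), None, ("female",)),
    "apoe4": Term((0,), None, ("apoe4",)),
    "age_c": Term((0,), None, ("age_c",)),
    "centiloid": Term((0,), None, ("centiloid",)),
    "female_x_apoe4": Term((0,), None, ("female", "apoe4")),
    "MEMR_x_MEMB": Term((1,), "MEMB", ()),
    "MEMR_x_female": Term((1,), None, ("female",)),
    "MEMB_x_female": Term((0,), "MEMB", ("female",)),
    "MEMR_x_MEMB_x_female": Term((1,), "MEMB", ("female",)),
    "MEMR_x_centiloid": Term((1,), None, ("centiloid",)),
    "MEMB_x_centiloid": Term((0,), "MEMB", ("centiloid",)),
    "female_x_centiloid": Term((0,), None, ("female", "centiloid")),
    "centiloid_x_apoe4": Term((0,), None, ("centiloid", "apoe4")),
    "MEMR_x_MEMB_x_centiloid": Term((1,), "MEMB", ("centiloid",)),
    "MEMR_x_female_x_centiloid": Term((1,), None, ("female", "centiloid")),
    "MEMB_x_female_x_centiloid": Term((0,), "MEMB", ("female", "centiloid")),
    "female_x_centiloid_x_apoe4": Term((0,), None,
                                       ("female", "centiloid", "apoe4")),
    "MEMR_x_MEMB_x_female_x_centiloid": Term((1,), "MEMB",
                                             ("female", "centiloid")),
}


def structural_term(label: str) -> Term:
    try:
        return _TERM_DEFS[label]
    except KeyError:
        raise ConfigError(f"unknown structural predictor label {label!r}")


def canonical_order(labels) -> list[str]:
    """Published row order (main-effects table first, then amyloid rows)."""
    ordering = list(AMYLOID_MODEL_BETAS) + [k for k in MAIN_MODEL_BETAS
                                     if k not in AMYLOID_MODEL_BETAS]
    known = [k for k in (MAIN_MODEL_BETAS if set(labels) <= set(MAIN_MODEL_BETAS)
                         else ordering) if k in labels]
    extra = [k for k in labels if k not in known]
    return known + extra


# ---------------------------------------------------------------------------
# closed-form population moments
# ---------------------------------------------------------------------------

class PopulationExoMoments:
    """Raw population moments of products of exogenous predictor columns.

    Components are mutually independent except education (inside the MEMD
    composite) and sex; powers above 2 are not needed and not supported.
    """

    def __init__(self, cfg: GeneratorConfig, demo: "DemographicModel"):
        p = cfg.apoe_probs
        self.pf = cfg.prop_female
        self.m = {
            "female": (self.pf, self.pf),
            "apoe4": (p[1] + 2 * p[2], p[1] + 4 * p[2]),
            "age_c": (cfg.age_mean - 70.0,
                      (cfg.age_mean - 70.0) ** 2 + cfg.age_sd ** 2),
            "centiloid": (cfg.centiloid_mean,
                          cfg.centiloid_mean ** 2 + cfg.centiloid_sd ** 2),
            "MEMD": (0.0, cfg.planted.memd_var),
        }
        self.cov_memd_female = demo.cov_memd_female

    def __call__(self, cols: tuple[str, ...]) -> float:
        pow_: dict[str, int] = {}
        for c in cols:
            pow_[c] = pow_.get(c, 0) + 1
        out = 1.0
        d_pow = pow_.pop("MEMD", 0)
        f_pow = pow_.pop("female", 0)
        if d_pow == 1:
            if f_pow >= 1:
                out *= self.cov_memd_female  # E[D * F] (D zero-mean)
                f_pow = 0
            else:
                return 0.0
        elif d_pow == 2:
            if f_pow:
                raise NotImplementedError("MEMD^2 x sex moment not needed")
            out *= self.m["MEMD"][1]
        elif d_pow > 2:
            raise NotImplementedError("MEMD power > 2")
        if f_pow >= 1:
            out *= self.pf  # binary: F^k = F
        for c, k in pow_.items():
            if k == 1:
                out *= self.m[c][0]
            elif k == 2:
                out *= self.m[c][1]
            else:
                raise NotImplementedError(f"{c} power {k}")
        return out


class DemographicModel:
    """Joint model of the demographic/methodological covariates.

    Education is normal with sex-specific means; number of prior
    assessments is Poisson; the prior-assessment interval is 18 months per
    prior visit with a mean-one lognormal jitter; their product is the
    practice-exposure interaction.  MEMD is a fixed linear combination of
    the four standardized columns, scaled to the planted MEMD variance.
    """

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        pf = cfg.prop_female
        if cfg.edu_by_sex is not None:
            (mm, sm), (mf, sf) = cfg.edu_by_sex
        else:
            mm = mf = cfg.edu_mean
            sm = sf = cfg.edu_sd
        self.edu_params = (mm, sm, mf, sf)
        self.edu_mean = pf * mf + (1 - pf) * mm
        self.edu_var = (pf * sf ** 2 + (1 - pf) * sm ** 2
                        + pf * (1 - pf) * (mf - mm) ** 2)
        lam = cfg.n_prior_mean
        s = cfg.prior_interval_jitter_sd
        c = cfg.prior_interval_per_visit
        ej2 = math.exp(s ** 2)          # E[J^2] for mean-one lognormal J
        # Poisson raw moments
        m1 = lam
        m2 = lam + lam ** 2
        m3 = lam ** 3 + 3 * lam ** 2 + lam
        m4 = lam ** 4 + 6 * lam ** 3 + 7 * lam ** 2 + lam
        self.np_mean, self.np_var = m1, lam
        self.int_mean = c * m1
        self.int_var = c ** 2 * (m2 * ej2 - m1 ** 2)
        self.prod_mean = c * m2
        self.prod_var = c ** 2 * (m4 * ej2 - m2 ** 2)
        cov_np_int = c * (m2 - m1 * m1)
        cov_np_prod = c * (m3 - m1 * m2)
        cov_int_prod = c ** 2 * (m3 * ej2 - m1 * m2)
        sds = np.sqrt([self.edu_var, self.np_var, self.int_var, self.prod_var])
        self.sds = sds
        self.means = np.array([self.edu_mean, self.np_mean, self.int_mean,
                               self.prod_mean])
        S = np.diag(sds ** 2).astype(float)
        S[1, 2] = S[2, 1] = cov_np_int
        S[1, 3] = S[3, 1] = cov_np_prod
        S[2, 3] = S[3, 2] = cov_int_prod
        self.cov = S
        Sz = S / sds[:, None] / sds[None, :]
        dir_ = np.asarray(cfg.planted.demo_weight_dir, float)
        scale = math.sqrt(cfg.planted.memd_var / float(dir_ @ Sz @ dir_))
        self.delta = dir_ * scale            # weights on standardized columns
        self.cov_memd_female = (self.delta[0] * pf * (1 - pf) * (mf - mm)
                                / sds[0])

    def draw(self, rng: np.random.Generator, female: np.ndarray):
        cfg, n = self.cfg, female.size
        mm, sm, mf, sf = self.edu_params
        edu = np.where(female == 1, rng.normal(mf, sf, n),
                       rng.normal(mm, sm, n))
        n_prior = rng.poisson(cfg.n_prior_mean, n)
        s = cfg.prior_interval_jitter_sd
        jitter = np.exp(rng.normal(-0.5 * s ** 2, s, n))
        interval = cfg.prior_interval_per_visit * n_prior * jitter
        return edu, n_prior, interval

    def memd(self, edu, n_prior, interval) -> np.ndarray:
        cols = np.column_stack([
            edu, n_prior, interval, n_prior * interval])
        z = (cols - self.means) / self.sds
        return z @ self.delta


# ---------------------------------------------------------------------------
# standardized -> raw structural coefficients
# ---------------------------------------------------------------------------

@dataclass
class StructuralSolution:
    labels: list[str]
    terms: list[Term]
    cov_P: np.ndarray
    mean_P: np.ndarray
    sd_P: np.ndarray
    var_intercept: float
    var_slope: float
    raw_intercept: np.ndarray
    raw_slope: np.ndarray
    alpha_intercept: float
    alpha_slope: float


def solve_structural(cfg: GeneratorConfig,
                     demo: DemographicModel | None = None
                     ) -> StructuralSolution:
    """Convert planted standardized betas to raw generator coefficients.

    The outcome variance is the closed-form fixed point
    V = resid / (1 - beta' R beta) with R the population correlation matrix
    of the predictor terms.
    """
    planted = cfg.planted
    demo = demo or DemographicModel(cfg)
    exo = PopulationExoMoments(cfg, demo)
    labels = canonical_order(list(planted.structural_betas))
    terms = [structural_term(l) for l in labels]

    def rem_cov(a: str, b: str) -> float:
        if a == b == "MEMB":
            return planted.memb_var
        raise NotImplementedError((a, b))

    qvar = (planted.memr_var,)
    S = term_cov_matrix(terms, qvar, rem_cov, exo)
    mean_P = term_means(terms, exo)
    sd = np.sqrt(np.diag(S))
    R = S / sd[:, None] / sd[None, :]
    out = {}
    for name, resid, target_mean in (
            ("intercept", planted.intercept_resid_var, cfg.ef_intercept_mean),
            ("slope", planted.slope_resid_var, cfg.ef_slope_mean)):
        beta = np.array([planted.structural_betas[l][0 if name == "intercept"
                                                     else 1] for l in labels])
        q = float(beta @ R @ beta)
        if q >= 0.99:
            raise ConfigError(
                f"planted {name} betas imply explained variance {q:.3f} >= "
                "99%; no positive total variance exists")
        V = resid / (1.0 - q)
        raw = beta * math.sqrt(V) / sd
        alpha = target_mean - float(raw @ mean_P)
        out[name] = (V, raw, alpha)
    return StructuralSolution(
        labels=labels, terms=terms, cov_P=S, mean_P=mean_P, sd_P=sd,
        var_intercept=out["intercept"][0], var_slope=out["slope"][0],
        raw_intercept=out["intercept"][1], raw_slope=out["slope"][1],
        alpha_intercept=out["intercept"][2], alpha_slope=out["slope"][2],
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _term_columns(sol: StructuralSolution, memr, memb, cols: dict
                  ) -> np.ndarray:
    P = np.empty((memr.size, len(sol.terms)))
    for j, t in enumerate(sol.terms):
        v = np.ones_like(memr)
        if t.rpow[0]:
            v = v * memr ** t.rpow[0]
        if t.rem == "MEMB":
            v = v * memb
        for c in t.exo:
            v = v * cols[c]
        P[:, j] = v
    return P


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from the planted-truth model, then apply attrition."""
    config.validate()
    planted = config.planted
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    female = (rng.random(n) < config.prop_female).astype(int)
    apoe = rng.choice(3, size=n, p=np.asarray(config.apoe_probs, float))
    age = rng.normal(config.age_mean, config.age_sd, n)
    demo = DemographicModel(config)
    edu, n_prior, interval = demo.draw(rng, female)
    memd = demo.memd(edu, n_prior, interval)

    # brain true scores (variance = reliability) and standardized indicators
    rel = planted.brain_reliability
    Rb = np.eye(3)
    Rb[0, 1] = Rb[1, 0] = planted.brain_corr[0]
    Rb[0, 2] = Rb[2, 0] = planted.brain_corr[1]
    Rb[1, 2] = Rb[2, 1] = planted.brain_corr[2]
    Phi = rel * Rb
    eta = rng.multivariate_normal(np.zeros(3), Phi, size=n,
                                  method="cholesky")
    ind = eta + rng.normal(0.0, math.sqrt(1.0 - rel), (n, 3))
    dir_ = np.asarray(planted.brain_weight_dir, float)
    w = dir_ * math.sqrt(planted.memb_var / float(dir_ @ Phi @ dir_))
    memb = eta @ w

    shift = planted.memr_sex_shift
    pf = config.prop_female
    resid = planted.memr_var - shift ** 2 * pf * (1 - pf)
    if resid <= 0:
        raise ConfigError("memr_sex_shift implies negative residual "
                          "reserve variance")
    memr = shift * (female - pf) + rng.normal(0.0, math.sqrt(resid), n)

    mem_std = memb + memd + memr + rng.normal(
        0.0, math.sqrt(planted.mem_error_var), n)
    total_var = (planted.memb_var + planted.memd_var + planted.memr_var
                 + planted.mem_error_var)
    mem = config.mem_mean + config.mem_sd / math.sqrt(total_var) * mem_std

    centiloid = rng.normal(config.centiloid_mean, config.centiloid_sd, n)
    cl_out = centiloid.copy()
    if config.centiloid_missing_prob > 0:
        cl_out[rng.random(n) < config.centiloid_missing_prob] = np.nan

    sol = solve_structural(config, demo)
    cols = {
        "female": female.astype(float),
        "apoe4": apoe.astype(float),
        "age_c": age - 70.0,
        "centiloid": centiloid,
        "MEMD": memd,
    }
    P = _term_columns(sol, memr, memb, cols)
    resmat = np.array([
        [planted.intercept_resid_var, planted.slope_intercept_cov],
        [planted.slope_intercept_cov, planted.slope_resid_var]])
    zeta = rng.multivariate_normal(np.zeros(2), resmat, size=n,
                                   method="cholesky")
    icept = sol.alpha_intercept + P @ sol.raw_intercept + zeta[:, 0]
    slope = sol.alpha_slope + P @ sol.raw_slope + zeta[:, 1]

    tgrid = np.array(TIME_CODES, float)
    ef = icept[:, None] + slope[:, None] * tgrid[None, :] + rng.normal(
        0.0, math.sqrt(planted.ef_residual_var), (n, len(tgrid)))

    # raw-scale back-transform of the indicators
    gm = config.gm_mean + config.gm_sd * ind[:, 0]
    hippo = config.hippo_mean + config.hippo_sd * ind[:, 1]
    if config.wmh_lognormal:
        s2 = math.log(1.0 + (config.wmh_sd / config.wmh_mean) ** 2)
        mu = math.log(config.wmh_mean) - 0.5 * s2
        wmh = np.exp(mu + math.sqrt(s2) * ind[:, 2])
    else:
        wmh = config.wmh_mean + config.wmh_sd * ind[:, 2]

    ids = np.arange(1, n + 1)
    baseline = pd.DataFrame({
        "id": ids, "sex_female": female, "age_first_mri": age,
        "apoe4_count": apoe, "education_years": edu,
        "n_prior_assessments": n_prior, "prior_interval_months": interval,
        "withdrawn": 0, "deceased": 0,
        "gm_vol": gm, "hippo_vol": hippo, "wmh_vol": wmh,
        "mem_composite": mem, "centiloid": cl_out,
    })
    truth = pd.DataFrame({
        "id": ids, "memb": memb, "memd": memd, "memr": memr,
        "intercept": icept, "slope": slope,
    })

    # long visit table; enrolment truncation: only min(n_prior, 3)
    # pre-baseline assessments exist
    rows = []
    first_t = -np.minimum(n_prior, 3)
    for j, t in enumerate(TIME_CODES):
        keep = t >= first_t
        rows.append(pd.DataFrame({
            "id": ids[keep], "T": t,
            "months_from_first_mri": t * MONTHS_PER_VISIT,
            "ef": ef[keep, j],
        }))
    visits = pd.concat(rows, ignore_index=True)
    visits = visits.sort_values(["id", "T"]).reset_index(drop=True)

    cohort = Cohort(baseline=baseline, visits=visits, truth=truth)
    if config.attrition is not None:
        cohort = apply_attrition(cohort, config.attrition,
                                 seed=int(rng.integers(2 ** 31)))
    return cohort


def apply_attrition(cohort: Cohort, attrition: AttritionConfig,
                    seed: int) -> Cohort:
    """Monotone dropout after the first-MRI visit, linked to EF level/change.

    Deceased subjects (sex-dependent Bernoulli) stop at a uniformly drawn
    post-baseline visit; the remainder face a per-visit hazard scaled by
    exp(l_I * z(EF at T=0) + l_S * z(observed EF change per visit so far)).
    Because dropout depends only on *observed* values, the missingness is
    MAR given the modelled data and FIML remains consistent.  Withdrawn /
    deceased flags are set consistently; observations before the first MRI
    are never touched.
    """
    attrition.validate()
    rng = np.random.default_rng(seed)
    n = cohort.n
    base = cohort.baseline.copy()
    ids = base["id"].to_numpy()
    wide = cohort.visits.pivot(index="id", columns="T", values="ef")
    wide = wide.reindex(index=ids, columns=list(cohort.time_codes))
    ef = wide.to_numpy(float)
    t0_col = list(cohort.time_codes).index(0)

    def zscore(v):
        v = np.where(np.isfinite(v), v, 0.0)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    female = base["sex_female"].to_numpy()
    p_death = np.where(female == 1, attrition.death_prob,
                       attrition.death_prob * attrition.male_death_multiplier)
    deceased = rng.random(n) < p_death

    post_visits = [t for t in cohort.time_codes if t > 0]
    last_obs = np.full(n, cohort.time_codes[-1])
    if post_visits:
        zI = zscore(ef[:, t0_col])
        dropped = np.zeros(n, dtype=bool)
        last = np.full(n, cohort.time_codes[-1])
        for k, t in enumerate(post_visits):
            if k == 0:
                zS = np.zeros(n)
            else:
                prev_col = t0_col + k
                change = (ef[:, prev_col] - ef[:, t0_col]) / float(k)
                zS = zscore(change)
            hazard = np.clip(
                attrition.base_dropout_hazard
                * np.exp(attrition.hazard_load_intercept * zI
                         + attrition.hazard_load_slope * zS),
                0.0, 1.0)
            drop_now = (~dropped) & (rng.random(n) < hazard)
            last = np.where(drop_now, ([0] + post_visits)[k], last)
            dropped |= drop_now
        last_obs = last
        last_obs_dec = rng.integers(0, len(post_visits), n)
        last_obs = np.where(deceased, np.minimum(last_obs, last_obs_dec),
                            last_obs)
    withdrawn = (~deceased) & (last_obs < cohort.time_codes[-1])
    base["withdrawn"] = withdrawn.astype(int)
    base["deceased"] = deceased.astype(int)

    cut = pd.Series(last_obs, index=ids)
    visits = cohort.visits.copy()
    keep = visits["T"] <= cut.loc[visits["id"]].to_numpy()
    visits = visits[keep].reset_index(drop=True)

    if attrition.intermittent_prob > 0:
        nonbase = visits["T"] != 0
        zap = nonbase & (rng.random(len(visits)) < attrition.intermittent_prob)
        visits = visits[~zap].reset_index(drop=True)

    truth = None if cohort.truth is None else cohort.truth.copy()
    return Cohort(baseline=base, visits=visits, truth=truth,
                  time_codes=cohort.time_codes)


def truth_report(config: GeneratorConfig) -> pd.DataFrame:
    """Planted standardized effects, in published row order."""
    betas = config.planted.structural_betas
    labels = canonical_order(list(betas))
    return pd.DataFrame({
        "term": labels,
        "intercept": [betas[l][0] for l in labels],
        "slope": [betas[l][1] for l in labels],
    })


def ols_recovery(cohort: Cohort, config: GeneratorConfig) -> pd.DataFrame:
    """Standardized OLS estimates on the noise-free true latents.

    Independent oracle for the generator: regress the true intercept/slope
    on the true predictor columns and re-standardize with sample SDs.
    """
    if cohort.truth is None:
        raise ValueError("cohort carries no planted truth")
    sol = solve_structural(config)
    base = cohort.baseline
    truth = cohort.truth
    cols = {
        "female": base["sex_female"].to_numpy(float),
        "apoe4": base["apoe4_count"].to_numpy(float),
        "age_c": base["age_first_mri"].to_numpy(float) - 70.0,
        "centiloid": base["centiloid"].to_numpy(float),
        "MEMD": truth["memd"].to_numpy(),
    }
    P = _term_columns(sol, truth["memr"].to_numpy(),
                      truth["memb"].to_numpy(), cols)
    X = np.column_stack([np.ones(len(P)), P])
    out = {"term": sol.labels}
    for name, y in (("intercept", truth["intercept"].to_numpy()),
                    ("slope", truth["slope"].to_numpy())):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[name] = coef[1:] * P.std(axis=0, ddof=0) / y.std(ddof=0)
    return pd.DataFrame(out)
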