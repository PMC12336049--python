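"""Stage 3: the joint moderation model.

Single SEM combining the memory decomposition, the linear EF growth model,
and structural regressions of the EF intercept and slope on MEMR, MEMB,
MEMD, sex, APOE e4 count, centred age, and all published interaction
terms, up to MEMR x MEMB x sex (and the four-way Centiloid extension).
The latent products make the marginal likelihood non-normal; estimation
marginalizes over MEMR with adaptive Gauss-Hermite quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, TIME_CODES, ef_column
from .config import AnalysisConfig, MAIN_MODEL_BETAS, AMYLOID_MODEL_BETAS
from .decomposition import (DEFAULT_COVARIATES, DecompositionResult,
                            build_decomposition_spec, decompose,
                            prepare_decomposition_frame)
from .growth import build_growth_spec, growth_dataset
from .sem import (Dataset, FitOptions, FitResult, ModelSpec, compile_spec,
                  fit_ml)
from .sem.scores import factor_scores
from .sem.standardize import standardize
from .synthetic import _TERM_DEFS, canonical_order

OUTCOMES = ("I", "slope")


class AnalyticalError(ValueError):
    pass


def term_predictor(label: str):
    """Spec predictor (name or tuple) for a canonical term label."""
    t = _TERM_DEFS[label]
    parts: list[str] = []
    if t.rpow[0]:
        parts.extend(["MEMR"] * t.rpow[0])
    if t.rem is not None:
        parts.append(t.rem)
    parts.extend(t.exo)
    return parts[0] if len(parts) == 1 else tuple(parts)


def structural_labels(include_amyloid: bool) -> list[str]:
    base = AMYLOID_MODEL_BETAS if include_amyloid else MAIN_MODEL_BETAS
    return canonical_order(list(base))


def build_analytical_spec(include_amyloid: bool = False, *,
                          covariates=DEFAULT_COVARIATES,
                          equal_residuals: bool = True,
                          time_unit: str = "visit") -> ModelSpec:
    """Joint decomposition + growth + structural moderation model."""
    covariates = list(covariates)
    spec = build_decomposition_spec(covariates)
    exo_extra = ["female", "apoe4", "age_c"]
    if include_amyloid:
        exo_extra.append("centiloid")
    for name in exo_extra:
        spec.exogenous.append(name)
    growth = build_growth_spec("linear", equal_residuals=equal_residuals,
                               unit=time_unit)
    spec.observed.extend(growth.observed)
    spec.latents.extend(growth.latents)
    for p in growth.params:
        spec.params.append(p)
    labels = structural_labels(include_amyloid)
    for outcome in OUTCOMES:
        for lab in labels:
            spec.add_regression(outcome, term_predictor(lab),
                                value=0.0, label=f"{outcome}:{lab}")
    return spec


@dataclass
class AnalyticalResult:
    """Joint fit plus reporting helpers."""

    fit: FitResult
    include_amyloid: bool
    labels: list[str]
    std_table: pd.DataFrame
    decomposition: DecompositionResult | None = None
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    # -------------------------------------------------------------- helpers
    def _std_lookup(self) -> dict[str, tuple[float, float]]:
        return {r.label: (r.std, r.std_se)
                for r in self.std_table.itertuples()}

    def coefficient_table(self) -> pd.DataFrame:
        """est, SE, est/SE, p (raw and standardized) in published layout."""
        std = self._std_lookup()
        est = self.fit.estimates_dict()
        rows = []
        for outcome, block in (("I", "intercept"), ("slope", "slope")):
            for lab in self.labels:
                key = f"{outcome}:{lab}"
                idx = self.fit.labels.index(key)
                se = float(self.fit.se[idx])
                raw = est[key]
                z = raw / se if se > 0 else np.nan
                s, s_se = std.get(key, (np.nan, np.nan))
                rows.append({
                    "outcome": block, "term": lab, "est": raw, "se": se,
                    "est_se": z,
                    "p": float(2 * _norm_sf(abs(z))) if np.isfinite(z)
                    else np.nan,
                    "std": s, "std_se": s_se,
                })
        return pd.DataFrame(rows)

    @property
    def memb_sd(self) -> float:
        est = self.fit.estimates_dict()
        w = np.array([est[f"w_b_{k}"] for k in ("gm", "hippo", "wmh")])
        Phi = np.zeros((3, 3))
        names = ("b_gm", "b_hippo", "b_wmh")
        for i, a in enumerate(names):
            Phi[i, i] = est[f"phi_{a}"]
            for j, b in enumerate(names[:i]):
                Phi[i, j] = Phi[j, i] = est[f"phi_{b}_{a}"]
        return float(np.sqrt(w @ Phi @ w))

    @property
    def memr_sd(self) -> float:
        return float(np.sqrt(self.fit["psi_memr"]))


def _norm_sf(x):
    from scipy.stats import norm

    return norm.sf(x)


def prepare_analytical_frame(cohort: Cohort, *,
                             include_amyloid: bool = False,
                             covariates=DEFAULT_COVARIATES,
                             age_center: float = 70.0):
    frame, standardizers = prepare_decomposition_frame(cohort, covariates)
    b = cohort.baseline
    frame["female"] = b["sex_female"].to_numpy(float)
    frame["apoe4"] = b["apoe4_count"].to_numpy(float)
    frame["age_c"] = b["age_first_mri"].to_numpy(float) - age_center
    if include_amyloid:
        frame["centiloid"] = b["centiloid"].to_numpy(float)
    wide = cohort.ef_wide().set_index("id")
    for t in TIME_CODES:
        frame[ef_column(t)] = frame["id"].map(wide[ef_column(t)])
    if include_amyloid:
        miss = ~np.isfinite(frame["centiloid"])
        if miss.any():
            warnings.warn(f"dropping {int(miss.sum())} subjects without a "
                          "Centiloid value for the amyloid model")
            frame = frame.loc[~miss].reset_index(drop=True)
    return frame, standardizers


def two_stage_starts(cohort: Cohort, *, include_amyloid: bool = False,
                     covariates=DEFAULT_COVARIATES,
                     options: FitOptions | None = None) -> tuple[dict, "DecompositionResult"]:
    """Starting values from the two-stage factor-score path.

    Decomposition and growth are fitted separately; the growth factors'
    Bartlett scores are regressed on the decomposition scores and
    covariates by OLS.  The attenuated structural estimates make good
    (reproducible) starting values for the joint fit, and serve as the
    known-attenuation cross-check.
    """
    opts = options or FitOptions()
    dec = decompose(cohort, covariates=covariates, options=opts)
    start = dec.fit.estimates_dict()
    gdata = growth_dataset(cohort)
    from .growth import growth_starts

    gfit = fit_ml(build_growth_spec("linear"), gdata,
                  start=growth_starts(gdata), options=opts)
    start.update({k: v for k, v in gfit.estimates_dict().items()})
    gscores = factor_scores(gfit.model, gfit.theta_internal, gfit.data,
                            method="bartlett")
    frame, _ = prepare_analytical_frame(cohort,
                                        include_amyloid=include_amyloid,
                                        covariates=covariates)
    labels = structural_labels(include_amyloid)
    cols = {
        "MEMR": dec.scores["memr"].to_numpy(),
        "MEMB": dec.scores["memb"].to_numpy(),
        "MEMD": dec.scores["memd"].to_numpy(),
        "female": frame["female"].to_numpy(),
        "apoe4": frame["apoe4"].to_numpy(),
        "age_c": frame["age_c"].to_numpy(),
    }
    if include_amyloid:
        cols["centiloid"] = frame["centiloid"].to_numpy()

    def term_col(lab: str) -> np.ndarray:
        t = _TERM_DEFS[lab]
        v = np.ones(len(frame))
        if t.rpow[0]:
            v = v * cols["MEMR"] ** t.rpow[0]
        if t.rem is not None:
            v = v * cols[t.rem]
        for c in t.exo:
            v = v * cols[c]
        return v

    X = np.column_stack([np.ones(len(frame))]
                        + [term_col(l) for l in labels])
    resid_var = {}
    for outcome in ("I", "slope"):
        y = gscores[outcome].to_numpy()
        ok = np.isfinite(y)
        coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        start[f"mean_{outcome}"] = float(coef[0])
        for j, lab in enumerate(labels):
            start[f"{outcome}:{lab}"] = float(coef[1 + j])
        resid_var[outcome] = float(np.var(y[ok] - X[ok] @ coef))
    # factor-score noise inflates the OLS residual; shrink toward the
    # structural residual as a starting value
    start["psi_I"] = max(0.8 * resid_var["I"], 1e-3)
    start["psi_slope"] = max(0.6 * resid_var["slope"], 1e-5)
    start["psi_I_slope"] = 0.0
    return start, dec


def fit_analytical(cohort: Cohort, *, include_amyloid: bool = False,
                   config: AnalysisConfig | None = None,
                   covariates=DEFAULT_COVARIATES,
                   start: dict | None = None,
                   use_two_stage_start: bool = True,
                   compute_se: bool = True,
                   se_method: str = "observed") -> AnalyticalResult:
    """Fit the joint moderation model by FIML with latent interactions."""
    config = config or AnalysisConfig()
    config.validate()
    spec = build_analytical_spec(include_amyloid, covariates=covariates,
                                 time_unit=config.time_unit)
    model = compile_spec(spec)
    frame, _ = prepare_analytical_frame(
        cohort, include_amyloid=include_amyloid, covariates=covariates,
        age_center=config.age_center)
    data = Dataset.from_frame(frame, model.obs, model.exo, id_col="id")

    sexes = np.unique(data.X[:, model.exo.index("female")])
    if len(sexes) < 2:
        raise AnalyticalError(
            "single-sex cohort: sex main effect and every sex-involved "
            "interaction are aliased with the intercept/structural terms")

    opts = FitOptions(n_nodes=config.quadrature_nodes,
                      adaptive=config.adaptive_quadrature,
                      gtol=config.gtol, ll_rtol=config.ll_rtol,
                      compute_se=compute_se, se_method=se_method,
                      seed=config.seed)
    dec = None
    starts: dict = {}
    if use_two_stage_start:
        stage_opts = FitOptions(compute_se=False, seed=config.seed)
        starts, dec = two_stage_starts(cohort,
                                       include_amyloid=include_amyloid,
                                       covariates=covariates,
                                       options=stage_opts)
    if start:
        starts.update(start)
    starts = {k: v for k, v in starts.items() if k in model.labels}
    fit = fit_ml(model, data, start=starts, options=opts)
    std_table = standardize(fit, std_binary=config.std_binary)
    return AnalyticalResult(fit=fit, include_amyloid=include_amyloid,
                            labels=structural_labels(include_amyloid),
                            std_table=std_table, decomposition=dec,
                            config=config)


# ---------------------------------------------------------------------------
# hypothesis tests, probing, prediction
# ---------------------------------------------------------------------------

@dataclass
class InteractionTest:
    term: str
    outcome: str
    est: float
    se: float
    std: float
    std_se: float
    z: float
    p: float


def _extract_test(result: AnalyticalResult, lab: str) -> list[InteractionTest]:
    std = result._std_lookup()
    out = []
    for outcome, block in (("I", "intercept"), ("slope", "slope")):
        key = f"{outcome}:{lab}"
        if key not in result.fit.labels:
            raise AnalyticalError(f"term {lab!r} not in the fitted model")
        idx = result.fit.labels.index(key)
        est = float(result.fit.estimates[idx])
        se = float(result.fit.se[idx])
        z = est / se if se > 0 else np.nan
        s, s_se = std.get(key, (np.nan, np.nan))
        out.append(InteractionTest(
            term=lab, outcome=block, est=est, se=se, std=s, std_se=s_se,
            z=z, p=float(2 * _norm_sf(abs(z))) if np.isfinite(z) else np.nan))
    return out


def test_threeway(result: AnalyticalResult) -> list[InteractionTest]:
    """The MEMR x MEMB x sex moderation of EF intercept and slope."""
    return _extract_test(result, "MEMR_x_MEMB_x_female")


def test_fourway(result: AnalyticalResult) -> list[InteractionTest]:
    """The MEMR x MEMB x sex x amyloid term (amyloid model only)."""
    if not result.include_amyloid:
        raise AnalyticalError("four-way term requires the amyloid model")
    return _extract_test(result, "MEMR_x_MEMB_x_female_x_centiloid")


def simple_slopes(result: AnalyticalResult,
                  memb_levels=(-1.0, 0.0, 1.0),
                  sexes=(0.0, 1.0),
                  outcomes=OUTCOMES) -> pd.DataFrame:
    """Conditional effect of MEMR at each MEMB level (in SD units) by sex.

    slope(m, f) = b_R + b_RM * m*sd_B + b_RF * f + b_RMF * m*sd_B * f,
    with delta-method standard errors from the joint parameter covariance
    (implied SDs treated as fixed).
    """
    fit = result.fit
    sd_b = result.memb_sd
    rows = []
    for outcome in outcomes:
        keys = [f"{outcome}:{k}" for k in
                ("MEMR", "MEMR_x_MEMB", "MEMR_x_female",
                 "MEMR_x_MEMB_x_female")]
        idx = [fit.labels.index(k) for k in keys]
        b = fit.estimates[idx]
        V = fit.vcov[np.ix_(idx, idx)] if fit.vcov is not None else None
        for m in memb_levels:
            for f in sexes:
                g = np.array([1.0, m * sd_b, f, m * sd_b * f])
                val = float(g @ b)
                se = float(np.sqrt(g @ V @ g)) if V is not None else np.nan
                rows.append({
                    "outcome": "intercept" if outcome == "I" else "slope",
                    "memb_level": m, "female": f,
                    "simple_slope": val, "se": se,
                    "z": val / se if se and se > 0 else np.nan,
                })
    return pd.DataFrame(rows)


DEFAULT_REFERENCE = {
    "age_c": 0.0,        # 70-year-old
    "apoe4": 0.0,        # APOE e4 negative
    "MEMD": 0.0,         # average demographic standing
    "centiloid": 0.0,
}


def predict_trajectories(result: AnalyticalResult,
                         memb_levels=(-1.0, 0.0, 1.0),
                         memr_levels=(-1.0, 0.0, 1.0),
                         sexes=(0.0, 1.0),
                         reference: dict | None = None,
                         time_codes=TIME_CODES) -> pd.DataFrame:
    """Model-predicted EF trajectories over sex x MEMB x MEMR cells.

    Levels are in SD units of the implied latent distributions; the
    reference profile fixes the remaining covariates (70 years old, no e4
    allele, average demographic standing).
    """
    ref = dict(DEFAULT_REFERENCE)
    ref.update(reference or {})
    fit = result.fit
    est = fit.estimates_dict()
    sd_b, sd_r = result.memb_sd, result.memr_sd
    rows = []
    terms = result.labels
    for f in sexes:
        for mb in memb_levels:
            for mr in memr_levels:
                vals = {
                    "MEMR": mr * sd_r, "MEMB": mb * sd_b,
                    "MEMD": ref["MEMD"], "female": f,
                    "apoe4": ref["apoe4"], "age_c": ref["age_c"],
                    "centiloid": ref["centiloid"],
                }
                pred = {}
                for outcome, alpha_key in (("I", "mean_I"),
                                           ("slope", "mean_slope")):
                    total = est[alpha_key]
                    for lab in terms:
                        t = _TERM_DEFS[lab]
                        v = 1.0
                        if t.rpow[0]:
                            v *= vals["MEMR"] ** t.rpow[0]
                        if t.rem is not None:
                            v *= vals[t.rem]
                        for c in t.exo:
                            v *= vals[c]
                        total += est[f"{outcome}:{lab}"] * v
                    pred[outcome] = total
                for t_code in time_codes:
                    rows.append({
                        "female": f, "memb_level": mb, "memr_level": mr,
                        "T": t_code,
                        "predicted_ef": pred["I"] + pred["slope"] * t_code,
                    })
    return pd.DataFrame(rows)
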