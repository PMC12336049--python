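"""Stage 2: latent growth curves of executive function over seven visits.

EF at visit offsets T = -3..+3 (18-month spacing, T = 0 at the first MRI)
loads on a latent intercept (basis all ones, "expected EF at the first
MRI") and growth terms whose bases are fixed functions of T.  The time
unit is one 18-month visit interval by default; month coding rescales the
bases by 18.  Linear, quadratic and logarithmic forms are compared on
identical cases with the full fit battery, selecting the most parsimonious
adequate form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, TIME_CODES, ef_column
from .config import AnalysisConfig
from .indices import FitStats, fit_battery
from .sem import Dataset, FitOptions, FitResult, ModelSpec, fit_ml

GROWTH_FORMS = ("linear", "quadratic", "logarithmic")


class GrowthError(ValueError):
    pass


def time_basis(form: str, t: np.ndarray, *, unit: str = "visit"
               ) -> dict[str, np.ndarray]:
    """Fixed loading bases per growth factor; basis(0) = 0 for all slopes.

    The logarithmic basis is sign(T) * ln(1 + |T|) / ln 2, an odd monotone
    curve equal to the linear basis at T = +-1, defined for the
    pre-baseline visits where a plain ln(T) would not be.
    """
    t = np.asarray(t, float)
    scale = 18.0 if unit == "month" else 1.0
    if form == "linear":
        out = {"slope": t * scale}
    elif form == "quadratic":
        out = {"slope": t * scale, "quad": (t * scale) ** 2}
    elif form == "logarithmic":
        out = {"slope": np.sign(t) * np.log1p(np.abs(t)) / np.log(2.0)
               * scale}
    else:
        raise GrowthError(f"unknown growth form {form!r}")
    return out


def build_growth_spec(form: str = "linear", *,
                      equal_residuals: bool = True,
                      unit: str = "visit",
                      time_codes=TIME_CODES) -> ModelSpec:
    t = np.asarray(time_codes, float)
    bases = time_basis(form, t, unit=unit)
    cols = [ef_column(int(x)) for x in time_codes]
    factors = ["I"] + list(bases)
    spec = ModelSpec(observed=cols, latents=factors)
    for j, c in enumerate(cols):
        spec.add_loading(c, "I", free=False, value=1.0)
        for f, basis in bases.items():
            spec.add_loading(c, f, free=False, value=float(basis[j]))
        spec.add_intercept(c, free=False, value=0.0)
        spec.add_variance(c, value=0.1,
                          label="theta_ef" if equal_residuals
                          else f"theta_{c}")
    for i, f in enumerate(factors):
        spec.add_intercept(f, value=0.0, label=f"mean_{f}")
        spec.add_variance(f, value=0.25 if f == "I" else 0.01,
                          label=f"psi_{f}")
        for g in factors[:i]:
            spec.add_covariance(f, g, value=0.0, label=f"psi_{g}_{f}")
    return spec


def growth_starts(data, form: str = "linear", *, unit: str = "visit",
                  time_codes=TIME_CODES) -> dict[str, float]:
    """Starting values from casewise OLS of EF on the time bases.

    Per-subject regressions give crude intercept/slope estimates whose
    means and (shrunken) variances start the latent parameters in the
    right basin; the joint likelihood surface has stationary points with
    collapsed slope variance that default starts can fall into.
    """
    t = np.asarray(time_codes, float)
    bases = time_basis(form, t, unit=unit)
    X_full = np.column_stack([np.ones_like(t)] + list(bases.values()))
    cols = [ef_column(int(x)) for x in time_codes]
    Y = data.Y if hasattr(data, "Y") else np.asarray(data[cols], float)
    coefs, resid = [], []
    for row in Y:
        ok = np.isfinite(row)
        if ok.sum() <= X_full.shape[1]:
            continue
        beta, res, *_ = np.linalg.lstsq(X_full[ok], row[ok], rcond=None)
        coefs.append(beta)
        dof = ok.sum() - X_full.shape[1]
        if len(res) and dof > 0:
            resid.append(res[0] / dof)
    C = np.array(coefs)
    start: dict[str, float] = {}
    names = ["I"] + list(bases)
    theta = float(np.mean(resid)) if resid else 0.1
    start["theta_ef"] = max(theta, 1e-3)
    for j, name in enumerate(names):
        start[f"mean_{name}"] = float(C[:, j].mean())
        shrink = 0.8 if name == "I" else 0.5
        start[f"psi_{name}"] = max(shrink * float(C[:, j].var()), 1e-4)
    for i, f in enumerate(names):
        for j, g in enumerate(names[:i]):
            start[f"psi_{g}_{f}"] = 0.5 * float(
                np.cov(C[:, i], C[:, j])[0, 1])
    return start


@dataclass
class GrowthComparison:
    table: pd.DataFrame          # one row per form: fit battery + ICs
    fits: dict[str, FitResult]
    stats: dict[str, FitStats]
    selected: str
    rationale: str


def growth_dataset(cohort: Cohort, time_codes=TIME_CODES) -> Dataset:
    wide = cohort.ef_wide()
    cols = [ef_column(t) for t in time_codes]
    return Dataset.from_frame(wide, cols, [], id_col="id")


def _adequate(fs: FitStats) -> bool:
    # conventional cutoffs: CFI >= .95, RMSEA <= .06, SRMR <= .08
    return fs.cfi >= 0.95 and fs.rmsea <= 0.06 and fs.srmr <= 0.08


def compare_growth_forms(cohort: Cohort, forms=GROWTH_FORMS, *,
                         config: AnalysisConfig | None = None,
                         options: FitOptions | None = None
                         ) -> GrowthComparison:
    """Fit each growth form on identical cases and rank them.

    Selection rule: if every converged form fits adequately, the one with
    the fewest parameters wins (parsimony); otherwise the lowest BIC.
    Non-converged forms are excluded with a flag in the table.
    """
    forms = list(forms)
    if len(forms) < 1:
        raise GrowthError("no growth forms requested")
    config = config or AnalysisConfig()
    data = growth_dataset(cohort)
    fits: dict[str, FitResult] = {}
    stats: dict[str, FitStats] = {}
    rows = []
    for form in forms:
        spec = build_growth_spec(form, unit=config.time_unit)
        fit = fit_ml(spec, data, start=growth_starts(data, form,
                                                     unit=config.time_unit),
                     options=options or FitOptions())
        fits[form] = fit
        row = {"form": form, "converged": fit.converged,
               "n_params": fit.n_params, "loglik": fit.loglik}
        if fit.converged:
            fs = fit_battery(fit, rmsea_n_convention=config.rmsea_n_convention)
            stats[form] = fs
            row.update(fs.row())
        rows.append(row)
    table = pd.DataFrame(rows)
    usable = [f for f in forms if fits[f].converged]
    if not usable:
        raise GrowthError("no growth form converged")
    if all(_adequate(stats[f]) for f in usable):
        selected = min(usable, key=lambda f: fits[f].n_params)
        rationale = ("all converged forms fit adequately; selected "
                     f"{selected!r} for parsimony (fewest parameters)")
    else:
        selected = min(usable, key=lambda f: stats[f].bic)
        rationale = f"selected {selected!r} by lowest BIC"
    return GrowthComparison(table=table, fits=fits, stats=stats,
                            selected=selected, rationale=rationale)
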