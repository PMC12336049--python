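"""Standardized estimates from model-implied moments.

Each path coefficient is multiplied by SD(predictor)/SD(outcome), with all
variances model-implied: latent variances propagate through the structural
equations, product-term variances follow the moment rules of
:mod:`rri.moments` (quadrature latents independent of everything else;
remaining latents in products zero-mean normal and independent of the
covariates), and covariate moments come from the sample.  Binary
covariates are standardized by their sample SD by default (the STDYX
convention); ``std_binary="stdy"`` leaves them on the raw scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..moments import SampleExoMoments, Term, term_cov
from .compile import CompiledModel
from .fitting import FitResult
from .likelihood import Evaluator


class StandardizationError(ValueError):
    pass


def _ext_columns(model: CompiledModel, X: np.ndarray) -> dict[str, np.ndarray]:
    cols = {name: X[:, j] for j, name in enumerate(model.exo)}
    return cols


def implied_variances(fit: FitResult):
    """Total (product-inclusive) latent covariance and observed variances.

    Returns (V_lat, var_obs, helpers) where helpers carries the pieces the
    standardizer needs (exo moments, term machinery, assembled matrices).
    """
    model, data = fit.model, fit.data
    ev = Evaluator(model, data)
    nat = fit.estimates
    A = ev._assemble(nat)
    m, d, p = len(model.rlat), model.d, len(model.obs)
    F = np.linalg.inv(np.eye(m) - A.B0)
    psiQ = np.asarray(A.psiQ, float)

    cols = _ext_columns(model, data.X)
    exo_m = SampleExoMoments(cols) if cols else (lambda c: 1.0)

    # effective exogenous effect matrix, with derived product columns
    gam_cols: list[np.ndarray] = []
    Gam_ext = [A.Gam]
    for pl, v in A.dyn_a:
        if any(pl.rexp) or len(pl.exo) < 2:
            continue
        col = np.ones(data.n)
        for c in pl.exo:
            col = col * data.X[:, c]
        extra = np.zeros((m, 1))
        extra[pl.i, 0] = v
        Gam_ext.append(extra)
        gam_cols.append(col)
    Gam_ext = np.hstack(Gam_ext)
    Xext = np.hstack([data.X] + [c[:, None] for c in gam_cols]) \
        if gam_cols else data.X
    if Xext.shape[1]:
        xm = Xext.mean(axis=0)
        Sx = (Xext - xm).T @ (Xext - xm) / data.n
    else:
        Sx = np.zeros((0, 0))

    V_lin = F @ (A.Psi + Gam_ext @ Sx @ Gam_ext.T
                 + A.BQ @ np.diag(psiQ) @ A.BQ.T) @ F.T
    C_lq = F @ A.BQ @ np.diag(psiQ)                    # cov(eta, q)
    C_lx = F @ Gam_ext @ Sx                            # cov(eta, x_ext)

    # product terms: placements with a node power or a B-slot exo multiplier
    terms: list[tuple[float, int, Term]] = []
    for pl, v in list(A.dyn_B) + list(A.dyn_a):
        if pl.slot != "B" and not any(pl.rexp) and len(pl.exo) >= 2:
            continue  # pure covariate product, already in Gam_ext
        if pl.slot != "B" and sum(pl.rexp) == 1 and not pl.exo:
            continue  # linear quadrature-latent effect, already in BQ
        rem = model.rlat[pl.j] if pl.slot == "B" else None
        exo_names = tuple(model.exo[c] for c in pl.exo)
        terms.append((v, pl.i, Term(tuple(pl.rexp), rem, exo_names)))

    def rem_cov(a: str, b: str) -> float:
        ia, ib = model.rlat.index(a), model.rlat.index(b)
        return float(V_lin[ia, ib])

    for _, _, t in terms:
        if t.rem is not None:
            ia = model.rlat.index(t.rem)
            if np.abs(C_lx[ia]).max() > 1e-8 * max(1.0, np.abs(V_lin).max()):
                warnings.warn(
                    f"latent {t.rem!r} in a product term depends on "
                    "covariates; product-moment rules are approximate")

    V_prod = np.zeros((m, m))
    Cq_prod = np.zeros((m, d))
    for c1, g1, t1 in terms:
        for c2, g2, t2 in terms:
            cv = term_cov(t1, t2, psiQ, rem_cov, exo_m)
            V_prod += c1 * c2 * cv * np.outer(F[:, g1], F[:, g2])
        # cross with linear latent parts
        ez = exo_m(t1.exo) if t1.exo else 1.0
        if sum(t1.rpow) == 1 and t1.rem is None:
            q = t1.rpow.index(1)
            cross = psiQ[q] * (F @ A.BQ)[:, q] * ez
            Cq_prod[:, q] += c1 * F[:, g1] * psiQ[q] * ez
        elif sum(t1.rpow) == 0 and t1.rem is not None:
            il = model.rlat.index(t1.rem)
            cross = V_lin[il, :] * ez
        else:
            cross = np.zeros(m)
        V_prod += c1 * (np.outer(F[:, g1], cross)
                        + np.outer(cross, F[:, g1]))
    V_lat = V_lin + V_prod
    C_lq = C_lq + Cq_prod

    # observed variances
    var_obs = np.zeros(p)
    for rix in range(p):
        lam = A.Lam[rix]
        lamq = A.LamQ[rix] if d else np.zeros(0)
        k = A.K[rix]
        v = float(lam @ V_lat @ lam)
        if d:
            v += 2.0 * float(lam @ C_lq @ lamq) + float(lamq ** 2 @ psiQ)
        if data.X.shape[1]:
            Sxx = Sx[:data.X.shape[1], :data.X.shape[1]]
            v += float(k @ Sxx @ k)
            v += 2.0 * float(lam @ C_lx[:, :data.X.shape[1]] @ k)
        v += float(A.Theta[rix, rix])
        var_obs[rix] = v

    helpers = dict(A=A, F=F, exo_m=exo_m, rem_cov=rem_cov, psiQ=psiQ,
                   cols=cols, Sx=Sx)
    return V_lat, var_obs, helpers


def standardize(fit: FitResult, *, std_binary: str = "stdyx") -> pd.DataFrame:
    """Standardized estimate for every free parameter of a fit.

    Path coefficients are rescaled by implied SDs; variances become
    variance fractions of their variable's total variance; covariances
    become correlations.  The ``std_se`` column scales the raw SE by the
    same factor, so est/SE is preserved.
    """
    model = fit.model
    V_lat, var_obs, h = implied_variances(fit)
    A, psiQ, exo_m = h["A"], h["psiQ"], h["exo_m"]
    if (np.diag(V_lat) < -1e-10).any() or (var_obs < 0).any():
        raise StandardizationError("negative implied variance")

    def sd_lat(name: str) -> float:
        if name in model.qlat:
            return float(np.sqrt(psiQ[model.qlat.index(name)]))
        v = V_lat[model.rlat.index(name), model.rlat.index(name)]
        if v <= 0:
            raise StandardizationError(
                f"latent {name!r} has zero implied variance")
        return float(np.sqrt(v))

    def sd_obs(i: int) -> float:
        if var_obs[i] <= 0:
            raise StandardizationError(
                f"observed {model.obs[i]!r} has zero implied variance")
        return float(np.sqrt(var_obs[i]))

    def sd_exo(j: int) -> float:
        col = fit.data.X[:, j]
        if std_binary == "stdy" and set(np.unique(col)) <= {0.0, 1.0}:
            return 1.0
        sd = col.std()
        if sd == 0:
            raise StandardizationError(
                f"covariate {model.exo[j]!r} is constant")
        return float(sd)

    rows = []
    seen = set()
    for pl in model.placements:
        if pl.pidx is None or pl.pidx in seen:
            continue
        seen.add(pl.pidx)
        lab = model.labels[pl.pidx]
        raw = float(fit.estimates[pl.pidx])
        se_raw = float(fit.se[pl.pidx]) if np.isfinite(fit.se[pl.pidx]) \
            else np.nan
        slot = pl.slot
        factor: float | None = None
        if slot == "lambda":
            factor = sd_lat(model.rlat[pl.j]) / sd_obs(pl.i)
        elif slot == "lambdaQ":
            factor = sd_lat(model.qlat[pl.j]) / sd_obs(pl.i)
        elif slot == "kappa":
            factor = sd_exo(pl.j) / sd_obs(pl.i)
        elif slot == "B":
            out_sd = sd_lat(model.rlat[pl.i])
            term = Term(tuple(pl.rexp), model.rlat[pl.j],
                        tuple(model.exo[c] for c in pl.exo))
            var_t = term_cov(term, term, psiQ, h["rem_cov"], exo_m)
            factor = float(np.sqrt(max(var_t, 0.0))) / out_sd
        elif slot == "a":
            out_sd = sd_lat(model.rlat[pl.i])
            if not any(pl.rexp) and len(pl.exo) == 1:
                factor = sd_exo(pl.exo[0]) / out_sd
            elif not any(pl.rexp) and not pl.exo:
                factor = None          # latent intercept: left raw
            else:
                term = Term(tuple(pl.rexp), None,
                            tuple(model.exo[c] for c in pl.exo))
                var_t = term_cov(term, term, psiQ, h["rem_cov"], exo_m)
                factor = float(np.sqrt(max(var_t, 0.0))) / out_sd
        elif slot == "psi":
            if pl.i == pl.j:
                tot = V_lat[pl.i, pl.i]
                factor = 1.0 / tot if tot > 0 else None
            else:
                si, sj = sd_lat(model.rlat[pl.i]), sd_lat(model.rlat[pl.j])
                factor = 1.0 / (si * sj)
        elif slot == "psiQ":
            factor = 1.0 / raw if raw > 0 else None
        elif slot == "theta":
            if pl.i == pl.j:
                factor = 1.0 / var_obs[pl.i] if var_obs[pl.i] > 0 else None
            else:
                factor = 1.0 / (sd_obs(pl.i) * sd_obs(pl.j))
        elif slot == "nu":
            factor = None
        rows.append({
            "label": lab, "est": raw, "se": se_raw,
            "std": raw * factor if factor is not None else np.nan,
            "std_se": abs(factor) * se_raw if factor is not None else np.nan,
        })
    return pd.DataFrame(rows)
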