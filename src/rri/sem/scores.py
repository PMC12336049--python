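"""Per-subject factor scores for linear (product-free) models.

Regression scores are posterior means E[eta | y_obs, x] (shrunken toward
the prior); Bartlett scores are the GLS estimator of the fundamental
latent residuals, conditionally unbiased for the true latents.  Derived
latents (zero residual variance, e.g. formative composites) are propagated
deterministically through the structural equations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .compile import CompiledModel
from .data import Dataset
from .likelihood import Evaluator


def factor_scores(model: CompiledModel, internal: np.ndarray, data: Dataset,
                  method: str = "bartlett") -> pd.DataFrame:
    """Latent scores for every subject; columns follow spec latent order."""
    if model.node_dep_B or any(
            any(pl.rexp) and (pl.slot == "B" or pl.exo)
            for pl in model.placements):
        raise NotImplementedError(
            "factor scores are defined for the linear part only; fit the "
            "decomposition stage separately for scoring")
    if method not in ("regression", "bartlett"):
        raise ValueError("method must be 'regression' or 'bartlett'")
    ev = Evaluator(model, data)
    nat = model.transform.to_natural(np.asarray(internal, float))
    A = ev._assemble(nat)
    m = len(model.rlat)
    d = model.d
    n = data.n
    I = np.eye(m)
    F = np.linalg.inv(I - A.B0)
    H = A.Lam @ F
    psiQ = np.diag(A.psiQ) if d else np.zeros((0, 0))

    # joint covariance of (eta_rem, q) and the observed vector
    Vr = F @ (A.Psi + A.BQ @ psiQ @ A.BQ.T) @ F.T
    Crq = F @ A.BQ @ psiQ
    C_lat = np.block([[Vr, Crq], [Crq.T, psiQ]])
    L_full = np.hstack([A.Lam, A.LamQ])
    Sig_y = L_full @ C_lat @ L_full.T + A.Theta
    C_eta_y = C_lat @ L_full.T

    mu_rem = (A.alpha0 + data.X @ A.Gam.T) @ F.T          # (n, m)
    mu_lat = np.hstack([mu_rem, np.zeros((n, d))])
    mu_y = A.nu + data.X @ A.K.T + mu_rem @ A.Lam.T       # (n, p)

    out = np.full((n, m + d), np.nan)
    if method == "bartlett":
        fund = np.where(np.diag(A.Psi) > 0)[0]            # fundamental rem
        G = np.hstack([H[:, fund], A.LamQ + H @ A.BQ])    # d(y)/d(zeta, q)
    for pat in data.patterns:
        o, rows = pat.obs_idx, pat.rows
        resid = data.Y[np.ix_(rows, o)] - mu_y[np.ix_(rows, o)]
        if method == "regression":
            So = Sig_y[np.ix_(o, o)]
            W = np.linalg.solve(So, C_eta_y[:, o].T).T    # (m+d, p_o)
            out[rows] = mu_lat[rows] + resid @ W.T
        else:
            Go = G[o]
            if np.linalg.matrix_rank(Go) < Go.shape[1]:
                warnings.warn(
                    "Bartlett scores unavailable for a missingness pattern "
                    "(loading submatrix rank deficient); regression scores "
                    "substituted for those subjects")
                So = Sig_y[np.ix_(o, o)]
                W = np.linalg.solve(So, C_eta_y[:, o].T).T
                out[rows] = mu_lat[rows] + resid @ W.T
                continue
            Th = A.Theta[np.ix_(o, o)]
            Tinv_G = np.linalg.solve(Th, Go)
            M = np.linalg.solve(Go.T @ Tinv_G, Tinv_G.T)  # (q_fund+d, p_o)
            uz = resid @ M.T
            # propagate: eta = F (a(x) + Sel zeta); q latents directly
            zeta = np.zeros((len(rows), m))
            zeta[:, fund] = uz[:, :len(fund)]
            eta = (zeta + (A.alpha0 + data.X[rows] @ A.Gam.T)
                   + uz[:, len(fund):] @ A.BQ.T) @ F.T
            out[rows, :m] = eta
            out[rows, m:] = uz[:, len(fund):]
    cols = list(model.rlat) + list(model.qlat)
    return pd.DataFrame(out, columns=cols,
                        index=data.ids if data.ids is not None else None)
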