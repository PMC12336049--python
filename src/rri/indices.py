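"""Global model-fit battery: chi-square, CFI/TLI, RMSEA with 90 % CI,
SRMR, AIC/BIC/aBIC.

Conventions (documented, overridable where the literature disagrees): the
chi-square compares the fitted model with the saturated mean/covariance
model on the same cases; the CFI/TLI baseline is the independence model
(free means and variances, zero covariances); the RMSEA denominator uses n
by default (the ``n-1`` convention is available); the sample-size-adjusted
BIC substitutes (n + 2)/24 for n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

from .sem.data import Dataset
from .sem.fitting import FitResult
from .sem.saturated import independence_model, saturated_model


class IndexError_(ValueError):
    pass


@dataclass
class FitStats:
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    srmr: float
    aic: float
    bic: float
    abic: float
    n: int
    n_params: int
    loglik: float

    def to_dict(self) -> dict:
        return asdict(self)

    def row(self) -> dict:
        """One-row summary in the conventional reporting order."""
        return {
            "cfi": self.cfi, "tli": self.tli, "rmsea": self.rmsea,
            "rmsea_lo90": self.rmsea_lo, "rmsea_hi90": self.rmsea_hi,
            "srmr": self.srmr, "aic": self.aic, "bic": self.bic,
            "abic": self.abic, "chi2": self.chi2_model, "df": self.df_model,
        }


def chi_square(loglik_model: float, n_params_model: int,
               saturated_loglik: float, n_params_saturated: int
               ) -> tuple[float, int]:
    """Likelihood-ratio chi-square against the saturated model."""
    df = n_params_saturated - n_params_model
    if df < 0:
        raise IndexError_(
            f"model has more parameters ({n_params_model}) than the "
            f"saturated model ({n_params_saturated})")
    chi2 = 2.0 * (saturated_loglik - loglik_model)
    if chi2 < 0:
        if chi2 < -1e-6:
            warnings.warn(f"negative chi-square {chi2:.3g} clipped to 0")
        chi2 = 0.0
    return float(chi2), int(df)


def cfi_tli(chi2_m: float, df_m: int, chi2_b: float, df_b: int
            ) -> tuple[float, float]:
    """Comparative fit index and (uncapped) Tucker-Lewis index."""
    if df_b == 0:
        raise IndexError_("baseline model has zero degrees of freedom")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df_m == 0:
        tli = 1.0
    else:
        ratio_b = chi2_b / df_b
        ratio_m = chi2_m / df_m
        if ratio_b == 1.0:
            warnings.warn("degenerate baseline (chi2/df = 1): TLI undefined")
            tli = float("nan")
        else:
            tli = (ratio_b - ratio_m) / (ratio_b - 1.0)
    return float(cfi), float(tli)


def rmsea(chi2: float, df: int, n: int, *, conf: float = 0.90,
          n_convention: str = "n") -> tuple[float, float, float]:
    """Point estimate and confidence interval for the RMSEA.

    The CI inverts the noncentral chi-square CDF in the noncentrality
    parameter; endpoints with no root are 0 (or the point estimate's
    limiting value).  ``n_convention`` selects the denominator n or n - 1.
    """
    if df <= 0:
        raise IndexError_("RMSEA undefined for df <= 0")
    if n <= 1:
        raise IndexError_("RMSEA requires n > 1")
    denom = float(n if n_convention == "n" else n - 1)
    point = float(np.sqrt(max(chi2 - df, 0.0) / (df * denom)))
    alpha = 1.0 - conf

    def lam_for(prob: float) -> float:
        # solve P(chi2_{df, lam} <= chi2) = prob for lam >= 0
        f0 = stats.ncx2.cdf(chi2, df, 1e-12) - prob
        if f0 <= 0:
            return 0.0
        hi = max(10.0, 2 * chi2)
        while stats.ncx2.cdf(chi2, df, hi) - prob > 0:
            hi *= 2
            if hi > 1e8:
                return np.nan
        return float(optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob,
            1e-12, hi, xtol=1e-8))

    lam_lo = lam_for(1.0 - alpha / 2.0)
    lam_hi = lam_for(alpha / 2.0)
    lo = float(np.sqrt(lam_lo / (df * denom)))
    hi = float(np.sqrt(lam_hi / (df * denom)))
    return point, lo, hi


def srmr(sample_mean, sample_cov, implied_mean, implied_cov) -> float:
    """Standardized root mean square residual over unique (co)variances."""
    S = np.asarray(sample_cov, float)
    Sig = np.asarray(implied_cov, float)
    if S.shape != Sig.shape or S.shape[0] != S.shape[1]:
        raise IndexError_("moment matrices not conformable")
    sd = np.sqrt(np.diag(S))
    if (sd <= 0).any():
        raise IndexError_("non-positive sample variance")
    p = S.shape[0]
    resid = []
    for i in range(p):
        for j in range(i + 1):
            resid.append((S[i, j] - Sig[i, j]) / (sd[i] * sd[j]))
    return float(np.sqrt(np.mean(np.square(resid))))


def information_criteria(loglik: float, n_params: int, n: int
                         ) -> tuple[float, float, float]:
    """AIC, BIC, and sample-size-adjusted BIC (Sclove: n -> (n + 2)/24)."""
    if n <= 0:
        raise IndexError_("n must be positive")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n)
    abic = -2.0 * loglik + n_params * np.log((n + 2.0) / 24.0)
    return float(aic), float(bic), float(abic)


def fit_battery(fit: FitResult, *, rmsea_n_convention: str = "n"
                ) -> FitStats:
    """Full fit battery for a fitted (product-free) model.

    With exogenous covariates, both sides of each likelihood-ratio
    comparison are augmented with the same saturated covariate block, so
    the chi-square measures only the fit of the structured part.
    """
    data = fit.data
    y_only = data
    extra_ll = 0.0
    extra_par = 0
    if data.X.shape[1]:
        import pandas as pd

        frame = pd.DataFrame(
            np.hstack([data.Y, data.X]),
            columns=data.observed_names + data.exogenous_names)
        joint = Dataset.from_frame(frame,
                                   data.observed_names + data.exogenous_names)
        _, _, ll_sat, k_sat = saturated_model(joint)
        # model side: structured y | x plus saturated x marginal
        xdat = Dataset.from_frame(frame[data.exogenous_names],
                                  data.exogenous_names)
        _, _, ll_x, k_x = saturated_model(xdat)
        extra_ll, extra_par = ll_x, k_x
        _, _, ll_base_y, k_base_y = independence_model(y_only)
        ll_base, k_base = ll_base_y + ll_x, k_base_y + k_x
    else:
        _, _, ll_sat, k_sat = saturated_model(y_only)
        _, _, ll_base, k_base = independence_model(y_only)

    ll_m = fit.loglik + extra_ll
    k_m = fit.n_params + extra_par
    chi2_m, df_m = chi_square(ll_m, k_m, ll_sat, k_sat)
    chi2_b, df_b = chi_square(ll_base, k_base, ll_sat, k_sat)
    cfi, tli = cfi_tli(chi2_m, df_m, chi2_b, df_b)
    if df_m > 0:
        pt, lo, hi = rmsea(chi2_m, df_m, data.n,
                           n_convention=rmsea_n_convention)
    else:
        pt = lo = hi = 0.0
    mu_s, Sig_s, _, _ = saturated_model(y_only)
    mu_i, Sig_i = fit.implied_moments()
    srmr_v = srmr(mu_s, Sig_s, mu_i, Sig_i)
    aic, bic, abic = information_criteria(fit.loglik, fit.n_params, data.n)
    return FitStats(
        chi2_model=chi2_m, df_model=df_m, chi2_baseline=chi2_b,
        df_baseline=df_b, cfi=cfi, tli=tli, rmsea=pt, rmsea_lo=lo,
        rmsea_hi=hi, srmr=srmr_v, aic=aic, bic=bic, abic=abic,
        n=data.n, n_params=fit.n_params, loglik=fit.loglik,
    )
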