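"""Fit-index battery: closed forms, calibration, CI inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rri.indices import (FitStats, chi_square, cfi_tli, fit_battery,
                         information_criteria, rmsea, srmr, IndexError_)
from rri.sem import Dataset, FitOptions, ModelSpec, fit_ml
from rri.sem.saturated import independence_model, saturated_model
from rri.sem.spec import saturated_spec


def test_chi_square_identities():
    assert chi_square(-100.0, 5, -100.0, 5) == (0.0, 0)
    chi2, df = chi_square(-105.0, 5, -100.0, 10)
    assert chi2 == 10.0 and df == 5
    with pytest.raises(IndexError_):
        chi_square(-100.0, 12, -100.0, 10)


def test_chi_square_negative_clipped():
    with pytest.warns(UserWarning, match="clipped"):
        chi2, _ = chi_square(-99.0, 5, -100.0, 10)
    assert chi2 == 0.0


def test_cfi_tli_closed_forms():
    cfi, tli = cfi_tli(10.0, 5, 110.0, 10)
    assert abs(cfi - 0.95) < 1e-12
    assert abs(tli - 0.9) < 1e-12
    cfi, _ = cfi_tli(5.0, 5, 110.0, 10)
    assert cfi == 1.0


def test_rmsea_closed_forms():
    pt, lo, hi = rmsea(20.0, 10, 101, n_convention="n-1")
    assert abs(pt - 0.1) < 1e-12
    pt, _, _ = rmsea(8.0, 10, 101)
    assert pt == 0.0
    assert lo <= hi


def test_rmsea_ci_inverts_noncentral_chi2():
    """Endpoints satisfy the defining noncentral-chi2 CDF equations, and
    agree with Monte-Carlo quantiles on a lambda grid."""
    chi2, df, n = 35.0, 12, 400
    pt, lo, hi = rmsea(chi2, df, n)
    lam_lo = lo ** 2 * df * n
    lam_hi = hi ** 2 * df * n
    assert abs(stats.ncx2.cdf(chi2, df, lam_lo) - 0.95) < 1e-6
    assert abs(stats.ncx2.cdf(chi2, df, lam_hi) - 0.05) < 1e-6
    rng = np.random.default_rng(7)
    for lam, prob in ((lam_lo, 0.95), (lam_hi, 0.05)):
        draws = stats.ncx2.rvs(df, lam, size=200_000, random_state=rng)
        mc = np.mean(draws <= chi2)
        assert abs(mc - prob) < 0.005


def test_srmr_closed_forms():
    S = np.array([[1.0, 0.3], [0.3, 1.0]])
    assert srmr(None, S, None, S) == 0.0
    Sig = np.array([[1.0, 0.3 - 0.12], [0.3 - 0.12, 1.0]])
    assert abs(srmr(None, S, None, Sig) - np.sqrt(0.12 ** 2 / 3)) < 1e-12


def test_information_criteria_hand_values():
    assert information_criteria(0.0, 0, 10) == (0.0, 0.0, 0.0)
    aic, bic, abic = information_criteria(-100.0, 3, 100)
    assert abs(aic - 206.0) < 1e-12
    assert abs(bic - (200.0 + 3 * np.log(100))) < 1e-12
    assert abs(abic - (200.0 + 3 * np.log(102.0 / 24.0))) < 1e-12
    # AIC < BIC whenever ln(n) > 2
    for n in (8, 50, 10_000):
        a, b, _ = information_criteria(-10.0, 4, n)
        assert a < b


def test_saturated_model_battery_is_perfect(rng):
    Y = rng.multivariate_normal([0, 0, 0], np.eye(3) + 0.4, size=200)
    frame = pd.DataFrame(Y, columns=["a", "b", "c"])
    fit = fit_ml(saturated_spec(["a", "b", "c"]), frame,
                 options=FitOptions(compute_se=False))
    fs = fit_battery(fit)
    assert fs.chi2_model < 1e-6
    assert fs.df_model == 0
    assert fs.cfi == 1.0
    assert fs.rmsea == 0.0
    assert fs.srmr < 1e-6


def test_chi2_mean_matches_df_under_true_model(rng):
    """Likelihood-ratio statistic calibration over replicates."""
    # one-factor model with 3 indicators: df = 9 - 7... loadings 2 free,
    # variances 4, intercepts 3 => 9 params; saturated 9 => df 0. Use 4
    # indicators: saturated 14, model 12 => df 2.
    chis = []
    for rep in range(300):
        n = 150
        f = rng.normal(size=n)
        Y = np.column_stack([
            lam * f + rng.normal(0, 0.6, n) for lam in (1.0, 0.8, 1.2, 0.9)])
        frame = pd.DataFrame(Y, columns=list("abcd"))
        spec = ModelSpec(observed=list("abcd"), latents=["f"])
        spec.add_loading("a", "f", free=False, value=1.0)
        for o in "bcd":
            spec.add_loading(o, "f", value=1.0)
        spec.add_variance("f", value=1.0)
        for o in "abcd":
            spec.add_variance(o, value=0.36)
            spec.add_intercept(o, value=0.0)
        fit = fit_ml(spec, frame, options=FitOptions(compute_se=False))
        ds = Dataset.from_frame(frame, list("abcd"))
        _, _, ll_sat, k_sat = saturated_model(ds)
        chi2, df = chi_square(fit.loglik, fit.n_params, ll_sat, k_sat)
        assert df == 2
        chis.append(chi2)
    mean = np.mean(chis)
    # E[chi2] = df; MC standard error = sqrt(2*2/300) ~ 0.115
    assert abs(mean - 2.0) < 4 * np.sqrt(4 / len(chis))


def test_em_saturated_matches_complete_case_on_mcar(rng):
    """EM saturated LL beats any structured model and is stable."""
    Y = rng.multivariate_normal([0, 1], [[1, .5], [.5, 2]], size=400)
    Y[rng.random((400, 2)) < 0.2] = np.nan
    keep = np.isfinite(Y).any(axis=1)
    frame = pd.DataFrame(Y[keep], columns=["a", "b"])
    ds = Dataset.from_frame(frame, ["a", "b"])
    mu, Sig, ll, k = saturated_model(ds)
    assert k == 5
    # independence model cannot beat the saturated one
    _, _, ll_ind, _ = independence_model(ds)
    assert ll >= ll_ind
    # EM at the optimum: casewise FIML of a refit equals ll
    fit = fit_ml(saturated_spec(["a", "b"]), ds,
                 options=FitOptions(compute_se=False))
    assert fit.loglik <= ll + 1e-4
    np.testing.assert_allclose(fit.loglik, ll, atol=1e-3)


def test_indices_invariant_to_subject_order(rng, small_cohort):
    from rri.growth import compare_growth_forms

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = compare_growth_forms(small_cohort, forms=("linear",))
        shuffled = small_cohort.copy()
        shuffled.baseline = shuffled.baseline.sample(
            frac=1.0, random_state=1).reset_index(drop=True)
        b = compare_growth_forms(shuffled, forms=("linear",))
    for key in ("cfi", "tli", "rmsea", "srmr", "aic", "bic"):
        np.testing.assert_allclose(a.table[key], b.table[key], atol=1e-6)
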