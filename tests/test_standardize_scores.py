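"""Standardized estimates and factor scores."""

import numpy as np
import pandas as pd
import pytest

from rri.sem import Dataset, FitOptions, ModelSpec, compile_spec, fit_ml
from rri.sem.scores import factor_scores
from rri.sem.standardize import standardize


def test_simple_regression_closed_form(rng):
    """y = 0.2 x with Var(x)=4, Var(y)=1  ->  standardized 0.4."""
    n = 200_000
    x = rng.normal(0, 2.0, n)
    y = 0.2 * x + rng.normal(0, np.sqrt(1 - 0.16), n)
    frame = pd.DataFrame({"x": x, "y": y})
    spec = ModelSpec(observed=["y"], exogenous=["x"])
    spec.add_covariate("y", "x", value=0.1)
    spec.add_variance("y", value=1.0)
    spec.add_intercept("y", value=0.0)
    fit = fit_ml(spec, frame, options=FitOptions(compute_se=False))
    std = standardize(fit)
    val = std.loc[std.label == "y~x", "std"].iloc[0]
    assert abs(val - 0.4) < 0.01


def test_paths_on_unit_variance_variables_unchanged(rng):
    n = 300_000
    f = rng.normal(size=n)
    y = 0.5 * f + rng.normal(0, np.sqrt(0.75), n)
    frame = pd.DataFrame({"v": f, "y": y})
    spec = ModelSpec(observed=["v", "y"], latents=["f", "eta"])
    spec.add_loading("v", "f", free=False, value=1.0)
    spec.add_loading("y", "eta", free=False, value=1.0)
    spec.add_variance("v", free=False, value=0.0)
    spec.add_variance("y", free=False, value=0.0)
    spec.add_variance("f", value=1.0)
    spec.add_variance("eta", value=0.75)
    spec.add_intercept("v", value=0.0)
    spec.add_intercept("y", value=0.0)
    spec.add_regression("eta", "f", value=0.4)
    fit = fit_ml(spec, frame, options=FitOptions(compute_se=False))
    std = standardize(fit)
    raw = fit["eta~f"]
    val = std.loc[std.label == "eta~f", "std"].iloc[0]
    # Var(f)=1 and Var(eta_total)=1 in truth: standardized equals raw
    assert abs(val - raw) < 0.01
    assert abs(val - 0.5) < 0.01


def test_standardization_invariant_to_indicator_rescaling(small_cohort):
    """Multiplying an indicator by 10 leaves standardized estimates alone."""
    import warnings

    from rri.decomposition import decompose

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = decompose(small_cohort)
        scaled = small_cohort.copy()
        scaled.baseline["gm_vol"] = scaled.baseline["gm_vol"] * 10.0
        b = decompose(scaled)
    sa = standardize(a.fit).set_index("label")["std"]
    sb = standardize(b.fit).set_index("label")["std"]
    for lab in sa.index:
        if np.isfinite(sa[lab]):
            assert abs(sa[lab] - sb[lab]) < 1e-6, lab


# ------------------------------------------------------------------ scores
def _two_factor_setup(rng, n, noise=True):
    f1 = rng.normal(size=n)
    f2 = rng.normal(size=n)           # orthogonal truth
    e = (lambda s: rng.normal(0, s, n)) if noise else (lambda s: 0.0)
    frame = pd.DataFrame({
        "a1": f1 + e(0.5), "a2": 0.8 * f1 + e(0.5),
        "a3": 1.1 * f1 + e(0.5),
        "b1": f2 + e(0.5), "b2": 1.2 * f2 + e(0.5),
        "b3": 0.9 * f2 + e(0.5),
    })
    spec = ModelSpec(observed=list(frame.columns), latents=["f1", "f2"])
    spec.add_loading("a1", "f1", free=False, value=1.0)
    spec.add_loading("a2", "f1", value=0.8)
    spec.add_loading("a3", "f1", value=1.1)
    spec.add_loading("b1", "f2", free=False, value=1.0)
    spec.add_loading("b2", "f2", value=1.2)
    spec.add_loading("b3", "f2", value=0.9)
    spec.add_variance("f1", value=1.0)
    spec.add_variance("f2", value=1.0)
    spec.add_covariance("f1", "f2", value=0.1)
    for o in frame.columns:
        spec.add_variance(o, value=0.25 if noise else 0.01)
        spec.add_intercept(o, value=0.0)
    return frame, spec, f1, f2


def test_scores_noiseless_limit(rng):
    frame, spec, f1, f2 = _two_factor_setup(rng, 200, noise=False)
    cm = compile_spec(spec)
    nat = cm.start_natural.copy()
    # evaluate scores at the true parameters with tiny error variances
    for i, lab in enumerate(cm.labels):
        if lab in ("a2~f1",):
            nat[i] = 0.8
        if lab in ("b2~f2",):
            nat[i] = 1.2
        if lab.startswith(("a1~a1", "a2~a2", "b1~b1", "b2~b2")):
            nat[i] = 1e-8
        if lab.startswith("nu:"):
            nat[i] = 0.0
    ds = Dataset.from_frame(frame, cm.obs, [])
    internal = cm.transform.to_internal(nat)
    sc = factor_scores(cm, internal, ds, method="bartlett")
    np.testing.assert_allclose(sc["f1"], f1, atol=1e-5)
    np.testing.assert_allclose(sc["f2"], f2, atol=1e-5)


def test_bartlett_scores_conditionally_unbiased(rng):
    frame, spec, f1, f2 = _two_factor_setup(rng, 5000)
    fit = fit_ml(spec, frame, options=FitOptions(compute_se=False))
    sc = factor_scores(fit.model, fit.theta_internal, fit.data,
                       method="bartlett")
    slope1 = np.polyfit(f1, sc["f1"], 1)[0]
    slope2 = np.polyfit(f2, sc["f2"], 1)[0]
    assert abs(slope1 - 1.0) < 0.03
    assert abs(slope2 - 1.0) < 0.03
    # orthogonal truth: score correlation stays small
    assert abs(np.corrcoef(sc["f1"], sc["f2"])[0, 1]) < 0.05
    # regression scores are shrunken relative to Bartlett
    rc = factor_scores(fit.model, fit.theta_internal, fit.data,
                       method="regression")
    assert rc["f1"].var() < sc["f1"].var()


def test_scores_reject_product_models(small_cohort):
    from rri.analytical import build_analytical_spec

    cm = compile_spec(build_analytical_spec())
    with pytest.raises(NotImplementedError):
        factor_scores(cm, cm.start_internal(), None)
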