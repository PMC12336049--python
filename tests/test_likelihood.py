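"""Likelihood machinery: implied moments, FIML, latent-product quadrature."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from rri.sem import (Dataset, Evaluator, ModelSpec, compile_spec,
                     casewise_loglik, marginal_loglik_interaction)


def _evaluator(spec, frame, **kw):
    cm = compile_spec(spec)
    ds = Dataset.from_frame(frame, cm.obs, cm.exo)
    return cm, ds, Evaluator(cm, ds, **kw)


# ---------------------------------------------------------------- moments
def test_implied_moments_identity_model():
    spec = ModelSpec(observed=["y"], latents=["f"])
    spec.add_loading("y", "f", free=False, value=1.0)
    spec.add_variance("f", free=False, value=1.0)
    spec.add_variance("y", free=False, value=0.0)
    spec.add_intercept("y", free=False, value=0.0)
    cm = compile_spec(spec)
    ds = Dataset.from_frame(pd.DataFrame({"y": [0.0]}), ["y"])
    mu, Sig = Evaluator(cm, ds).implied_moments(cm.start_internal())
    np.testing.assert_allclose(Sig, [[1.0]])
    np.testing.assert_allclose(mu, [0.0])


def test_implied_moments_two_indicator_closed_form():
    spec = ModelSpec(observed=["a", "b"], latents=["f"])
    for o in ("a", "b"):
        spec.add_loading(o, "f", free=False, value=1.0)
        spec.add_variance(o, free=False, value=0.1)
        spec.add_intercept(o, free=False, value=0.0)
    spec.add_variance("f", free=False, value=1.0)
    cm = compile_spec(spec)
    ds = Dataset.from_frame(pd.DataFrame({"a": [0.0], "b": [0.0]}),
                            ["a", "b"])
    _, Sig = Evaluator(cm, ds).implied_moments(cm.start_internal())
    np.testing.assert_allclose(Sig, [[1.1, 1.0], [1.0, 1.1]], atol=1e-12)


def test_implied_moments_match_simulation(rng):
    """Random recursive 6-variable model vs 10^6 simulated draws."""
    spec = ModelSpec(observed=[f"y{i}" for i in range(6)],
                     latents=["f1", "f2"])
    lam = [1.0, 0.8, 1.2, 0.0, 0.0, 0.0]
    lam2 = [0.0, 0.0, 0.0, 1.0, 0.7, 0.9]
    for i in range(6):
        if lam[i]:
            spec.add_loading(f"y{i}", "f1", free=False, value=lam[i])
        if lam2[i]:
            spec.add_loading(f"y{i}", "f2", free=False, value=lam2[i])
        spec.add_variance(f"y{i}", free=False, value=0.3 + 0.05 * i)
        spec.add_intercept(f"y{i}", free=False, value=0.1 * i)
    spec.add_variance("f1", free=False, value=1.0)
    spec.add_variance("f2", free=False, value=0.6)
    spec.add_regression("f2", "f1", free=False, value=0.5)
    cm = compile_spec(spec)
    ds = Dataset.from_frame(
        pd.DataFrame(np.zeros((1, 6)), columns=cm.obs), cm.obs)
    mu, Sig = Evaluator(cm, ds).implied_moments(cm.start_internal())

    n = 1_000_000
    f1 = rng.normal(0, 1, n)
    f2 = 0.5 * f1 + rng.normal(0, np.sqrt(0.6), n)
    Y = np.empty((n, 6))
    for i in range(6):
        Y[:, i] = (0.1 * i + lam[i] * f1 + lam2[i] * f2
                   + rng.normal(0, np.sqrt(0.3 + 0.05 * i), n))
    np.testing.assert_allclose(mu, Y.mean(axis=0), atol=5e-3)
    np.testing.assert_allclose(Sig, np.cov(Y.T, bias=True), atol=1e-2)


# ------------------------------------------------------------------- FIML
def _factor_frame(rng, n=300, missing=False):
    f = rng.normal(size=n)
    Y = np.column_stack([
        f + rng.normal(0, 0.6, n),
        0.8 * f + rng.normal(0, 0.6, n),
        1.2 * f + rng.normal(0, 0.6, n),
    ])
    if missing:
        hide = rng.random((n, 3)) < 0.25
        hide[~(~hide).any(axis=1) > 0] = False
        hide[(hide.all(axis=1))] = False
        Y[hide] = np.nan
    return pd.DataFrame(Y, columns=["y0", "y1", "y2"])


def _factor_spec():
    spec = ModelSpec(observed=["y0", "y1", "y2"], latents=["f"])
    spec.add_loading("y0", "f", free=False, value=1.0)
    spec.add_loading("y1", "f", value=0.9)
    spec.add_loading("y2", "f", value=1.1)
    spec.add_variance("f", value=0.9)
    for o in ("y0", "y1", "y2"):
        spec.add_variance(o, value=0.4)
        spec.add_intercept(o, value=0.05)
    return spec


def test_complete_record_equals_mvn_density(rng):
    frame = _factor_frame(rng)
    cm, ds, ev = _evaluator(_factor_spec(), frame)
    x = cm.start_internal()
    mu, Sig = ev.implied_moments(x)
    expect = multivariate_normal(mu, Sig).logpdf(frame.to_numpy())
    np.testing.assert_allclose(ev.casewise_loglik(x), expect, rtol=1e-10)


def test_marginalization_oracle_bivariate(rng):
    """One missing variable: casewise FIML equals the marginal density."""
    spec = ModelSpec(observed=["a", "b"], latents=["f"])
    spec.add_loading("a", "f", free=False, value=1.0)
    spec.add_loading("b", "f", value=0.8)
    spec.add_variance("f", value=1.0)
    for o in ("a", "b"):
        spec.add_variance(o, value=0.5)
        spec.add_intercept(o, value=0.0)
    cm = compile_spec(spec)
    for _ in range(1000):
        lam = rng.uniform(0.2, 1.5)
        psi = rng.uniform(0.3, 2.0)
        th_a, th_b = rng.uniform(0.2, 1.0, 2)
        nu_a, nu_b = rng.normal(0, 1, 2)
        theta = np.array([lam, psi, th_a, nu_a, th_b, nu_b])
        nat = dict(zip(cm.labels, theta))
        a_val = rng.normal()
        got = casewise_loglik(cm, [nat[l] for l in cm.labels],
                              {"a": a_val})
        want = norm(nat["nu:a"], np.sqrt(nat["f~f"] + nat["a~a"])
                    ).logpdf(a_val)
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_sufficient_statistic_identity(rng):
    """Complete-data FIML total equals the Wishart/sufficient-stat form."""
    frame = _factor_frame(rng, n=400)
    cm, ds, ev = _evaluator(_factor_spec(), frame)
    x = cm.start_internal()
    total = ev.loglik(x)
    mu, Sig = ev.implied_moments(x)
    Y = frame.to_numpy()
    n, p = Y.shape
    ybar = Y.mean(axis=0)
    S = (Y - ybar).T @ (Y - ybar) / n
    d = ybar - mu
    Sinv = np.linalg.inv(Sig)
    expect = -0.5 * n * (p * np.log(2 * np.pi)
                         + np.linalg.slogdet(Sig)[1]
                         + np.trace(S @ Sinv) + d @ Sinv @ d)
    np.testing.assert_allclose(total, expect, rtol=1e-10)


def test_loglik_invariant_to_orderings(rng):
    frame = _factor_frame(rng, n=200, missing=True)
    cm, ds, ev = _evaluator(_factor_spec(), frame)
    x = cm.start_internal()
    base = ev.loglik(x)
    # subject order
    perm = frame.sample(frac=1.0, random_state=3)
    _, _, ev2 = _evaluator(_factor_spec(), perm)
    np.testing.assert_allclose(ev2.loglik(x), base, rtol=1e-12)
    # variable order: rebuild an equivalent spec with reordered observed
    spec = ModelSpec(observed=["y2", "y0", "y1"], latents=["f"])
    spec.add_loading("y0", "f", free=False, value=1.0)
    spec.add_loading("y1", "f", value=0.9)
    spec.add_loading("y2", "f", value=1.1)
    spec.add_variance("f", value=0.9)
    for o in ("y2", "y0", "y1"):
        spec.add_variance(o, value=0.4)
        spec.add_intercept(o, value=0.05)
    cm3 = compile_spec(spec)
    ds3 = Dataset.from_frame(frame, cm3.obs, [])
    ev3 = Evaluator(cm3, ds3)
    nat = dict(zip(cm.labels, cm.transform.to_natural(x)))
    x3 = cm3.transform.to_internal(
        np.array([nat[l] for l in cm3.labels]))
    np.testing.assert_allclose(ev3.loglik(x3), base, rtol=1e-12)


def test_empty_record_contributes_zero_with_warning():
    spec = _factor_spec()
    cm = compile_spec(spec)
    with pytest.warns(UserWarning, match="empty"):
        out = casewise_loglik(cm, cm.start_natural, {})
    assert out == 0.0


# ------------------------------------------------- latent products
def _interaction_spec(prod_value):
    spec = ModelSpec(observed=["v1", "v2", "y"], latents=["x1", "x2", "eta"])
    spec.add_loading("v1", "x1", free=False, value=1.0)
    spec.add_loading("v2", "x2", free=False, value=1.0)
    spec.add_loading("y", "eta", free=False, value=1.0)
    spec.add_variance("x1", value=1.0)
    spec.add_variance("x2", value=0.8)
    spec.add_variance("eta", value=0.5)
    spec.add_variance("v1", value=0.3)
    spec.add_variance("v2", value=0.25)
    spec.add_variance("y", free=False, value=0.1)
    for v in ("v1", "v2", "y"):
        spec.add_intercept(v, value=0.0)
    spec.add_regression("eta", "x1", value=0.6)
    spec.add_regression("eta", "x2", value=-0.4)
    spec.add_regression("eta", ("x1", "x2"), value=prod_value)
    return spec


def _interaction_frame(rng, n=200):
    x1 = rng.normal(size=n)
    x2 = rng.normal(0, np.sqrt(0.8), n)
    eta = 0.6 * x1 - 0.4 * x2 + 0.5 * x1 * x2 + rng.normal(0, np.sqrt(0.5), n)
    return pd.DataFrame({
        "v1": x1 + rng.normal(0, np.sqrt(0.3), n),
        "v2": x2 + rng.normal(0, np.sqrt(0.25), n),
        "y": eta + rng.normal(0, np.sqrt(0.1), n),
    })


def test_zero_products_reduce_to_linear_likelihood(rng):
    frame = _interaction_frame(rng)
    cm, ds, ev = _evaluator(_interaction_spec(0.0), frame, n_nodes=15)
    x = cm.start_internal()
    ev.set_rule(x)
    ll_quad = ev.casewise_loglik(x)
    # same model without the product term
    spec = _interaction_spec(0.0)
    spec.params = [p for p in spec.params if not isinstance(p.col, tuple)]
    cml, dsl, evl = _evaluator(spec, frame)
    ll_lin = evl.casewise_loglik(cml.start_internal())
    np.testing.assert_allclose(ll_quad, ll_lin, atol=1e-10)


def test_node_refinement_converges(rng):
    frame = _interaction_frame(rng)
    cm = compile_spec(_interaction_spec(0.5))
    x = cm.start_internal()
    lls = {}
    for nn in (15, 31, 63):
        ds = Dataset.from_frame(frame, cm.obs, [])
        ev = Evaluator(cm, ds, n_nodes=nn)
        ev.set_rule(x)
        lls[nn] = ev.loglik(x)
    assert abs(lls[31] - lls[15]) < 1e-6
    assert abs(lls[63] - lls[31]) < 1e-8


def test_latent_by_binary_product_group_split_oracle(rng):
    """Latent x observed-binary product = exact two-group mixture."""
    n = 150
    x = (rng.random(n) < 0.5).astype(float)
    xi = rng.normal(size=n)
    eta = 0.6 * xi + 0.9 * xi * x + rng.normal(0, np.sqrt(0.5), n)
    frame = pd.DataFrame({
        "v": 0.1 + xi + rng.normal(0, np.sqrt(0.3), n),
        "y": eta - 0.2,
        "x": x,
    })
    spec = ModelSpec(observed=["v", "y"], exogenous=["x"],
                     latents=["xi", "eta"])
    spec.add_loading("v", "xi", free=False, value=1.0)
    spec.add_loading("y", "eta", free=False, value=1.0)
    spec.add_variance("xi", value=1.0)
    spec.add_variance("eta", value=0.5)
    spec.add_variance("v", value=0.3)
    spec.add_variance("y", free=False, value=0.0)
    spec.add_intercept("v", value=0.1)
    spec.add_intercept("y", value=-0.2)
    spec.add_regression("eta", "xi", value=0.6)
    spec.add_regression("eta", ("xi", "x"), value=0.9)
    cm = compile_spec(spec)
    ds = Dataset.from_frame(frame, cm.obs, cm.exo)
    ev = Evaluator(cm, ds)
    got = ev.loglik(cm.start_internal())
    want = 0.0
    for g in (0.0, 1.0):
        lam = 0.6 + 0.9 * g
        Sig = np.array([[1.3, lam], [lam, lam ** 2 + 0.5]])
        sel = frame.loc[frame.x == g, ["v", "y"]].to_numpy()
        want += multivariate_normal([0.1, -0.2], Sig).logpdf(sel).sum()
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_marginal_loglik_interaction_api(rng):
    spec = _interaction_spec(0.5)
    nat = compile_spec(spec).start_natural
    rec = {"v1": 0.3, "v2": -0.1, "y": 0.5}
    a = marginal_loglik_interaction(spec, nat, rec, nodes=31)
    b = marginal_loglik_interaction(spec, nat, rec, nodes=63)
    assert abs(a - b) < 1e-7
    with pytest.warns(UserWarning, match="empty"):
        assert marginal_loglik_interaction(spec, nat, {}) == 0.0


# ------------------------------------------------------------- gradients
@pytest.mark.parametrize("case", ["linear", "interaction"])
def test_analytic_gradient_matches_finite_differences(rng, case):
    if case == "linear":
        frame = _factor_frame(rng, n=120, missing=True)
        cm, ds, ev = _evaluator(_factor_spec(), frame)
    else:
        frame = _interaction_frame(rng, n=120)
        frame.loc[:10, "v2"] = np.nan
        cm, ds, ev = _evaluator(_interaction_spec(0.5), frame, n_nodes=7)
    x = cm.start_internal()
    ev.set_rule(x)
    _, g = ev.loglik_and_grad(x)
    for j in range(len(x)):
        h = 1e-6
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fd = (ev.loglik(xp) - ev.loglik(xm)) / (2 * h)
        assert abs(g[j] - fd) < 1e-4 * max(1.0, abs(fd))
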