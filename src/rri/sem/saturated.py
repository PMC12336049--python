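"""Saturated and independence reference models under missing data.

The saturated (unrestricted mean/covariance) ML solution with arbitrary
missingness is found by EM over missingness patterns; with complete data it
reduces to the closed-form sample moments (ML, denominator n).  These
reference log-likelihoods anchor the chi-square, CFI/TLI and information
criteria.
"""

from __future__ import annotations

import numpy as np

from .data import Dataset

_LOG2PI = np.log(2.0 * np.pi)


def _fiml_loglik(data: Dataset, mu: np.ndarray, Sigma: np.ndarray) -> float:
    total = 0.0
    for pat in data.patterns:
        o, rows = pat.obs_idx, pat.rows
        Y = data.Y[np.ix_(rows, o)]
        So = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            return -np.inf
        e = Y - mu[o]
        u = np.linalg.solve(So, e.T).T
        total += -0.5 * (len(rows) * (len(o) * _LOG2PI + logdet)
                         + float(np.sum(e * u)))
    return float(total)


def saturated_model(data: Dataset, *, tol: float = 1e-10,
                    max_iter: int = 1000):
    """ML mean/covariance of the observed block and its log-likelihood.

    Returns (mu, Sigma, loglik, n_params).
    """
    p = data.p
    n_params = p + p * (p + 1) // 2
    if data.complete():
        mu, Sigma = data.sample_moments()
        return mu, Sigma, _fiml_loglik(data, mu, Sigma), n_params

    # available-case start
    mask = np.isfinite(data.Y)
    Y0 = np.where(mask, data.Y, 0.0)
    cnt = mask.sum(axis=0)
    mu = Y0.sum(axis=0) / np.maximum(cnt, 1)
    resid = np.where(mask, data.Y - mu, 0.0)
    denom = np.maximum(mask.T.astype(float) @ mask.astype(float), 2.0)
    Sigma = (resid.T @ resid) / denom
    Sigma = 0.5 * (Sigma + Sigma.T)
    w, V = np.linalg.eigh(Sigma)
    Sigma = (V * np.maximum(w, 1e-6)) @ V.T

    ll_prev = -np.inf
    n = data.n
    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pat in data.patterns:
            o, rows = pat.obs_idx, pat.rows
            mis = np.setdiff1d(np.arange(p), o)
            Y = data.Y[np.ix_(rows, o)]
            if mis.size == 0:
                s1 += Y.sum(axis=0)
                s2 += Y.T @ Y
                continue
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(mis, o)]
            W = np.linalg.solve(Soo, Smo.T).T            # (mis, obs)
            Em = mu[mis] + (Y - mu[o]) @ W.T
            Cmm = Sigma[np.ix_(mis, mis)] - W @ Smo.T
            full1 = np.zeros(p)
            full1[o] = Y.sum(axis=0)
            full1[mis] = Em.sum(axis=0)
            s1 += full1
            s2[np.ix_(o, o)] += Y.T @ Y
            s2[np.ix_(o, mis)] += Y.T @ Em
            s2[np.ix_(mis, o)] += Em.T @ Y
            s2[np.ix_(mis, mis)] += Em.T @ Em + len(rows) * Cmm
        mu = s1 / n
        Sigma = s2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _fiml_loglik(data, mu, Sigma)
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            break
        ll_prev = ll
    return mu, Sigma, _fiml_loglik(data, mu, Sigma), n_params


def independence_model(data: Dataset):
    """Free means/variances, zero covariances (FIML closed form).

    Under independence each variable's casewise contribution factorizes, so
    the ML solution is the per-variable mean/variance over available cases.
    Returns (mu, Sigma, loglik, n_params).
    """
    p = data.p
    mu = np.zeros(p)
    var = np.zeros(p)
    ll = 0.0
    for j in range(p):
        y = data.Y[:, j]
        y = y[np.isfinite(y)]
        mu[j] = y.mean()
        var[j] = y.var()
        ll += -0.5 * y.size * (_LOG2PI + np.log(var[j]) + 1.0)
    return mu, np.diag(var), float(ll), 2 * p
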