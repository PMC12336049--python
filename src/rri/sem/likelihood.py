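"""Casewise FIML likelihood with latent-interaction marginalization.

Likelihood model: conditional on the quadrature latents ``r`` (and on the
exogenous covariates), the model is linear Gaussian,

    eta = (I - B(r, x))^-1 [a(r, x) + zeta],   zeta ~ N(0, Psi)
    y   = nu + K x + LamQ r + Lam eta + eps,   eps  ~ N(0, Theta)

and the marginal casewise log-likelihood integrates the conditional normal
density of each subject's *observed* subvector over r with Gauss-Hermite
quadrature (adaptive per-subject mode/curvature recentring, or centred on
the prior).  With no quadrature latents this reduces exactly to classic
FIML over missingness patterns.

Gradients are analytic: posterior node weights times casewise normal score
terms, chained through the parameter placements and the unconstrained
internal parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .compile import CompiledModel
from .data import Dataset

_LOG2PI = np.log(2.0 * np.pi)


class NonPDError(np.linalg.LinAlgError):
    """Implied covariance not positive definite at the requested parameters."""


@dataclass
class _Assembled:
    nu: np.ndarray        # (p,)
    K: np.ndarray         # (p, k)
    Lam: np.ndarray       # (p, m)
    LamQ: np.ndarray      # (p, d)
    Psi: np.ndarray       # (m, m)
    Theta: np.ndarray     # (p, p)
    psiQ: np.ndarray      # (d,)
    B0: np.ndarray        # (m, m) static part
    alpha0: np.ndarray    # (m,)
    Gam: np.ndarray       # (m, k) single-covariate effects
    BQ: np.ndarray        # (m, d) linear effects of quadrature latents
    dyn_B: list           # placements with node/subject multipliers
    dyn_a: list


def _mult(pl, r, X):
    """Multiplier array for a placement: prod r^e * prod x, shape (nr, nk)."""
    out = None
    for q, e in enumerate(pl.rexp):
        if e:
            fac = r[..., q] ** e
            out = fac if out is None else out * fac
    for c in pl.exo:
        fac = X[:, None, c]
        out = fac if out is None else out * fac
    if out is None:
        return np.ones((1, 1))
    return out


class Evaluator:
    """Evaluate (and differentiate) the total FIML log-likelihood."""

    def __init__(self, model: CompiledModel, data: Dataset, *,
                 n_nodes: int = 15, adaptive: bool = True):
        if model.obs != data.observed_names:
            raise ValueError("dataset observed columns do not match spec")
        if model.exo != data.exogenous_names:
            raise ValueError("dataset exogenous columns do not match spec")
        self.model = model
        self.data = data
        self.n_nodes = int(n_nodes)
        self.adaptive = bool(adaptive)
        d = model.d
        if d > 0:
            if self.n_nodes < 3:
                raise ValueError("need at least 3 quadrature nodes")
            x, w = np.polynomial.hermite_e.hermegauss(self.n_nodes)
            # probabilists' rule; the latent prior density is applied
            # explicitly at evaluation time, so weights carry no 1/sqrt(2pi)
            grids = np.meshgrid(*([x] * d), indexing="ij")
            self._gh_x = np.stack([g.ravel() for g in grids], axis=-1)  # (K, d)
            lw = np.log(w)
            lws = np.meshgrid(*([lw] * d), indexing="ij")
            self._gh_logw = np.sum([g.ravel() for g in lws], axis=0)    # (K,)
        else:
            self._gh_x = np.zeros((1, 0))
            self._gh_logw = np.zeros(1)
        # frozen rule state
        self._r: np.ndarray | None = None          # (nr, K, d)
        self._logw_base: np.ndarray | None = None  # (nr, K)

    # ------------------------------------------------------------- assembly
    def _assemble(self, nat: np.ndarray) -> _Assembled:
        m = self.model
        p, k = len(m.obs), len(m.exo)
        mm, d = len(m.rlat), m.d
        A = _Assembled(
            nu=np.zeros(p), K=np.zeros((p, k)), Lam=np.zeros((p, mm)),
            LamQ=np.zeros((p, d)), Psi=np.zeros((mm, mm)),
            Theta=np.zeros((p, p)), psiQ=np.zeros(d), B0=np.zeros((mm, mm)),
            alpha0=np.zeros(mm), Gam=np.zeros((mm, k)), BQ=np.zeros((mm, d)),
            dyn_B=[], dyn_a=[],
        )
        for pl in m.placements:
            v = nat[pl.pidx] if pl.pidx is not None else pl.value
            dynamic = any(pl.rexp) or bool(pl.exo)
            if pl.slot == "nu":
                A.nu[pl.i] += v
            elif pl.slot == "kappa":
                A.K[pl.i, pl.j] += v
            elif pl.slot == "lambda":
                A.Lam[pl.i, pl.j] += v
            elif pl.slot == "lambdaQ":
                A.LamQ[pl.i, pl.j] += v
            elif pl.slot == "psi":
                A.Psi[pl.i, pl.j] += v
                if pl.i != pl.j:
                    A.Psi[pl.j, pl.i] += v
            elif pl.slot == "theta":
                A.Theta[pl.i, pl.j] += v
                if pl.i != pl.j:
                    A.Theta[pl.j, pl.i] += v
            elif pl.slot == "psiQ":
                A.psiQ[pl.i] += v
            elif pl.slot == "B":
                if dynamic:
                    A.dyn_B.append((pl, v))
                else:
                    A.B0[pl.i, pl.j] += v
            elif pl.slot == "a":
                if not dynamic:
                    A.alpha0[pl.i] += v
                elif not any(pl.rexp) and len(pl.exo) == 1:
                    A.Gam[pl.i, pl.exo[0]] += v
                elif sum(pl.rexp) == 1 and not pl.exo:
                    A.BQ[pl.i, pl.rexp.index(1)] += v
                    A.dyn_a.append((pl, v))
                else:
                    A.dyn_a.append((pl, v))
        return A

    # ------------------------------------------------------------ rule
    def set_rule(self, internal: np.ndarray | None = None, *,
                 grid: int = 21, span: float = 5.0) -> None:
        """Freeze the quadrature rule (nodes and base log-weights).

        Adaptive mode scans the conditional posterior of each subject's
        quadrature latent on a grid, recentres at its mode and rescales by
        the local curvature.  Non-adaptive mode centres on the prior.
        """
        m = self.model
        if m.d == 0:
            self._r = np.zeros((1, 1, 0))
            self._logw_base = np.zeros((1, 1))
            return
        nat = m.transform.to_natural(
            np.asarray(internal, float)) if internal is not None \
            else m.start_natural
        A = self._assemble(nat)
        sd = np.sqrt(A.psiQ)
        if not self.adaptive:
            r = (np.sqrt(2.0) * 0 + self._gh_x) * sd  # prior-centred
            self._r = r[None, :, :]
            base = self._gh_logw + 0.5 * np.sum(self._gh_x ** 2, axis=1) \
                + np.sum(np.log(sd))
            self._logw_base = base[None, :]
            return
        if m.d > 1:
            raise NotImplementedError(
                "adaptive recentring implemented for one quadrature latent")
        # posterior scan
        g = np.linspace(-span, span, grid) * sd[0]
        r_grid = np.tile(g[None, :, None], (1, 1, 1))          # (1, G, 1)
        cond = self._conditional_ll(A, r_grid)                 # (n, G)
        prior = -0.5 * (g / sd[0]) ** 2 - np.log(sd[0]) - 0.5 * _LOG2PI
        post = cond + prior[None, :]
        imax = np.argmax(post, axis=1)
        imax = np.clip(imax, 1, grid - 2)
        idx = np.arange(self.data.n)
        y0, y1, y2 = post[idx, imax - 1], post[idx, imax], post[idx, imax + 1]
        h = g[1] - g[0]
        denom = y0 - 2 * y1 + y2
        denom = np.minimum(denom, -1e-10)
        offset = 0.5 * (y0 - y2) / denom * h
        offset = np.clip(offset, -h, h)
        center = g[imax] + offset
        curv = -denom / h ** 2
        scale = 1.0 / np.sqrt(np.maximum(curv, 1e-12))
        scale = np.clip(scale, 0.05 * sd[0], 2.0 * sd[0])
        x = self._gh_x[:, 0]
        r = center[:, None] + scale[:, None] * x[None, :]
        self._r = r[:, :, None]
        self._logw_base = (self._gh_logw[None, :]
                           + 0.5 * x[None, :] ** 2
                           + np.log(scale)[:, None])

    # --------------------------------------------------------- conditionals
    def _forward(self, A: _Assembled, r: np.ndarray):
        """Conditional means/covariances given nodes r of shape (nr, K, d)."""
        X = self.data.X
        n = self.data.n
        mm = len(self.model.rlat)
        nr, K, d = r.shape
        I = np.eye(mm)
        # B: node values are per-subject under the adaptive rule, so any
        # node-dependent entry is then subject-dependent too
        node_dep = any(any(pl.rexp) for pl, _ in A.dyn_B)
        need_n = any(pl.exo for pl, _ in A.dyn_B) or (node_dep and nr > 1)
        nB_n = n if need_n else 1
        nB_k = K if node_dep else 1
        B = np.broadcast_to(A.B0, (nB_n, nB_k, mm, mm)).copy()
        for pl, v in A.dyn_B:
            mult = v * _mult(pl, r, X)
            B[..., pl.i, pl.j] += np.broadcast_to(mult, (nB_n, nB_k))
        if A.dyn_B or A.B0.any():
            F = np.linalg.inv(I - B)
        else:
            F = np.broadcast_to(I, B.shape).copy()
        # latent intercept contributions
        K_a = K if self._a_node_dep(A) else 1
        a = np.zeros((n, K_a, mm))
        a += (A.alpha0 + X @ A.Gam.T)[:, None, :]
        for pl, v in A.dyn_a:
            a[..., pl.i] += v * _mult(pl, r, X)
        s = np.matmul(F, a[..., None])[..., 0]                  # (n|, K|, m)
        mu = (A.nu + X @ A.K.T[:, :])[:, None, :] \
            + np.matmul(r, A.LamQ.T) \
            + np.matmul(s, A.Lam.T)                             # (n, K|1, p)
        H = np.matmul(A.Lam, F)                                 # (nBn,nBk,p,m)
        Sigma = np.matmul(np.matmul(H, A.Psi), np.swapaxes(H, -1, -2)) + A.Theta
        return B, F, a, s, mu, H, Sigma

    @staticmethod
    def _a_node_dep(A: _Assembled) -> bool:
        return any(any(pl.rexp) for pl, _ in A.dyn_a)

    def _conditional_ll(self, A: _Assembled, r: np.ndarray) -> np.ndarray:
        """log p(y_i | r_k) for every subject/node, shape (n, K)."""
        _, _, _, _, mu, _, Sigma = self._forward(A, r)
        n, K = self.data.n, max(r.shape[1], mu.shape[1])
        out = np.zeros((n, K))
        for pat in self.data.patterns:
            o, rows = pat.obs_idx, pat.rows
            Yp = self.data.Y[np.ix_(rows, o)]
            mup = mu[rows][:, :, o] if mu.shape[0] > 1 else mu[:, :, o]
            Sp = Sigma[..., o[:, None], o[None, :]]
            Sp_r = Sp[rows] if Sp.shape[0] > 1 else Sp
            sign, logdet = np.linalg.slogdet(Sp_r)
            if (sign <= 0).any():
                raise NonPDError("implied covariance not positive definite")
            e = Yp[:, None, :] - mup
            u = np.linalg.solve(Sp_r, e[..., None])[..., 0]
            quad = np.sum(e * u, axis=-1)
            out[rows] = -0.5 * (len(o) * _LOG2PI + logdet + quad)
        return out

    # ------------------------------------------------------------- loglik
    def _rule(self):
        if self._r is None:
            self.set_rule(self.model.start_internal())
        return self._r, self._logw_base

    def _log_node_weights(self, A: _Assembled, r, logw_base) -> np.ndarray:
        if self.model.d == 0:
            return logw_base
        prior = -0.5 * (r ** 2 / A.psiQ + np.log(A.psiQ) + _LOG2PI)
        return logw_base + prior.sum(axis=-1)

    def casewise_loglik(self, internal: np.ndarray) -> np.ndarray:
        nat = self.model.transform.to_natural(np.asarray(internal, float))
        A = self._assemble(nat)
        r, logw_base = self._rule()
        cond = self._conditional_ll(A, r)
        logw = self._log_node_weights(A, r, logw_base)
        if cond.shape[1] == 1 and logw.shape[1] == 1:
            return cond[:, 0] + logw[:, 0]
        return logsumexp(np.broadcast_to(logw, cond.shape) + cond, axis=1)

    def loglik(self, internal: np.ndarray) -> float:
        return float(self.casewise_loglik(internal).sum())

    # ------------------------------------------------------------- gradient
    def loglik_and_grad(self, internal: np.ndarray, *,
                        casewise_scores: bool = False):
        """Total log-likelihood and its gradient on the internal scale.

        With ``casewise_scores`` also returns the (n, n_free) matrix of
        per-subject score vectors on the *natural* scale.
        """
        internal = np.asarray(internal, float)
        m = self.model
        nat = m.transform.to_natural(internal)
        A = self._assemble(nat)
        r, logw_base = self._rule()
        X = self.data.X
        n, nfree = self.data.n, m.n_free
        B, F, a, s, mu, H, Sigma = self._forward(A, r)
        logw = self._log_node_weights(A, r, logw_base)

        ll_case = np.zeros(n)
        grad_nat = np.zeros(nfree)
        scores = np.zeros((n, nfree)) if casewise_scores else None

        # derivative of the prior node-weight term wrt psiQ (natural scale)
        if m.d > 0:
            dprior = 0.5 * (r ** 2 / A.psiQ ** 2 - 1.0 / A.psiQ)  # (nr,K,d)

        if Sigma.shape[0] > 1:
            # subject-specific covariances (latent interactions with an
            # adaptive rule): handle all missingness patterns in one flat
            # batch by identity-padding the missing entries, which leaves
            # the observed-subvector density and scores exactly intact
            return self._flat_grad(internal, A, r, logw, F, s, mu, H, Sigma,
                                   dprior if m.d > 0 else None,
                                   casewise_scores)

        for pat in self.data.patterns:
            o, rows = pat.obs_idx, pat.rows
            nt = len(rows)
            Yp = self.data.Y[np.ix_(rows, o)]
            mup = mu[rows][:, :, o] if mu.shape[0] > 1 else mu[:, :, o]
            Sp = Sigma[..., o[:, None], o[None, :]]
            Sp = Sp[rows] if Sp.shape[0] > 1 else Sp
            Ho = H[..., o, :]
            Ho = Ho[rows] if Ho.shape[0] > 1 else Ho
            Fp = F[rows] if F.shape[0] > 1 else F
            sp = s[rows] if s.shape[0] > 1 else s
            rp = r[rows] if r.shape[0] > 1 else r
            lwp = logw[rows] if logw.shape[0] > 1 else logw

            sign, logdet = np.linalg.slogdet(Sp)
            if (sign <= 0).any():
                raise NonPDError("implied covariance not positive definite")
            U = np.linalg.inv(Sp)                                # (.,.,pt,pt)
            e = Yp[:, None, :] - mup                             # (nt,K?,pt)
            u = np.matmul(U, e[..., None])[..., 0]               # (nt,K,pt)
            quad = np.sum(e * u, axis=-1)
            cond = -0.5 * (len(o) * _LOG2PI + logdet + quad)     # (nt,K)
            joint = np.broadcast_to(lwp, cond.shape) + cond
            llp = logsumexp(joint, axis=1)
            ll_case[rows] = llp
            pw = np.exp(joint - llp[:, None])                    # (nt,K)

            # shared precomputations
            T = np.matmul(np.swapaxes(Ho, -1, -2), u[..., None])[..., 0]
            c = np.matmul(T, A.Psi)
            dvec = np.matmul(Fp, c[..., None])[..., 0]           # (nt,K,m)
            V = np.matmul(U, Ho)                                 # Σ^-1 Ho
            Q = np.matmul(np.swapaxes(Ho, -1, -2), V)            # (.,.,m,m)
            W = np.matmul(np.matmul(Fp, A.Psi), Q)               # (.,.,m,m)
            opos = {int(v): i for i, v in enumerate(o)}

            def accum(pidx, term, mult):
                contrib = pw * np.broadcast_to(term * mult, pw.shape)
                grad_nat[pidx] += contrib.sum()
                if casewise_scores:
                    scores[rows, pidx] += contrib.sum(axis=1)

            for pl in m.placements:
                if pl.pidx is None:
                    continue
                slot = pl.slot
                if slot in ("nu", "kappa", "lambdaQ"):
                    if pl.i not in opos:
                        continue
                    ui = u[..., opos[pl.i]]
                    if slot == "nu":
                        term, mult = ui, 1.0
                    elif slot == "kappa":
                        term, mult = ui, X[rows, pl.j][:, None]
                    else:
                        term, mult = ui, rp[..., pl.j]
                elif slot == "lambda":
                    if pl.i not in opos:
                        continue
                    io = opos[pl.i]
                    Mrow = np.matmul(np.matmul(Fp, A.Psi),
                                     np.swapaxes(V, -1, -2))[..., pl.j, io]
                    term = (u[..., io] * (sp[..., pl.j] + dvec[..., pl.j])
                            - Mrow)
                    mult = 1.0
                elif slot == "B":
                    term = (T[..., pl.i] * (sp[..., pl.j] + dvec[..., pl.j])
                            - W[..., pl.j, pl.i])
                    mult = _mult(pl, rp, X[rows])
                elif slot == "a":
                    term = T[..., pl.i]
                    mult = _mult(pl, rp, X[rows])
                elif slot == "psi":
                    if pl.i == pl.j:
                        term = 0.5 * (T[..., pl.i] ** 2 - Q[..., pl.i, pl.i])
                    else:
                        term = (T[..., pl.i] * T[..., pl.j]
                                - Q[..., pl.i, pl.j])
                    mult = 1.0
                elif slot == "theta":
                    if pl.i not in opos or pl.j not in opos:
                        continue
                    io, jo = opos[pl.i], opos[pl.j]
                    if io == jo:
                        term = 0.5 * (u[..., io] ** 2 - U[..., io, io])
                    else:
                        term = u[..., io] * u[..., jo] - U[..., io, jo]
                    mult = 1.0
                elif slot == "psiQ":
                    term = dprior[..., pl.i]
                    term = term[rows] if term.shape[0] > 1 else term
                    mult = 1.0
                else:  # pragma: no cover
                    continue
                accum(pl.pidx, term, mult)

        J = m.transform.jacobian(internal)
        grad_int = J.T @ grad_nat
        total = float(ll_case.sum())
        if casewise_scores:
            return total, grad_int, scores
        return total, grad_int

    def _flat_grad(self, internal, A, r, logw, F, s, mu, H, Sigma, dprior,
                   casewise_scores):
        """Single-batch likelihood/gradient with identity-padded missing."""
        m = self.model
        X = self.data.X
        n, nfree = self.data.n, m.n_free
        K = mu.shape[1]
        mask = np.isfinite(self.data.Y)                      # (n, p)
        mf = mask.astype(float)
        cnt = mf.sum(axis=1)
        Yf = np.where(mask, self.data.Y, 0.0)

        p = mu.shape[-1]
        Mout = mf[:, None, :, None] * mf[:, None, None, :]   # (n,1,p,p)
        # zero the cross blocks of missing entries, put 1 on their diagonal
        St = Sigma * Mout + np.eye(p) * (1.0 - mf)[:, None, :, None]
        sign, logdet = np.linalg.slogdet(St)
        if (sign <= 0).any():
            raise NonPDError("implied covariance not positive definite")
        U = np.linalg.inv(St)                                # (n,K,p,p)
        e = (Yf[:, None, :] - mu) * mf[:, None, :]           # (n,K,p)
        u = np.matmul(U, e[..., None])[..., 0]
        quad = np.sum(e * u, axis=-1)
        cond = -0.5 * (cnt[:, None] * _LOG2PI + logdet + quad)
        joint = np.broadcast_to(logw, cond.shape) + cond
        ll_case = logsumexp(joint, axis=1)
        pw = np.exp(joint - ll_case[:, None])

        Htil = H * mf[:, None, :, None]                      # (n,K,p,m)
        HtT = np.swapaxes(Htil, -1, -2)
        T = np.matmul(HtT, u[..., None])[..., 0]             # (n,K,m)
        c = np.matmul(T, A.Psi)
        dvec = np.matmul(F, c[..., None])[..., 0]
        V = np.matmul(U, Htil)
        Q = np.matmul(HtT, V)                                # (n,K,m,m)
        W = np.matmul(np.matmul(F, A.Psi), Q)
        Udiag = np.einsum("...ii->...i", U)

        grad_nat = np.zeros(nfree)
        scores = np.zeros((n, nfree)) if casewise_scores else None
        need_M = any(pl.slot == "lambda" and pl.pidx is not None
                     for pl in m.placements)
        if need_M:
            Mlam = np.matmul(np.matmul(F, A.Psi), np.swapaxes(V, -1, -2))
        sd = s + dvec                                        # (n,K,m)

        # batched placement terms: stack every free placement's (n,K) term
        # array into one tensor and contract with the posterior weights once
        terms: list[np.ndarray] = []
        pidx: list[int] = []
        for pl in m.placements:
            if pl.pidx is None:
                continue
            slot = pl.slot
            if slot == "nu":
                t_ = u[..., pl.i]
            elif slot == "kappa":
                t_ = u[..., pl.i] * X[:, pl.j][:, None]
            elif slot == "lambdaQ":
                t_ = u[..., pl.i] * r[..., pl.j]
            elif slot == "lambda":
                t_ = u[..., pl.i] * sd[..., pl.j] - Mlam[..., pl.j, pl.i]
            elif slot == "B":
                t_ = (T[..., pl.i] * sd[..., pl.j] - W[..., pl.j, pl.i]) \
                    * _mult(pl, r, X)
            elif slot == "a":
                t_ = T[..., pl.i] * _mult(pl, r, X)
            elif slot == "psi":
                if pl.i == pl.j:
                    t_ = 0.5 * (T[..., pl.i] ** 2 - Q[..., pl.i, pl.i])
                else:
                    t_ = T[..., pl.i] * T[..., pl.j] - Q[..., pl.i, pl.j]
            elif slot == "theta":
                if pl.i == pl.j:
                    t_ = 0.5 * (u[..., pl.i] ** 2 - Udiag[..., pl.i]) \
                        * mf[:, pl.i][:, None]
                else:
                    t_ = (u[..., pl.i] * u[..., pl.j] - U[..., pl.i, pl.j]) \
                        * (mf[:, pl.i] * mf[:, pl.j])[:, None]
            elif slot == "psiQ":
                t_ = dprior[..., pl.i]
            else:  # pragma: no cover
                continue
            terms.append(np.broadcast_to(t_, pw.shape))
            pidx.append(pl.pidx)
        if terms:
            stack = np.stack(terms, axis=-1)                 # (n,K,npl)
            per_subject = np.einsum("nk,nkp->np", pw, stack)
            contrib = per_subject.sum(axis=0)
            np.add.at(grad_nat, pidx, contrib)
            if casewise_scores:
                np.add.at(scores.T, pidx, per_subject.T)

        J = m.transform.jacobian(internal)
        grad_int = J.T @ grad_nat
        total = float(ll_case.sum())
        if casewise_scores:
            return total, grad_int, scores
        return total, grad_int

    # -------------------------------------------------------------- moments
    def implied_moments(self, internal: np.ndarray):
        """Model-implied mean and covariance of the observed variables.

        Linear part only: product terms are excluded, exogenous covariates
        are marginalized over their sample moments.
        """
        m = self.model
        nat = m.transform.to_natural(np.asarray(internal, float))
        A = self._assemble(nat)
        mm = len(m.rlat)
        Binv = np.linalg.inv(np.eye(mm) - A.B0)
        H = A.Lam @ Binv
        xm, Sx = self.data.x_moments()
        mu = A.nu + A.K @ xm + H @ (A.alpha0 + A.Gam @ xm)
        C = A.K + H @ A.Gam
        D = A.LamQ + H @ A.BQ
        Sigma = (H @ A.Psi @ H.T + A.Theta + C @ Sx @ C.T
                 + D @ np.diag(A.psiQ) @ D.T)
        return mu, Sigma


def casewise_loglik(spec, theta_natural, record: dict, *,
                    exogenous: dict | None = None):
    """Log-likelihood of one subject's observed subvector (linear model).

    ``record`` maps observed-variable names to values; variables absent
    from the mapping are treated as missing.  An empty record contributes
    zero with a warning.
    """
    import pandas as pd

    from .compile import compile_spec

    if not record:
        warnings.warn("empty observed subvector contributes 0 to the "
                      "log-likelihood")
        return 0.0
    model = spec if isinstance(spec, CompiledModel) else compile_spec(spec)
    row = {v: record.get(v, np.nan) for v in model.obs}
    row.update(exogenous or {})
    frame = pd.DataFrame([row])
    ds = Dataset.from_frame(frame, model.obs, model.exo)
    ev = Evaluator(model, ds)
    internal = model.transform.to_internal(np.asarray(theta_natural, float))
    return float(ev.casewise_loglik(internal)[0])


def marginal_loglik_interaction(spec, theta_natural, record: dict, *,
                                nodes: int = 15,
                                exogenous: dict | None = None,
                                adaptive: bool = True):
    """Marginal casewise log-likelihood for a model with latent products.

    Integrates the conditionally normal likelihood over the interacting
    latents with (adaptive) Gauss-Hermite quadrature; reduces exactly to
    :func:`casewise_loglik` when all product coefficients are zero.
    """
    import pandas as pd

    from .compile import compile_spec

    if not record:
        warnings.warn("empty observed subvector contributes 0 to the "
                      "log-likelihood")
        return 0.0
    model = spec if isinstance(spec, CompiledModel) else compile_spec(spec)
    row = {v: record.get(v, np.nan) for v in model.obs}
    row.update(exogenous or {})
    frame = pd.DataFrame([row])
    ds = Dataset.from_frame(frame, model.obs, model.exo)
    ev = Evaluator(model, ds, n_nodes=nodes, adaptive=adaptive)
    internal = model.transform.to_internal(np.asarray(theta_natural, float))
    ev.set_rule(internal)
    ll = ev.casewise_loglik(internal)
    if not np.isfinite(ll[0]):
        raise FloatingPointError(
            "quadrature produced a non-finite likelihood for the record")
    return float(ll[0])
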