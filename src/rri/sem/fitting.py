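"""Maximum-likelihood fitting of compiled SEMs.

Quasi-Newton (L-BFGS) maximization of the FIML log-likelihood with analytic
gradients on an unconstrained internal scale.  With latent interactions the
quadrature rule is frozen during each optimization pass and refreshed
(mode-and-curvature recentring) until the likelihood stabilizes.  Standard
errors come from the inverse observed information (finite differences of
the analytic gradient), mapped to the natural scale by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .compile import CompiledModel, compile_spec
from .data import Dataset
from .likelihood import Evaluator, NonPDError
from .spec import ModelSpec


class IdentificationError(ValueError):
    """Information matrix is rank deficient at the starting values."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(
            "model not identified; aliased parameters: " + ", ".join(aliased))


@dataclass
class FitOptions:
    n_nodes: int = 15
    adaptive: bool = True
    gtol: float = 1e-5
    ll_rtol: float = 1e-8
    max_iter: int = 500
    max_refresh: int = 3
    refresh_tol: float = 1e-6
    n_restarts: int = 0
    restart_scale: float = 0.2
    check_identification: bool = True
    compute_se: bool = True
    se_method: str = "observed"   # or "bhhh" (outer product of scores)
    var_floor: float = 1e-6
    seed: int | None = None


@dataclass
class FitResult:
    """Estimates, uncertainty and convergence metadata for one model fit."""

    labels: list[str]
    estimates: np.ndarray            # natural scale
    se: np.ndarray
    loglik: float
    n_params: int
    n_subjects: int
    converged: bool
    grad_norm: float
    n_iter: int
    model: CompiledModel
    data: Dataset
    theta_internal: np.ndarray
    vcov: np.ndarray | None = None   # natural scale
    se_unstable: bool = False
    options: FitOptions = field(default_factory=FitOptions)
    warnings_: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.estimates / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def __getitem__(self, label: str) -> float:
        return float(self.estimates[self.labels.index(label)])

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def estimates_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.estimates)))

    def implied_moments(self):
        ev = Evaluator(self.model, self.data,
                       n_nodes=self.options.n_nodes,
                       adaptive=self.options.adaptive)
        return ev.implied_moments(self.theta_internal)

    def coefficient_table(self):
        import pandas as pd

        return pd.DataFrame({
            "label": self.labels,
            "est": self.estimates,
            "se": self.se,
            "est_se": self.z,
            "p": self.pvalues,
        })


def _check_identification(ev: Evaluator, internal: np.ndarray,
                          labels: list[str]) -> None:
    _, _, scores = ev.loglik_and_grad(internal, casewise_scores=True)
    info = scores.T @ scores
    norm = np.sqrt(np.maximum(np.diag(info), 1e-300))
    info_n = info / norm[:, None] / norm[None, :]
    w, V = np.linalg.eigh(info_n)
    tol = 1e-8
    bad = np.where(w < tol * max(w.max(), 1.0))[0]
    if bad.size:
        aliased: list[str] = []
        for b in bad:
            idx = np.where(np.abs(V[:, b]) > 0.3)[0]
            aliased.extend(labels[i] for i in idx)
        raise IdentificationError(sorted(set(aliased)) or list(labels))


def fit_ml(spec: ModelSpec | CompiledModel, data: Dataset | "object", *,
           start: dict[str, float] | None = None,
           options: FitOptions | None = None) -> FitResult:
    """Fit a model by (full-information) maximum likelihood."""
    options = options or FitOptions()
    model = spec if isinstance(spec, CompiledModel) else compile_spec(spec)
    if not isinstance(data, Dataset):
        data = Dataset.from_frame(data, model.obs, model.exo)
    ev = Evaluator(model, data, n_nodes=options.n_nodes,
                   adaptive=options.adaptive)

    nat0 = model.start_natural.copy()
    if start:
        for lab, val in start.items():
            if lab in model.labels:
                nat0[model.labels.index(lab)] = val
    x0 = model.transform.to_internal(nat0)
    ev.set_rule(x0)

    if options.check_identification:
        _check_identification(ev, x0, model.labels)

    def objective(x):
        try:
            ll, g = ev.loglik_and_grad(x)
        except (NonPDError, FloatingPointError):
            return 1e12, np.zeros_like(x)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        return -ll, -g

    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_restarts):
        starts.append(x0 + rng.normal(scale=options.restart_scale,
                                      size=x0.shape))

    # diagonal preconditioner (BHHH curvature at the start values): evens
    # out the wildly different scales of means, paths and log-variances so
    # quasi-Newton line searches rarely backtrack
    try:
        _, _, sc0 = ev.loglik_and_grad(x0, casewise_scores=True)
        S0 = sc0 @ model.transform.jacobian(x0)
        dscale = np.sqrt((S0 ** 2).sum(axis=0))
        med = np.median(dscale[dscale > 0]) if (dscale > 0).any() else 1.0
        dscale = np.clip(dscale, 1e-3 * med, 1e3 * med)
        if not np.isfinite(dscale).all() or (dscale <= 0).any():
            raise FloatingPointError
    except (NonPDError, FloatingPointError):
        dscale = np.ones_like(x0)

    def objective_scaled(z):
        f, g = objective(z / dscale)
        return f, g / dscale

    # dense BFGS: the chol-block/composite-weight coupling is ill-scaled
    # for limited-memory updates but benign for a full Hessian approximation
    method = "BFGS" if model.n_free <= 150 else "L-BFGS-B"
    best = None
    n_iter_total = 0
    # quadrature models: quasi-Newton pass under the initial rule at a
    # loosened tolerance, then recentre and Newton-polish with the observed
    # information (which the SE step reuses)
    gtol_pass = max(options.gtol, 1e-3)   # Newton polish does the last mile
    best_x, best_ll = None, -np.inf
    info_cache = None
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore",
                                message="Desired error not necessarily")
        for x_start in starts:
            ev.set_rule(x_start)
            res = optimize.minimize(
                objective_scaled, x_start * dscale, jac=True, method=method,
                options={"maxiter": options.max_iter, "gtol": gtol_pass})
            x = res.x / dscale
            n_iter_total += res.nit
            info = None
            ll_here = -res.fun
            if model.d > 0:
                ll_ref = None
                for refresh in range(options.max_refresh + 1):
                    ev.set_rule(x)
                    x, info, ll_here, nit = _newton_polish(ev, x, options,
                                                           info)
                    n_iter_total += nit
                    if ll_ref is not None and abs(ll_here - ll_ref) \
                            < options.refresh_tol * max(1.0, abs(ll_here)):
                        break
                    ll_ref = ll_here
            else:
                x, info, ll_here, nit = _newton_polish(ev, x, options)
                n_iter_total += nit
            if ll_here > best_ll:
                best_x, best_ll, info_cache = x, ll_here, info
    assert best_x is not None
    x_opt = best_x
    ev.set_rule(x_opt)
    ll_opt, g_opt = ev.loglik_and_grad(x_opt)
    gmax = float(np.max(np.abs(g_opt))) if g_opt.size else 0.0
    thresh = max(options.gtol, 2e-7 * abs(ll_opt))
    if gmax >= thresh:
        # fall back to a fresh quasi-Newton pass at full precision
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore",
                                    message="Desired error not necessarily")
            res = optimize.minimize(
                objective, x_opt, jac=True, method=method,
                options={"maxiter": options.max_iter, "gtol": options.gtol})
        if -res.fun >= ll_opt:
            x_opt = res.x
            n_iter_total += res.nit
            info_cache = None
            ll_opt, g_opt = ev.loglik_and_grad(x_opt)
            gmax = float(np.max(np.abs(g_opt))) if g_opt.size else 0.0
    # converged: gradient max-norm below the absolute tolerance, or below
    # a relative tolerance tied to the log-likelihood magnitude (documented)
    converged = gmax < thresh
    # unbounded-likelihood guard: a variance diving to zero (degenerate
    # data) stalls the unconstrained pass; re-solve on the floored region
    logpos = model.transform.log_positions()
    floor = np.log(options.var_floor)
    if not converged and logpos.size and \
            (x_opt[logpos] < floor + 2.0).any():
        bounds = [(None, None)] * x_opt.size
        for j in logpos:
            bounds[j] = (floor, None)
        x_b = x_opt.copy()
        x_b[logpos] = np.maximum(x_b[logpos], floor)
        res = optimize.minimize(
            objective, x_b, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.max_iter, "gtol": options.gtol})
        x_opt = res.x
        n_iter_total += res.nit
        info_cache = None
        at_bound = np.zeros_like(x_opt, dtype=bool)
        at_bound[logpos] = x_opt[logpos] <= floor + 1e-8
        free_idx = np.where(~at_bound)[0]
        if at_bound.any() and free_idx.size:
            # freeze boundary variances, re-solve the remaining directions
            template = x_opt.copy()

            def obj_free(xf):
                xx = template.copy()
                xx[free_idx] = xf
                f, g = objective(xx)
                return f, g[free_idx]

            with warnings.catch_warnings():
                warnings.filterwarnings(
                    "ignore", message="Desired error not necessarily")
                res2 = optimize.minimize(
                    obj_free, x_opt[free_idx], jac=True, method="BFGS",
                    options={"maxiter": options.max_iter,
                             "gtol": options.gtol})
            if -res2.fun >= -res.fun:
                x_opt[free_idx] = res2.x
                n_iter_total += res2.nit
        ll_opt, g_opt = ev.loglik_and_grad(x_opt)
        gmax = float(np.max(np.abs(np.where(at_bound, 0.0, g_opt)))) \
            if x_opt.size else 0.0
        converged = gmax < max(options.gtol, 1e-6 * abs(ll_opt))
        if at_bound.any():
            warnings.warn("variance estimate at the zero boundary")
    warn_list: list[str] = []
    if not converged:
        warn_list.append(f"non-convergence: |grad|_max={gmax:.3g}")
        warnings.warn(warn_list[-1])

    nat = model.transform.to_natural(x_opt)
    se = np.full(model.n_free, np.nan)
    vcov = None
    unstable = False
    if options.compute_se and model.n_free:
        if options.se_method == "bhhh":
            vcov_int, unstable = _bhhh_vcov(ev, x_opt)
        else:
            vcov_int, unstable = _observed_info_vcov(ev, x_opt,
                                                     info=info_cache)
        J = model.transform.jacobian(x_opt)
        vcov = J @ vcov_int @ J.T
        diag = np.diag(vcov).copy()
        if (diag < -1e-8).any():
            unstable = True
        se = np.sqrt(np.clip(diag, 0.0, None))
        if unstable:
            warn_list.append("observed information not positive definite; "
                             "pseudo-inverse standard errors (unstable)")
            warnings.warn(warn_list[-1])

    return FitResult(
        labels=list(model.labels), estimates=nat, se=se, loglik=float(ll_opt),
        n_params=model.n_free, n_subjects=data.n, converged=bool(converged),
        grad_norm=gmax, n_iter=n_iter_total, model=model, data=data,
        theta_internal=x_opt, vcov=vcov, se_unstable=unstable,
        options=options, warnings_=warn_list,
    )


def _fd_information(ev: Evaluator, x: np.ndarray,
                    rel_step: float = 1e-5) -> np.ndarray:
    """Observed information via forward FD of the analytic gradient."""
    nfree = x.size
    info = np.zeros((nfree, nfree))
    _, g0 = ev.loglik_and_grad(x)
    for j in range(nfree):
        h = rel_step * max(1.0, abs(x[j]))
        xp = x.copy()
        xp[j] += h
        _, gp = ev.loglik_and_grad(xp)
        info[j] = -(gp - g0) / h
    return 0.5 * (info + info.T)


def _newton_polish(ev: Evaluator, x: np.ndarray, options: FitOptions,
                   info: np.ndarray | None = None):
    """Newton refinement under a freshly frozen quadrature rule.

    Uses (and returns) the finite-difference observed information, so the
    subsequent standard-error step can reuse it.
    """
    ll, g = ev.loglik_and_grad(x)
    nit = 0
    for _ in range(12):
        if np.abs(g).max() < max(options.gtol, 1e-8 * abs(ll)):
            break
        if info is None:
            info = _fd_information(ev, x)
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            break
        t, improved = 1.0, False
        for _ in range(8):
            try:
                ll_new, g_new = ev.loglik_and_grad(x + t * step)
            except (NonPDError, FloatingPointError):
                ll_new = -np.inf
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                x, ll, g = x + t * step, ll_new, g_new
                improved = True
                break
            t *= 0.5
        nit += 1
        if not improved:
            # stale curvature: refresh the information once, then give up
            if nit > 1:
                break
            info = _fd_information(ev, x)
    return x, info, ll, nit


def _observed_info_vcov(ev: Evaluator, x_opt: np.ndarray,
                        rel_step: float = 1e-5,
                        info: np.ndarray | None = None):
    """Inverse observed information (optionally reusing a cached matrix)."""
    if info is None:
        info = _fd_information(ev, x_opt, rel_step)
    try:
        w = np.linalg.eigvalsh(info)
        if w.min() <= 0:
            raise np.linalg.LinAlgError
        vcov = np.linalg.inv(info)
        return vcov, False
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info), True


def _bhhh_vcov(ev: Evaluator, x_opt: np.ndarray):
    """Inverse outer-product-of-scores information (one gradient pass).

    Casewise scores are accumulated on the natural scale; chain them to the
    internal scale so the caller's delta-method step applies uniformly.
    """
    _, _, scores = ev.loglik_and_grad(x_opt, casewise_scores=True)
    J = ev.model.transform.jacobian(x_opt)
    S_int = scores @ J                     # (n, nfree) internal-scale scores
    info = S_int.T @ S_int
    try:
        w = np.linalg.eigvalsh(info)
        if w.min() <= 0:
            raise np.linalg.LinAlgError
        return np.linalg.inv(info), False
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info), True


def standard_errors(fit: FitResult) -> np.ndarray:
    """Observed-information standard errors (natural scale).

    Recomputes them if the fit was run with ``compute_se=False``; flags the
    result as unstable when the information matrix is not positive definite.
    """
    if np.isfinite(fit.se).all() and fit.vcov is not None:
        return fit.se
    ev = Evaluator(fit.model, fit.data, n_nodes=fit.options.n_nodes,
                   adaptive=fit.options.adaptive)
    ev.set_rule(fit.theta_internal)
    vcov_int, unstable = _observed_info_vcov(ev, fit.theta_internal)
    J = fit.model.transform.jacobian(fit.theta_internal)
    fit.vcov = J @ vcov_int @ J.T
    fit.se_unstable = unstable
    fit.se = np.sqrt(np.clip(np.diag(fit.vcov), 0.0, None))
    return fit.se
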