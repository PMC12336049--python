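"""Declarative specification of constrained structural equation models.

A :class:`ModelSpec` lists observed endogenous variables, exogenous covariates
(conditioned on, never modelled), latent variables, and a table of parameters:
loadings, regressions (including product terms of latents and covariates),
intercepts/means and (co)variances.  Each parameter is either fixed at an
explicit value or free with a unique label; equality constraints are expressed
by sharing a label.

The spec is purely declarative; :mod:`rri.sem.compile` turns it into the
matrix form used by the likelihood machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence


class SpecError(ValueError):
    """Raised for malformed or inconsistent model specifications."""


# parameter matrices:
#   lambda : observed <- latent loading
#   kappa  : observed <- exogenous regression
#   nu     : observed intercept
#   beta   : latent <- latent (or product) regression
#   gamma  : latent <- exogenous (or product of exogenous) regression
#   alpha  : latent intercept
#   psi    : latent (co)variance
#   theta  : observed residual (co)variance
_MATRICES = ("lambda", "kappa", "nu", "beta", "gamma", "alpha", "psi", "theta")


@dataclass
class Parameter:
    matrix: str
    row: str
    col: tuple[str, ...] | str | None
    free: bool
    value: float
    label: str | None = None

    def key(self) -> tuple:
        col = tuple(self.col) if isinstance(self.col, (list, tuple)) else self.col
        return (self.matrix, self.row, col)


def _product_label(parts: Sequence[str]) -> str:
    return "*".join(parts)


@dataclass
class ModelSpec:
    """A constrained SEM over observed, exogenous and latent variables."""

    observed: list[str] = field(default_factory=list)
    exogenous: list[str] = field(default_factory=list)
    latents: list[str] = field(default_factory=list)
    params: list[Parameter] = field(default_factory=list)

    # ------------------------------------------------------------------ build
    def _check_new(self, p: Parameter) -> None:
        if p.matrix not in _MATRICES:
            raise SpecError(f"unknown parameter matrix {p.matrix!r}")
        for q in self.params:
            if q.key() == p.key():
                raise SpecError(f"duplicate parameter entry {p.key()}")
        if p.free and p.label:
            for q in self.params:
                if q.free and q.label == p.label and q.matrix != p.matrix:
                    # equality constraints across matrices are not meaningful here
                    raise SpecError(
                        f"label {p.label!r} reused across matrices "
                        f"{q.matrix}/{p.matrix}"
                    )

    def _add(self, p: Parameter) -> Parameter:
        if p.free and p.label is None:
            col = p.col
            if isinstance(col, (list, tuple)):
                col = _product_label(col)
            p.label = f"{p.row}~{col}" if col is not None else f"{p.matrix}:{p.row}"
        self._check_new(p)
        self.params.append(p)
        return p

    def add_loading(self, obs: str, latent: str, *, free: bool = True,
                    value: float = 1.0, label: str | None = None) -> Parameter:
        self._require(obs, self.observed, "observed")
        self._require(latent, self.latents, "latent")
        return self._add(Parameter("lambda", obs, latent, free, value, label))

    def add_regression(self, target: str, predictor: str | Sequence[str], *,
                       free: bool = True, value: float = 0.0,
                       label: str | None = None) -> Parameter:
        """Regress a latent on a latent, covariate, or product term.

        ``predictor`` may be a tuple of variable names, in which case the
        product of those (previously declared) variables is the predictor.
        """
        self._require(target, self.latents, "latent")
        if isinstance(predictor, (list, tuple)):
            parts = tuple(predictor)
            for v in parts:
                if v not in self.latents and v not in self.exogenous:
                    raise SpecError(f"product component {v!r} not declared")
            n_lat = sum(v in self.latents for v in parts)
            mat = "beta" if n_lat else "gamma"
            return self._add(Parameter(mat, target, parts, free, value, label))
        if predictor in self.latents:
            return self._add(Parameter("beta", target, predictor, free, value, label))
        if predictor in self.exogenous:
            return self._add(Parameter("gamma", target, predictor, free, value, label))
        raise SpecError(f"predictor {predictor!r} not declared")

    def add_covariate(self, obs: str, exo: str, *, free: bool = True,
                      value: float = 0.0, label: str | None = None) -> Parameter:
        self._require(obs, self.observed, "observed")
        self._require(exo, self.exogenous, "exogenous")
        return self._add(Parameter("kappa", obs, exo, free, value, label))

    def add_intercept(self, var: str, *, free: bool = True, value: float = 0.0,
                      label: str | None = None) -> Parameter:
        if var in self.observed:
            return self._add(Parameter("nu", var, None, free, value, label))
        if var in self.latents:
            return self._add(Parameter("alpha", var, None, free, value, label))
        raise SpecError(f"{var!r} is neither observed nor latent")

    def add_variance(self, var: str, *, free: bool = True, value: float = 1.0,
                     label: str | None = None) -> Parameter:
        if var in self.latents:
            return self._add(Parameter("psi", var, var, free, value, label))
        if var in self.observed:
            return self._add(Parameter("theta", var, var, free, value, label))
        raise SpecError(f"{var!r} is neither observed nor latent")

    def add_covariance(self, a: str, b: str, *, free: bool = True,
                       value: float = 0.0, label: str | None = None) -> Parameter:
        if a in self.latents and b in self.latents:
            mat = "psi"
        elif a in self.observed and b in self.observed:
            mat = "theta"
        else:
            raise SpecError("covariance endpoints must both be latent or both observed")
        a, b = sorted((a, b))
        return self._add(Parameter(mat, a, b, free, value, label))

    @staticmethod
    def _require(name: str, pool: list[str], kind: str) -> None:
        if name not in pool:
            raise SpecError(f"{kind} variable {name!r} not declared")

    # ------------------------------------------------------------ inspection
    @property
    def free_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.params:
            if p.free and p.label not in seen:
                seen.append(p.label)  # type: ignore[arg-type]
        return seen

    def product_terms(self) -> list[Parameter]:
        return [p for p in self.params if isinstance(p.col, tuple)]

    def has_latent_products(self) -> bool:
        return any(
            sum(v in self.latents for v in p.col) >= 1
            for p in self.product_terms()
            if p.matrix == "beta"
        )

    def get(self, matrix: str, row: str, col=None) -> Parameter:
        col_t = tuple(col) if isinstance(col, (list, tuple)) else col
        for p in self.params:
            if p.key() == (matrix, row, col_t):
                return p
        raise KeyError((matrix, row, col_t))

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        for p in d["params"]:
            if isinstance(p["col"], (list, tuple)):
                p["col"] = list(p["col"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        spec = cls(
            observed=list(d["observed"]),
            exogenous=list(d.get("exogenous", [])),
            latents=list(d.get("latents", [])),
        )
        for pd in d["params"]:
            col = pd["col"]
            if isinstance(col, list):
                col = tuple(col)
            spec._add(Parameter(pd["matrix"], pd["row"], col,
                                bool(pd["free"]), float(pd["value"]),
                                pd.get("label")))
        return spec

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "ModelSpec":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))


def saturated_spec(observed: Iterable[str]) -> ModelSpec:
    """Free mean + full free covariance model (the FIML saturated model)."""
    obs = list(observed)
    spec = ModelSpec(observed=obs)
    for i, v in enumerate(obs):
        spec.add_intercept(v, value=0.0)
        spec.add_variance(v, value=1.0)
        for w in obs[:i]:
            spec.add_covariance(v, w, value=0.0)
    return spec


def independence_spec(observed: Iterable[str]) -> ModelSpec:
    """Free means and variances, zero covariances (the CFI/TLI baseline)."""
    spec = ModelSpec(observed=list(observed))
    for v in spec.observed:
        spec.add_intercept(v, value=0.0)
        spec.add_variance(v, value=1.0)
    return spec
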