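"""Moment algebra for structural predictor terms.

The structural part of the analytical model regresses latent growth factors
on a mix of predictors: zero-mean latents (the residual reserve index R and
the brain composite), exogenous covariates, and products of these.  Under
the model's assumptions (quadrature latents independent of everything;
remaining latents in products zero-mean, jointly normal and independent of
the covariates) the covariance between any two such terms factorizes into

    cov(t1, t2) = prod_q m_q(e1q + e2q) * remfactor * E[z1 z2]  -  E[t1] E[t2]

where ``m_q`` are the central moments of the quadrature latents (1, 0,
psi_q for powers 0, 1, 2), ``remfactor`` covers the at-most-one remaining
latent per term, and ``z`` is the product of the term's exogenous columns
(arbitrary covariate dependence enters only through the moments of those
columns, supplied by a backend: sample columns, or closed-form population
moments in the cohort generator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class Term:
    """One structural predictor: prod_q r_q^e * (rem latent)^b * prod exo."""

    rpow: tuple[int, ...]            # powers of quadrature latents
    rem: str | None                  # remaining latent name, or None
    exo: tuple[str, ...]             # exogenous column names (product)

    @property
    def has_latent(self) -> bool:
        return self.rem is not None or any(self.rpow)


def _qmoment(power: int, var: float) -> float:
    if power == 0:
        return 1.0
    if power == 1:
        return 0.0
    if power == 2:
        return var
    raise NotImplementedError(f"quadrature-latent power {power} unsupported")


def term_mean(t: Term, exo_mean: Callable[[tuple[str, ...]], float]) -> float:
    if t.has_latent:
        return 0.0
    return exo_mean(t.exo) if t.exo else 1.0


def term_cov(t1: Term, t2: Term, qvar: Sequence[float],
             rem_cov: Callable[[str, str], float],
             exo_mean: Callable[[tuple[str, ...]], float]) -> float:
    """Covariance between two predictor terms under the model assumptions."""
    qpart = 1.0
    for q, v in enumerate(qvar):
        qpart *= _qmoment(t1.rpow[q] + t2.rpow[q], v)
    if qpart == 0.0:
        return 0.0
    if t1.rem is not None and t2.rem is not None:
        rempart = rem_cov(t1.rem, t2.rem)
    elif t1.rem is not None or t2.rem is not None:
        return 0.0  # single zero-mean latent factor
    else:
        rempart = 1.0
    ez = exo_mean(t1.exo + t2.exo) if (t1.exo or t2.exo) else 1.0
    return qpart * rempart * ez - term_mean(t1, exo_mean) * term_mean(t2, exo_mean)


def term_cov_matrix(terms: Sequence[Term], qvar: Sequence[float],
                    rem_cov: Callable[[str, str], float],
                    exo_mean: Callable[[tuple[str, ...]], float]) -> np.ndarray:
    k = len(terms)
    S = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1):
            S[i, j] = S[j, i] = term_cov(terms[i], terms[j], qvar,
                                         rem_cov, exo_mean)
    return S


def term_means(terms: Sequence[Term],
               exo_mean: Callable[[tuple[str, ...]], float]) -> np.ndarray:
    return np.array([term_mean(t, exo_mean) for t in terms])


class SampleExoMoments:
    """Raw product moments of exogenous columns from a data table."""

    def __init__(self, columns: dict[str, np.ndarray]):
        self.columns = {k: np.asarray(v, float) for k, v in columns.items()}

    def __call__(self, cols: tuple[str, ...]) -> float:
        if not cols:
            return 1.0
        prod = np.ones_like(next(iter(self.columns.values())))
        for c in cols:
            prod = prod * self.columns[c]
        return float(prod.mean())
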