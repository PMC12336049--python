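"""Compile a :class:`~rri.sem.spec.ModelSpec` into conditionally linear form.

The engine's central representation: conditioning on a minimal set of
"quadrature latents" (those that appear multiplied with another latent in a
product term) renders the model linear Gaussian.  Every parameter entry
becomes a *placement* into one of the conditional model matrices, with a
multiplier that may depend on the conditioned latent values ``r`` and on
exogenous covariate columns:

    nu, kappa        observed intercepts / covariate effects (mean only)
    lambda, lambdaQ  observed loadings on remaining / conditioned latents
    B, a             latent <- latent coefficients and latent intercept
                     contributions (products land here)
    psi, theta       latent and observed residual (co)variances
    psiQ             prior variances of the conditioned latents

Free parameters are optimized on an unconstrained internal scale (log for
variances, Cholesky blocks for covariance blocks); reporting stays on the
natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spec import ModelSpec, Parameter, SpecError


@dataclass
class Placement:
    slot: str
    i: int
    j: int
    pidx: int | None          # free-parameter index, None if fixed
    value: float              # fixed value (ignored when free)
    rexp: tuple[int, ...]     # powers of each conditioned latent
    exo: tuple[int, ...]      # exogenous column indices multiplied in


@dataclass
class CholBlock:
    latents: list[int]                    # rem-latent indices, block-local order
    entries: dict[tuple[int, int], int]   # (local i>=j) -> free-parameter index


class ParamTransform:
    """Bijection between the natural and unconstrained internal scales."""

    def __init__(self, labels: list[str], log_mask: np.ndarray,
                 blocks: list[CholBlock]):
        self.labels = labels
        self.log_mask = log_mask
        self.blocks = blocks
        self.n = len(labels)
        self._block_pos = set()
        for b in blocks:
            self._block_pos.update(b.entries.values())

    def to_internal(self, nat: np.ndarray) -> np.ndarray:
        nat = np.asarray(nat, float)
        if (nat[self.log_mask] <= 0).any():
            raise ValueError("variance start values must be > 0")
        internal = nat.copy()
        internal[self.log_mask] = np.log(nat[self.log_mask])
        for blk in self.blocks:
            b = len(blk.latents)
            M = np.zeros((b, b))
            for (i, j), pos in blk.entries.items():
                M[i, j] = M[j, i] = nat[pos]
            w, _ = np.linalg.eigh(M)
            if w.min() <= 1e-10:
                M += np.eye(b) * (1e-8 - min(w.min(), 0))
            L = np.linalg.cholesky(M)
            for (i, j), pos in blk.entries.items():
                internal[pos] = np.log(L[i, i]) if i == j else L[i, j]
        return internal

    def to_natural(self, internal: np.ndarray) -> np.ndarray:
        internal = np.asarray(internal, float)
        nat = internal.copy()
        nat[self.log_mask] = np.exp(internal[self.log_mask])
        for blk in self.blocks:
            b = len(blk.latents)
            L = np.zeros((b, b))
            for (i, j), pos in blk.entries.items():
                L[i, j] = np.exp(internal[pos]) if i == j else internal[pos]
            M = L @ L.T
            for (i, j), pos in blk.entries.items():
                nat[pos] = M[i, j]
        return nat

    def log_positions(self) -> np.ndarray:
        """Internal indices on a log scale (variances, block diagonals)."""
        pos = list(np.where(self.log_mask)[0])
        for blk in self.blocks:
            for (i, j), p in blk.entries.items():
                if i == j:
                    pos.append(p)
        return np.array(sorted(pos), dtype=int)

    def jacobian(self, internal: np.ndarray) -> np.ndarray:
        """d(natural)/d(internal), dense (n, n)."""
        internal = np.asarray(internal, float)
        J = np.eye(self.n)
        for idx in np.where(self.log_mask)[0]:
            J[idx, idx] = np.exp(internal[idx])
        for blk in self.blocks:
            b = len(blk.latents)
            L = np.zeros((b, b))
            for (i, j), pos in blk.entries.items():
                L[i, j] = np.exp(internal[pos]) if i == j else internal[pos]
            for (i, j), pos_n in blk.entries.items():      # natural entry Psi_ij
                for (a, c), pos_i in blk.entries.items():  # internal entry L_ac
                    d = 0.0
                    if i == a:
                        d += L[j, c]
                    if j == a:
                        d += L[i, c]
                    if a == c:
                        d *= L[a, a]   # chain through log-diagonal
                    J[pos_n, pos_i] = d
        return J


@dataclass
class CompiledModel:
    spec: ModelSpec
    obs: list[str]
    exo: list[str]
    qlat: list[str]
    rlat: list[str]
    placements: list[Placement]
    labels: list[str]
    start_natural: np.ndarray
    transform: ParamTransform
    fixed_matrices: dict = field(default_factory=dict)
    subject_dep_B: bool = False
    node_dep_B: bool = False

    @property
    def n_free(self) -> int:
        return len(self.labels)

    @property
    def d(self) -> int:
        return len(self.qlat)

    def start_internal(self) -> np.ndarray:
        return self.transform.to_internal(self.start_natural)


def _select_quadrature(spec: ModelSpec) -> list[str]:
    """Minimal latent set whose conditioning linearizes all product terms."""
    multi = []
    for p in spec.product_terms():
        if p.matrix != "beta":
            continue
        lats = [v for v in p.col if v in spec.latents]  # type: ignore[union-attr]
        if len(lats) >= 2:
            multi.append(lats)
    # only structurally exogenous latents can be conditioned on
    endogenous = {p.row for p in spec.params
                  if p.matrix in ("beta", "gamma")}
    candidates = [v for v in spec.latents if v not in endogenous]
    Q: list[str] = []
    while True:
        pending = [set(l) - set(Q) for l in multi]
        pending = [s for s in pending if len(s) >= 2]
        if not pending:
            break
        counts = {}
        for s in pending:
            for v in s:
                if v in candidates and v not in Q:
                    counts[v] = counts.get(v, 0) + 1
        if not counts:
            raise SpecError(
                "product terms cannot be linearized: no exogenous latent "
                "available to condition on")
        best = max(candidates, key=lambda v: counts.get(v, 0))
        Q.append(best)
    # any latent in Q must be exogenous in the structural part
    for p in spec.params:
        if p.matrix == "beta" and p.row in Q:
            raise SpecError(f"quadrature latent {p.row!r} cannot be regressed "
                            "on other variables")
        if p.matrix == "gamma" and p.row in Q:
            raise SpecError(f"quadrature latent {p.row!r} cannot depend on "
                            "covariates")
        if p.matrix == "psi" and p.row != p.col and (p.row in Q or p.col in Q):
            if p.free or p.value != 0.0:
                raise SpecError(
                    f"covariance {p.row}~~{p.col} involving a quadrature "
                    "latent must be fixed at zero")
        if p.matrix == "alpha" and p.row in Q and (p.free or p.value != 0.0):
            raise SpecError(f"quadrature latent {p.row!r} must have zero mean")
    return Q


def compile_spec(spec: ModelSpec) -> CompiledModel:
    obs, exo = list(spec.observed), list(spec.exogenous)
    qlat = _select_quadrature(spec)
    rlat = [v for v in spec.latents if v not in qlat]
    oi = {v: i for i, v in enumerate(obs)}
    xi = {v: i for i, v in enumerate(exo)}
    qi = {v: i for i, v in enumerate(qlat)}
    ri = {v: i for i, v in enumerate(rlat)}
    d = len(qlat)

    labels: list[str] = []
    label_idx: dict[str, int] = {}
    start: list[float] = []
    kind: list[str] = []          # "var" | "free"
    psi_entries: dict[str, tuple[int, int]] = {}

    def free_index(p: Parameter, is_var: bool) -> int:
        lab = p.label
        assert lab is not None
        if lab in label_idx:
            return label_idx[lab]
        label_idx[lab] = len(labels)
        labels.append(lab)
        start.append(p.value)
        kind.append("var" if is_var else "free")
        return label_idx[lab]

    placements: list[Placement] = []
    free_cov_edges: list[tuple[int, int, int]] = []  # (ri, rj, pidx) in psi

    for p in spec.params:
        col = p.col
        if p.matrix == "lambda":
            assert isinstance(col, str)
            if col in qi:
                slot, i, j = "lambdaQ", oi[p.row], qi[col]
            else:
                slot, i, j = "lambda", oi[p.row], ri[col]
            rexp, exoc = (0,) * d, ()
        elif p.matrix == "kappa":
            slot, i, j = "kappa", oi[p.row], xi[col]  # type: ignore[index]
            rexp, exoc = (0,) * d, ()
        elif p.matrix == "nu":
            slot, i, j = "nu", oi[p.row], 0
            rexp, exoc = (0,) * d, ()
        elif p.matrix == "alpha":
            if p.row in qi:
                continue  # validated fixed-zero in _select_quadrature
            slot, i, j = "a", ri[p.row], 0
            rexp, exoc = (0,) * d, ()
        elif p.matrix == "gamma":
            cols = col if isinstance(col, tuple) else (col,)
            slot, i, j = "a", ri[p.row], 0
            rexp = (0,) * d
            exoc = tuple(xi[c] for c in cols)
        elif p.matrix == "beta":
            cols = col if isinstance(col, tuple) else (col,)
            q_pow = [0] * d
            rem: list[str] = []
            exos: list[str] = []
            for c in cols:
                if c in qi:
                    q_pow[qi[c]] += 1
                elif c in ri:
                    rem.append(c)
                else:
                    exos.append(c)
            if len(rem) > 1:
                raise SpecError(f"product {cols} not linearized by "
                                f"quadrature set {qlat}")
            rexp = tuple(q_pow)
            exoc = tuple(xi[c] for c in exos)
            if rem:
                slot, i, j = "B", ri[p.row], ri[rem[0]]
            else:
                slot, i, j = "a", ri[p.row], 0
        elif p.matrix == "psi":
            assert isinstance(col, str)
            if p.row in qi and col in qi:
                if p.row != col:
                    continue  # fixed-zero cross covariance, validated
                slot, i, j = "psiQ", qi[p.row], 0
            elif p.row in qi or col in qi:
                continue      # fixed zero, validated
            else:
                a, b = ri[p.row], ri[col]
                slot, i, j = "psi", max(a, b), min(a, b)
            rexp, exoc = (0,) * d, ()
        elif p.matrix == "theta":
            assert isinstance(col, str)
            a, b = oi[p.row], oi[col]
            slot, i, j = "theta", max(a, b), min(a, b)
            rexp, exoc = (0,) * d, ()
        else:  # pragma: no cover
            raise SpecError(f"unhandled matrix {p.matrix}")

        is_var = slot in ("psiQ",) or (slot in ("psi", "theta") and i == j)
        pidx = free_index(p, is_var) if p.free else None
        if p.free and slot == "psi":
            psi_entries[p.label] = (i, j)  # type: ignore[index]
            if i != j:
                free_cov_edges.append((i, j, pidx))  # type: ignore[arg-type]
        placements.append(Placement(slot, i, j, pidx, p.value, rexp, exoc))

    # ----- cholesky blocks over rem-latent psi with free covariances -------
    blocks: list[CholBlock] = []
    if free_cov_edges:
        parent = list(range(len(rlat)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _ in free_cov_edges:
            parent[find(a)] = find(b)
        comps: dict[int, list[int]] = {}
        for v in range(len(rlat)):
            comps.setdefault(find(v), []).append(v)
        free_psi = {}
        for pl in placements:
            if pl.slot == "psi" and pl.pidx is not None:
                free_psi[(pl.i, pl.j)] = pl.pidx
        for members in comps.values():
            if len(members) < 2:
                continue
            ok = True
            for ii, a in enumerate(members):
                if (a, a) not in free_psi:
                    ok = False
                for b in members[:ii]:
                    hi, lo = max(a, b), min(a, b)
                    if (hi, lo) not in free_psi:
                        # undeclared pair => fixed 0; cholesky would free it
                        ok = False
            if not ok:
                continue
            local = {g: i for i, g in enumerate(sorted(members))}
            entries = {}
            for (hi, lo), pidx in free_psi.items():
                if hi in local and lo in local:
                    li, lj = local[hi], local[lo]
                    entries[(max(li, lj), min(li, lj))] = pidx
            blocks.append(CholBlock(latents=sorted(members), entries=entries))

    block_positions = set()
    for blk in blocks:
        block_positions.update(blk.entries.values())
    log_mask = np.array(
        [k == "var" and idx not in block_positions
         for idx, k in enumerate(kind)], dtype=bool)

    transform = ParamTransform(labels, log_mask, blocks)
    cm = CompiledModel(
        spec=spec, obs=obs, exo=exo, qlat=qlat, rlat=rlat,
        placements=placements, labels=labels,
        start_natural=np.array(start, float), transform=transform,
    )
    cm.subject_dep_B = any(pl.slot in ("B", "lambda") and pl.exo
                           for pl in placements)
    cm.node_dep_B = any(pl.slot in ("B", "lambda") and any(pl.rexp)
                        for pl in placements)
    return cm
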