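"""Observed-data container for SEM estimation.

Groups subjects by missingness pattern once, so the casewise (FIML)
likelihood can be evaluated pattern-by-pattern with vectorized linear
algebra.  Exogenous covariates are conditioned on and must be complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataError(ValueError):
    pass


@dataclass
class Pattern:
    """One missingness pattern: which observed columns are present."""

    obs_idx: np.ndarray   # indices into the observed-variable list
    rows: np.ndarray      # subject row indices sharing this pattern


@dataclass
class Dataset:
    observed_names: list[str]
    exogenous_names: list[str]
    Y: np.ndarray                 # (n, p) with NaN for missing
    X: np.ndarray                 # (n, k) complete
    patterns: list[Pattern] = field(default_factory=list)
    ids: np.ndarray | None = None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, observed: list[str],
                   exogenous: list[str] | None = None,
                   id_col: str | None = None) -> "Dataset":
        exogenous = list(exogenous or [])
        missing_cols = [c for c in observed + exogenous if c not in frame.columns]
        if missing_cols:
            raise DataError(f"columns absent from data: {missing_cols}")
        Y = frame[observed].to_numpy(dtype=float)
        X = (frame[exogenous].to_numpy(dtype=float)
             if exogenous else np.empty((len(frame), 0)))
        if X.size and not np.isfinite(X).all():
            bad = np.where(~np.isfinite(X))
            raise DataError(
                f"exogenous covariate {exogenous[bad[1][0]]!r} missing/non-finite "
                f"at row {bad[0][0]}"
            )
        ids = frame[id_col].to_numpy() if id_col else None
        ds = cls(list(observed), exogenous, Y, X, ids=ids)
        ds._index_patterns()
        return ds

    def _index_patterns(self) -> None:
        mask = np.isfinite(self.Y)
        if not mask.any(axis=1).all():
            bad = int(np.where(~mask.any(axis=1))[0][0])
            raise DataError(f"row {bad} has no observed endogenous values")
        # group rows by identical mask
        order = np.lexsort(mask.T[::-1])
        sorted_mask = mask[order]
        change = np.ones(len(order), dtype=bool)
        change[1:] = (sorted_mask[1:] != sorted_mask[:-1]).any(axis=1)
        starts = np.where(change)[0]
        bounds = list(starts) + [len(order)]
        self.patterns = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows = np.sort(order[s:e])
            obs_idx = np.where(mask[rows[0]])[0]
            self.patterns.append(Pattern(obs_idx=obs_idx, rows=rows))

    # ------------------------------------------------------------------ info
    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    def x_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample mean and ML (denominator n) covariance of covariates."""
        if self.X.shape[1] == 0:
            return np.zeros(0), np.zeros((0, 0))
        xm = self.X.mean(axis=0)
        xc = self.X - xm
        return xm, xc.T @ xc / self.n

    def complete(self) -> bool:
        return np.isfinite(self.Y).all()

    def sample_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Complete-data ML mean/covariance (requires no missingness)."""
        if not self.complete():
            raise DataError("sample_moments requires complete data")
        ym = self.Y.mean(axis=0)
        yc = self.Y - ym
        return ym, yc.T @ yc / self.n
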