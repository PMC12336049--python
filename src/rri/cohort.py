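"""Cohort container: baseline table, long-format visit table, optional truth.

Visit offsets T run from -3 to +3 around the first MRI with 18-month
spacing; T = 0 is the assessment closest to the first MRI scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIME_CODES: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
MONTHS_PER_VISIT = 18.0

BASELINE_COLUMNS = [
    "id", "sex_female", "age_first_mri", "apoe4_count", "education_years",
    "n_prior_assessments", "prior_interval_months", "withdrawn", "deceased",
    "gm_vol", "hippo_vol", "wmh_vol", "mem_composite", "centiloid",
]
VISIT_COLUMNS = ["id", "T", "months_from_first_mri", "ef"]


class CohortError(ValueError):
    pass


@dataclass
class Cohort:
    baseline: pd.DataFrame
    visits: pd.DataFrame
    truth: pd.DataFrame | None = None
    time_codes: tuple[int, ...] = TIME_CODES

    def __post_init__(self) -> None:
        self.validate()

    # ---------------------------------------------------------------- checks
    def validate(self) -> None:
        missing = [c for c in BASELINE_COLUMNS if c not in self.baseline.columns]
        if missing:
            raise CohortError(f"baseline table missing columns: {missing}")
        missing = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing:
            raise CohortError(f"visit table missing columns: {missing}")
        ids = self.baseline["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate subject id {dup!r} in baseline")
        bad_t = ~self.visits["T"].isin(self.time_codes)
        if bad_t.any():
            t = self.visits.loc[bad_t, "T"].iloc[0]
            raise CohortError(
                f"visit offset T={t} outside allowed range "
                f"{self.time_codes[0]}..{self.time_codes[-1]}")
        stray = set(self.visits["id"]) - set(ids)
        if stray:
            raise CohortError(f"visit rows for unknown subject ids: "
                              f"{sorted(stray)[:5]}")
        no_visit = set(ids) - set(self.visits["id"])
        if no_visit:
            raise CohortError(
                f"subjects without any EF observation: {sorted(no_visit)[:5]}")
        if self.visits.duplicated(["id", "T"]).any():
            raise CohortError("duplicate (id, T) rows in visit table")
        for col, allowed in (("sex_female", (0, 1)),
                             ("apoe4_count", (0, 1, 2)),
                             ("withdrawn", (0, 1)),
                             ("deceased", (0, 1))):
            vals = self.baseline[col]
            bad = ~vals.isin(allowed)
            if bad.any():
                sid = self.baseline.loc[bad, "id"].iloc[0]
                raise CohortError(
                    f"{col}={vals[bad].iloc[0]!r} out of domain {allowed} "
                    f"for subject {sid!r}")
        for col in ("gm_vol", "hippo_vol", "wmh_vol", "mem_composite"):
            vals = self.baseline[col].to_numpy(float)
            if not np.isfinite(vals[~np.isnan(vals)]).all():
                raise CohortError(f"non-finite values in {col}")

    # ------------------------------------------------------------ utilities
    @property
    def n(self) -> int:
        return len(self.baseline)

    def ef_wide(self) -> pd.DataFrame:
        """Baseline joined with EF columns ef_m3..ef_p3 (NaN = missing)."""
        wide = self.visits.pivot(index="id", columns="T", values="ef")
        wide = wide.reindex(columns=list(self.time_codes))
        wide.columns = [ef_column(t) for t in self.time_codes]
        out = self.baseline.set_index("id").join(wide).reset_index()
        return out

    def equals(self, other: "Cohort", rtol: float = 0.0, atol: float = 0.0
               ) -> bool:
        pairs = [
            (self.baseline.sort_values("id").reset_index(drop=True),
             other.baseline.sort_values("id").reset_index(drop=True)),
            (self.visits.sort_values(["id", "T"]).reset_index(drop=True),
             other.visits.sort_values(["id", "T"]).reset_index(drop=True)),
        ]
        for a, b in pairs:
            if len(a) != len(b) or set(a.columns) - set(b.columns):
                return False
            for col in a.columns:
                x = a[col].to_numpy()
                y = b[col].to_numpy()
                if np.issubdtype(x.dtype, np.number):
                    if not np.allclose(np.asarray(x, float),
                                       np.asarray(y, float),
                                       rtol=rtol, atol=atol,
                                       equal_nan=True):
                        return False
                elif not (x == y).all():
                    return False
        return True

    def copy(self) -> "Cohort":
        return Cohort(self.baseline.copy(), self.visits.copy(),
                      None if self.truth is None else self.truth.copy(),
                      self.time_codes)


def ef_column(t: int) -> str:
    return f"ef_{'m' if t < 0 else 'p'}{abs(t)}"
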