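"""Read, validate and write cohort tables; Table-1-style descriptives.

CSV dialect: comma-separated, UTF-8, header row, "." decimal, missing
values encoded as empty fields; floats written at 15 significant digits so
finite doubles round-trip.  A JSON sidecar documents the columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (BASELINE_COLUMNS, VISIT_COLUMNS, Cohort, CohortError,
                     TIME_CODES)

_FLOAT_FMT = "%.15g"

COLUMN_DICTIONARY = {
    "baseline": {
        "id": "unique subject identifier",
        "sex_female": "sex (0 = male, 1 = female)",
        "age_first_mri": "age in years at the first MRI scan",
        "apoe4_count": "number of APOE e4 alleles (0/1/2)",
        "education_years": "years of education",
        "n_prior_assessments": "cognitive assessments before the first MRI",
        "prior_interval_months": "months between first cognitive assessment "
                                 "and first MRI",
        "withdrawn": "withdrew from the study (0/1)",
        "deceased": "died during follow-up (0/1)",
        "gm_vol": "ICV-adjusted grey-matter volume (mm^3 x10^3)",
        "hippo_vol": "ICV-adjusted hippocampal volume (mm^3 x10^3)",
        "wmh_vol": "ICV-normalized white-matter-hyperintensity volume",
        "mem_composite": "episodic-memory composite (AIBL-Mem scale)",
        "centiloid": "PET amyloid burden, Centiloid scale (may be missing)",
    },
    "visits": {
        "id": "subject identifier (matches baseline)",
        "T": "visit offset from first MRI in 18-month units (-3..3)",
        "months_from_first_mri": "months between visit and first MRI",
        "ef": "executive-function composite (AIBL-EF scale)",
    },
}


def write_cohort(cohort: Cohort, out_dir, *, truth: bool = True) -> dict:
    """Write baseline.csv, visits.csv (+ truth.csv) and a column sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "baseline": out / "baseline.csv",
        "visits": out / "visits.csv",
        "dictionary": out / "columns.json",
    }
    cohort.baseline.to_csv(paths["baseline"], index=False,
                           float_format=_FLOAT_FMT)
    cohort.visits.to_csv(paths["visits"], index=False,
                         float_format=_FLOAT_FMT)
    with open(paths["dictionary"], "w") as fh:
        json.dump(COLUMN_DICTIONARY, fh, indent=2)
    if truth and cohort.truth is not None:
        paths["truth"] = out / "truth.csv"
        cohort.truth.to_csv(paths["truth"], index=False,
                            float_format=_FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(baseline_path, visits_path, truth_path=None) -> Cohort:
    """Read and validate cohort tables; missing values stay missing."""
    for path in (baseline_path, visits_path):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    baseline = pd.read_csv(baseline_path, float_precision="round_trip")
    visits = pd.read_csv(visits_path, float_precision="round_trip")
    missing = [c for c in BASELINE_COLUMNS if c not in baseline.columns]
    if missing:
        raise CohortError(
            f"{baseline_path}: missing baseline columns {missing}")
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise CohortError(f"{visits_path}: missing visit columns {missing}")
    truth = (pd.read_csv(truth_path, float_precision="round_trip")
             if truth_path else None)
    return Cohort(baseline=baseline, visits=visits, truth=truth)


# ---------------------------------------------------------------------------
# descriptives (Table-1-style)
# ---------------------------------------------------------------------------

_CONTINUOUS = [
    ("age_first_mri", "Age (years) at first MRI"),
    ("education_years", "Education (years)"),
    ("n_prior_assessments", "# assessments before first MRI"),
    ("prior_interval_months", "Months between first assessment and MRI"),
    ("gm_vol", "Grey matter volume"),
    ("hippo_vol", "Hippocampal volume"),
    ("wmh_vol", "WMH volume"),
    ("mem_composite", "Memory composite"),
    ("ef_baseline", "Executive function composite"),
    ("centiloid", "Amyloid burden (Centiloid)"),
]
_CATEGORICAL = [
    ("apoe4_count", "APOE e4 allele count"),
    ("withdrawn", "Withdrawn"),
    ("deceased", "Deceased"),
]


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """Unweighted-by-group pooled SD (Cohen-d convention, ddof=1)."""
    return float(np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0))


def smd(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute standardized mean difference |m_a - m_b| / pooled SD."""
    s = pooled_sd(a, b)
    if s == 0:
        return 0.0
    return float(abs(np.mean(a) - np.mean(b)) / s)


def descriptives(cohort: Cohort) -> pd.DataFrame:
    """Sex-stratified summary: means/SDs or counts, p-values and SMDs.

    Continuous variables: two-sample t-test and Cohen-style SMD;
    categorical: chi-square test and a proportion-based SMD for binary
    variables.  With a single-sex cohort the stratified columns are
    suppressed with a warning.
    """
    import warnings

    if cohort.n == 0:
        raise CohortError("empty cohort")
    df = cohort.baseline.copy()
    ef0 = cohort.visits.loc[cohort.visits["T"] == 0].set_index("id")["ef"]
    df["ef_baseline"] = df["id"].map(ef0)

    both_sexes = df["sex_female"].nunique() == 2
    if not both_sexes:
        warnings.warn("single-sex cohort: stratified columns suppressed")
    male = df[df["sex_female"] == 0]
    female = df[df["sex_female"] == 1]

    rows = []
    for col, label in _CONTINUOUS:
        x = df[col].dropna().to_numpy(float)
        if x.size == 0:
            continue
        row = {"variable": label, "type": "continuous",
               "overall_mean": x.mean(), "overall_sd": x.std(ddof=1)}
        if both_sexes:
            xm = male[col].dropna().to_numpy(float)
            xf = female[col].dropna().to_numpy(float)
            row.update(
                male_mean=xm.mean(), male_sd=xm.std(ddof=1),
                female_mean=xf.mean(), female_sd=xf.std(ddof=1),
                p=float(stats.ttest_ind(xm, xf, equal_var=True).pvalue),
                smd=smd(xf, xm),
            )
        rows.append(row)
    for col, label in _CATEGORICAL:
        x = df[col].to_numpy()
        row = {"variable": label, "type": "categorical",
               "overall_mean": float(np.mean(x)),
               "overall_sd": float(np.std(x, ddof=1))}
        if both_sexes:
            tab = pd.crosstab(df["sex_female"], df[col])
            if tab.shape[1] > 1:
                chi2 = stats.chi2_contingency(tab.to_numpy())
                row["p"] = float(chi2.pvalue)
            else:
                row["p"] = 1.0
            xm = male[col].to_numpy(float)
            xf = female[col].to_numpy(float)
            row["male_mean"] = xm.mean()
            row["female_mean"] = xf.mean()
            row["smd"] = smd(xf, xm)
        rows.append(row)
    return pd.DataFrame(rows)
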