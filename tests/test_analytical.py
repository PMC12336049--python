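"""Joint moderation model: spec shape, probing algebra, invariances."""

import warnings

import numpy as np
import pytest

from rri.analytical import (AnalyticalError, build_analytical_spec,
                            fit_analytical, predict_trajectories,
                            simple_slopes)
from rri.analytical import test_fourway as extract_fourway
from rri.analytical import test_threeway as extract_threeway
from rri.config import AnalysisConfig
from rri.sem import Dataset, Evaluator, compile_spec
from rri.decomposition import decompose
from rri.growth import build_growth_spec, growth_dataset, growth_starts
from rri.sem import FitOptions, fit_ml


def _structural_count(spec, outcome):
    return sum(1 for p in spec.params
               if p.matrix in ("beta", "gamma") and p.row == outcome)


def test_structural_predictor_counts():
    spec = build_analytical_spec(include_amyloid=False)
    # 11 published predictors + the MEMD composite equation lives elsewhere
    assert _structural_count(spec, "I") == 11
    assert _structural_count(spec, "slope") == 11
    spec_ab = build_analytical_spec(include_amyloid=True)
    assert _structural_count(spec_ab, "I") == 21
    assert _structural_count(spec_ab, "slope") == 21


def test_nesting_reduces_to_separate_stage_fits(small_cohort, fast_analysis):
    """All structural paths fixed at zero: the joint likelihood factorizes
    into the decomposition and growth likelihoods (complete-data blocks)."""
    spec = build_analytical_spec()
    for p in spec.params:
        if p.matrix in ("beta", "gamma") and p.row in ("I", "slope"):
            p.free = False
            p.value = 0.0
    from rri.analytical import prepare_analytical_frame

    frame, _ = prepare_analytical_frame(small_cohort)
    cm = compile_spec(spec)
    data = Dataset.from_frame(frame, cm.obs, cm.exo, id_col="id")
    opts = FitOptions(compute_se=False, n_nodes=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        joint = fit_ml(cm, data, options=opts)
        dec = decompose(small_cohort, options=opts)
        gdata = growth_dataset(small_cohort)
        growth = fit_ml(build_growth_spec("linear"), gdata,
                        start=growth_starts(gdata), options=opts)
    assert abs(joint.loglik - (dec.fit.loglik + growth.loglik)) < 1e-2


def test_male_only_cohort_raises(small_cohort, fast_analysis):
    solo = small_cohort.copy()
    keep = solo.baseline.sex_female == 0
    ids = set(solo.baseline.loc[keep, "id"])
    solo.baseline = solo.baseline[keep].reset_index(drop=True)
    solo.visits = solo.visits[solo.visits.id.isin(ids)].reset_index(drop=True)
    from rri.cohort import Cohort

    solo2 = Cohort(solo.baseline, solo.visits)
    with pytest.raises(AnalyticalError, match="single-sex"):
        fit_analytical(solo2, config=fast_analysis)


def test_coefficient_table_z_identity(small_joint_fit):
    tab = small_joint_fit.coefficient_table()
    ratio = tab.est / tab.se
    np.testing.assert_allclose(tab.est_se, ratio, rtol=1e-10)
    assert ((tab.p >= 0) & (tab.p <= 1)).all()


def test_threeway_extraction(small_joint_fit):
    tests = extract_threeway(small_joint_fit)
    assert {t.outcome for t in tests} == {"intercept", "slope"}
    for t in tests:
        assert abs(t.z - t.est / t.se) < 1e-10
    with pytest.raises(AnalyticalError):
        extract_fourway(small_joint_fit)


def test_simple_slopes_closed_form(small_joint_fit):
    ss = simple_slopes(small_joint_fit)
    est = small_joint_fit.fit.estimates_dict()
    sd_b = small_joint_fit.memb_sd
    for _, row in ss.iterrows():
        o = "I" if row.outcome == "intercept" else "slope"
        expect = (est[f"{o}:MEMR"]
                  + est[f"{o}:MEMR_x_MEMB"] * row.memb_level * sd_b
                  + est[f"{o}:MEMR_x_female"] * row.female
                  + est[f"{o}:MEMR_x_MEMB_x_female"]
                  * row.memb_level * sd_b * row.female)
        assert abs(row.simple_slope - expect) < 1e-12
    # no-interaction degenerate check: zero the interaction coefficients
    res = small_joint_fit
    idx = {lab: i for i, lab in enumerate(res.fit.labels)}
    saved = res.fit.estimates.copy()
    try:
        for o in ("I", "slope"):
            for term in ("MEMR_x_MEMB", "MEMR_x_female",
                         "MEMR_x_MEMB_x_female"):
                res.fit.estimates[idx[f"{o}:{term}"]] = 0.0
        flat = simple_slopes(res)
        for o, block in (("I", "intercept"), ("slope", "slope")):
            vals = flat[flat.outcome == block].simple_slope
            np.testing.assert_allclose(vals, res.fit.estimates[
                idx[f"{o}:MEMR"]])
    finally:
        res.fit.estimates = saved


def test_trajectories_at_t0_equal_intercept(small_joint_fit):
    traj = predict_trajectories(small_joint_fit)
    at0 = traj[traj["T"] == 0]
    # T=0 prediction must equal the model-implied intercept for the cell:
    # recompute one cell by hand
    est = small_joint_fit.fit.estimates_dict()
    sd_b = small_joint_fit.memb_sd
    sd_r = small_joint_fit.memr_sd
    cell = at0[(at0.female == 1.0) & (at0.memb_level == -1.0)
               & (at0.memr_level == 1.0)].iloc[0]
    expect = est["mean_I"]
    vals = {"MEMR": sd_r, "MEMB": -sd_b, "female": 1.0}
    from rri.synthetic import _TERM_DEFS

    for lab in small_joint_fit.labels:
        t = _TERM_DEFS[lab]
        v = 1.0
        if t.rpow[0]:
            v *= vals["MEMR"]
        if t.rem:
            v *= vals["MEMB"]
        for c in t.exo:
            v *= vals.get(c, 0.0)
        expect += est[f"I:{lab}"] * v
    assert abs(cell.predicted_ef - expect) < 1e-10
    # grid shape: 2 sexes x 3 x 3 x 7 time points
    assert len(traj) == 2 * 3 * 3 * 7


def test_female_low_brain_reserve_gap_direction(small_joint_fit):
    """With the published effects planted, the high-vs-low reserve slope
    gap in the low-brain cell is larger for females than males."""
    traj = predict_trajectories(small_joint_fit)

    def slope_of(female, mb, mr):
        sub = traj[(traj.female == female) & (traj.memb_level == mb)
                   & (traj.memr_level == mr)].sort_values("T")
        y = sub.predicted_ef.to_numpy()
        return np.polyfit(sub["T"].to_numpy(), y, 1)[0]

    gap_f = slope_of(1.0, -1.0, 1.0) - slope_of(1.0, -1.0, -1.0)
    gap_m = slope_of(0.0, -1.0, 1.0) - slope_of(0.0, -1.0, -1.0)
    assert gap_f > gap_m
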