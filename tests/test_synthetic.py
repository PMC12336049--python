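"""Cohort generator: marginals, planted truth, attrition, determinism."""

import numpy as np
import pandas as pd
import pytest

from rri.config import (AttritionConfig, ConfigError, GeneratorConfig,
                        PlantedTruth, MAIN_MODEL_BETAS)
from rri.moments import Term, term_cov_matrix
from rri.synthetic import (DemographicModel, PopulationExoMoments,
                           apply_attrition, generate_cohort, ols_recovery,
                           solve_structural, truth_report)


def test_config_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(apoe_probs=(0.5, 0.4, 0.2)).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(n_subjects=0).validate()
    with pytest.raises(ConfigError):
        GeneratorConfig(age_sd=-1.0).validate()
    bad = PlantedTruth(brain_corr=(0.99, -0.99, 0.99))
    with pytest.raises(ConfigError, match="positive definite"):
        GeneratorConfig(planted=bad).validate()


def test_overparameterized_betas_rejected():
    betas = dict(MAIN_MODEL_BETAS)
    betas["MEMB"] = (0.9, 0.9)
    betas["MEMR"] = (0.9, 0.9)
    betas["MEMD"] = (0.9, 0.9)
    cfg = GeneratorConfig(
        planted=PlantedTruth(structural_betas=betas))
    with pytest.raises(ConfigError, match="explained variance"):
        solve_structural(cfg)


def test_marginals_match_configuration(default_cohort, default_config):
    b = default_cohort.baseline
    n = len(b)
    cfg = default_config
    # each sample mean within ~3 standard errors of the target
    checks = [
        (b.age_first_mri, cfg.age_mean, cfg.age_sd),
        (b.gm_vol, cfg.gm_mean, cfg.gm_sd),
        (b.hippo_vol, cfg.hippo_mean, cfg.hippo_sd),
        (b.mem_composite, cfg.mem_mean, cfg.mem_sd),
        (b.centiloid, cfg.centiloid_mean, cfg.centiloid_sd),
    ]
    for col, mean, sd in checks:
        assert abs(col.mean() - mean) < 3.5 * sd / np.sqrt(n)
    assert abs(b.sex_female.mean() - cfg.prop_female) < 3.5 * 0.5 / np.sqrt(n)
    counts = b.apoe4_count.value_counts(normalize=True)
    for k, p in enumerate(cfg.apoe_probs):
        assert abs(counts.get(k, 0.0) - p) < 3.5 * np.sqrt(p * (1 - p) / n)
    # WMH right-skewed on the raw scale
    w = b.wmh_vol
    assert w.min() > 0
    assert w.skew() > 1.0


def test_memr_orthogonal_to_other_components(default_cohort):
    t = default_cohort.truth
    n = len(t)
    assert abs(np.corrcoef(t.memr, t.memb)[0, 1]) < 3 / np.sqrt(n)
    assert abs(np.corrcoef(t.memr, t.memd)[0, 1]) < 3 / np.sqrt(n)


def test_seed_reproducibility(default_config):
    a = generate_cohort(default_config)
    b = generate_cohort(default_config)
    assert a.equals(b)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_zero_effects_zero_noise_trajectories_flat():
    betas = {k: (0.0, 0.0) for k in MAIN_MODEL_BETAS}
    planted = PlantedTruth(structural_betas=betas,
                           intercept_resid_var=1e-12,
                           slope_resid_var=1e-12,
                           slope_intercept_cov=0.0,
                           ef_residual_var=1e-12)
    cfg = GeneratorConfig(n_subjects=50, planted=planted, attrition=None,
                          ef_slope_mean=0.0, seed=3)
    c = generate_cohort(cfg)
    wide = c.visits.pivot(index="id", columns="T", values="ef")
    arr = wide.to_numpy()
    arr = arr[np.isfinite(arr).all(axis=1)]
    # flat in T and identical across subjects (up to the ~1e-6 noise floor)
    assert np.nanstd(arr) < 1e-4


def test_attrition_identity_when_disabled(default_config):
    cfg = GeneratorConfig(**{**default_config.to_dict_shallow(),
                             "attrition": None})
    c = generate_cohort(cfg)
    null_att = AttritionConfig(base_dropout_hazard=0.0, death_prob=0.0)
    c2 = apply_attrition(c, null_att, seed=9)
    assert c2.equals(c)


def test_attrition_sign_check_and_death_rates():
    cfg = GeneratorConfig(
        n_subjects=10_000, seed=11,
        attrition=AttritionConfig(base_dropout_hazard=0.15,
                                  hazard_load_intercept=0.0,
                                  hazard_load_slope=-1.0,
                                  death_prob=0.034,
                                  male_death_multiplier=2.32))
    c = generate_cohort(cfg)
    nv = c.visits.groupby("id").size()
    truth = c.truth.set_index("id")
    r = np.corrcoef(nv, truth.loc[nv.index, "slope"])[0, 1]
    assert r > 0.0
    b = c.baseline
    male = b[b.sex_female == 0].deceased.mean()
    female = b[b.sex_female == 1].deceased.mean()
    assert male > female


def test_monotone_missingness(default_cohort):
    """No gaps after dropout among post-baseline visits."""
    for _, grp in default_cohort.visits.groupby("id"):
        post = sorted(grp.loc[grp["T"] >= 0, "T"])
        assert post == list(range(0, len(post)))


def test_truth_report_rows_and_zeroing(default_config):
    tr = truth_report(default_config)
    row = tr[tr.term == "MEMR_x_MEMB_x_female"].iloc[0]
    assert row.slope == -0.069
    assert row.intercept == -0.190
    zero = GeneratorConfig(planted=PlantedTruth(
        structural_betas={k: (0.0, 0.0) for k in MAIN_MODEL_BETAS}))
    tz = truth_report(zero)
    assert (tz[["intercept", "slope"]].to_numpy() == 0).all()


def test_ols_oracle_recovers_planted_betas():
    cfg = GeneratorConfig(n_subjects=100_000, seed=100, attrition=None)
    rec = ols_recovery(generate_cohort(cfg), cfg)
    tr = truth_report(cfg)
    m = rec.merge(tr, on="term", suffixes=("_est", "_true"))
    assert (m.intercept_est - m.intercept_true).abs().max() < 0.01
    assert (m.slope_est - m.slope_true).abs().max() < 0.01


def test_memr_slope_effect_recovered_large_n():
    cfg = GeneratorConfig(n_subjects=50_000, seed=4, attrition=None)
    rec = ols_recovery(generate_cohort(cfg), cfg).set_index("term")
    assert abs(rec.loc["MEMR", "slope"] - 0.028) < 0.005


def test_population_predictor_moments_match_monte_carlo():
    """Closed-form term covariances vs simulated predictor columns."""
    cfg = GeneratorConfig(n_subjects=200_000, seed=8, attrition=None)
    sol = solve_structural(cfg)
    c = generate_cohort(cfg)
    t, b = c.truth, c.baseline
    from rri.synthetic import _term_columns

    cols = {
        "female": b.sex_female.to_numpy(float),
        "apoe4": b.apoe4_count.to_numpy(float),
        "age_c": b.age_first_mri.to_numpy(float) - 70.0,
        "centiloid": b.centiloid.to_numpy(float),
        "MEMD": t.memd.to_numpy(),
    }
    P = _term_columns(sol, t.memr.to_numpy(), t.memb.to_numpy(), cols)
    S_emp = np.cov(P.T, bias=True)
    scale = np.sqrt(np.outer(np.diag(sol.cov_P), np.diag(sol.cov_P)))
    np.testing.assert_allclose(sol.cov_P / scale, S_emp / scale, atol=0.02)


def test_sex_shift_puts_reserve_advantage_in_memr():
    planted = PlantedTruth(memr_sex_shift=0.25)
    cfg = GeneratorConfig(n_subjects=5000, planted=planted, seed=6)
    c = generate_cohort(cfg)
    t = c.truth.merge(c.baseline[["id", "sex_female"]], on="id")
    f = t[t.sex_female == 1].memr.mean()
    m = t[t.sex_female == 0].memr.mean()
    assert f - m > 0.15
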