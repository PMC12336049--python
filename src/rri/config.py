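"""Configuration objects for the cohort generator and the analysis pipeline.

Generator defaults reproduce the marginal structure of the study cohort
(n = 997 older adults, 55.4 % female) and plant the published standardized
structural effects as ground truth, so that every downstream stage can be
checked against known values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# ---------------------------------------------------------------------------
# planted standardized structural effects (intercept, slope) per predictor
# ---------------------------------------------------------------------------

MAIN_MODEL_BETAS: dict[str, tuple[float, float]] = {
    "MEMR": (0.413, 0.028),
    "MEMB": (0.628, 0.123),
    "MEMD": (0.268, 0.025),
    "female": (0.016, 0.000),
    "apoe4": (0.040, -0.044),
    "age_c": (-0.008, 0.002),
    "female_x_apoe4": (0.033, 0.012),
    "MEMR_x_MEMB": (-0.110, 0.007),
    "MEMR_x_female": (-0.047, 0.009),
    "MEMB_x_female": (-0.039, -0.004),
    "MEMR_x_MEMB_x_female": (-0.190, -0.069),
}

AMYLOID_MODEL_BETAS: dict[str, tuple[float, float]] = {
    "MEMR": (0.409, -0.005),
    "MEMB": (0.568, 0.066),
    "MEMD": (0.264, 0.021),
    "female": (-0.008, -0.013),
    "centiloid": (0.000, 0.000),
    "apoe4": (-0.117, -0.030),
    "age_c": (-0.009, 0.002),
    "MEMR_x_MEMB": (-0.107, 0.047),
    "MEMR_x_female": (-0.075, 0.035),
    "MEMR_x_centiloid": (0.001, 0.000),
    "MEMB_x_female": (0.052, 0.037),
    "MEMB_x_centiloid": (0.003, 0.001),
    "female_x_centiloid": (-0.001, 0.000),
    "female_x_apoe4": (0.121, 0.019),
    "centiloid_x_apoe4": (0.004, 0.000),
    "MEMR_x_MEMB_x_female": (-0.142, -0.105),
    "MEMR_x_MEMB_x_centiloid": (0.001, 0.000),
    "MEMR_x_female_x_centiloid": (0.001, 0.000),
    "MEMB_x_female_x_centiloid": (-0.003, -0.001),
    "female_x_centiloid_x_apoe4": (-0.002, 0.000),
    "MEMR_x_MEMB_x_female_x_centiloid": (-0.001, 0.000),
}


class ConfigError(ValueError):
    pass


@dataclass
class AttritionConfig:
    """Dropout process after the first-MRI visit.

    Non-deceased subjects face a per-visit hazard scaled by their
    standardized executive-function intercept and slope (negative loadings:
    better and more stable cognition means longer retention, matching the
    observation that completers start higher and decline less).  Death is a
    sex-dependent Bernoulli with a male excess.
    """

    base_dropout_hazard: float = 0.098
    hazard_load_intercept: float = -0.25
    hazard_load_slope: float = -0.25
    death_prob: float = 0.034            # female rate; male = rate * multiplier
    male_death_multiplier: float = 2.32
    intermittent_prob: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.base_dropout_hazard <= 1.0:
            raise ConfigError("base_dropout_hazard must be in [0, 1]")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ConfigError("death_prob must be in [0, 1]")
        if self.male_death_multiplier <= 0:
            raise ConfigError("male_death_multiplier must be positive")
        if self.death_prob * self.male_death_multiplier > 1.0:
            raise ConfigError("male death probability exceeds 1")
        if not 0.0 <= self.intermittent_prob < 1.0:
            raise ConfigError("intermittent_prob must be in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground-truth latent structure planted by the generator.

    Variances are on the standardized memory scale, where the fixed
    measurement-error constraints (0.10 per brain indicator, 0.1365 for the
    memory composite) are defined; the default components sum to 1 so the
    standardized-scale decomposition recovers them directly.
    """

    brain_reliability: float = 0.90
    mem_error_var: float = 0.1365
    memr_var: float = 0.30
    memb_var: float = 0.40
    memd_var: float = 0.1635
    structural_betas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MAIN_MODEL_BETAS))
    intercept_resid_var: float = 0.22
    slope_resid_var: float = 0.0117
    slope_intercept_cov: float = 0.010
    ef_residual_var: float = 0.127
    memr_sex_shift: float = 0.0
    brain_weight_dir: tuple[float, float, float] = (0.45, 0.55, -0.15)
    brain_corr: tuple[float, float, float] = (0.50, -0.30, -0.25)
    # demographic signal direction: education, n prior assessments,
    # prior interval, n-prior x interval (standardized columns)
    demo_weight_dir: tuple[float, float, float, float] = (0.75, 0.35, 0.20, 0.10)

    def validate(self) -> None:
        for name in ("mem_error_var", "memr_var", "memb_var", "memd_var",
                     "intercept_resid_var", "slope_resid_var",
                     "ef_residual_var"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 < self.brain_reliability <= 1.0:
            raise ConfigError("brain_reliability must be in (0, 1]")
        c = self.slope_intercept_cov
        if c * c >= self.intercept_resid_var * self.slope_resid_var:
            raise ConfigError("slope/intercept residual covariance implies a "
                              "non-positive-definite residual matrix")
        R = np.eye(3)
        R[0, 1] = R[1, 0] = self.brain_corr[0]
        R[0, 2] = R[2, 0] = self.brain_corr[1]
        R[1, 2] = R[2, 1] = self.brain_corr[2]
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ConfigError("brain indicator correlation matrix is not "
                              "positive definite")


@dataclass
class GeneratorConfig:
    """Marginal and structural parameters of the synthetic cohort."""

    n_subjects: int = 997
    prop_female: float = 552.0 / 997.0
    apoe_probs: tuple[float, float, float] = (0.651, 0.292, 0.057)
    age_mean: float = 72.79
    age_sd: float = 6.60
    edu_mean: float = 12.95
    edu_sd: float = 3.07
    # per-sex education (male, female); None falls back to edu_mean/edu_sd
    edu_by_sex: tuple[tuple[float, float], tuple[float, float]] | None = (
        (13.33, 3.18), (12.63, 2.95))
    gm_mean: float = 454.17
    gm_sd: float = 25.32
    hippo_mean: float = 5.70
    hippo_sd: float = 0.72
    wmh_mean: float = 9.36
    wmh_sd: float = 13.41
    wmh_lognormal: bool = True
    centiloid_mean: float = 28.78
    centiloid_sd: float = 42.83
    centiloid_missing_prob: float = 0.0
    mem_mean: float = 0.50
    mem_sd: float = 0.91
    ef_intercept_mean: float = 0.82
    ef_slope_mean: float = -0.01
    n_prior_mean: float = 1.34          # previous assessments before first MRI
    prior_interval_per_visit: float = 18.0
    prior_interval_jitter_sd: float = 0.40
    planted: PlantedTruth = field(default_factory=PlantedTruth)
    attrition: AttritionConfig | None = field(default_factory=AttritionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError("prop_female must be in [0, 1]")
        if abs(sum(self.apoe_probs) - 1.0) > 1e-12:
            raise ConfigError("apoe_probs must sum to 1")
        if min(self.apoe_probs) < 0:
            raise ConfigError("apoe_probs must be non-negative")
        for name in ("age_sd", "edu_sd", "gm_sd", "hippo_sd", "wmh_sd",
                     "centiloid_sd", "mem_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_prior_mean <= 0:
            raise ConfigError("n_prior_mean must be > 0")
        self.planted.validate()
        if self.attrition is not None:
            self.attrition.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_dict_shallow(self) -> dict:
        """Field dict keeping nested config objects by reference."""
        return dict(self.__dict__)


@dataclass
class AnalysisConfig:
    """Options of the estimation pipeline."""

    time_unit: str = "visit"             # slope per 18-month visit interval
    age_center: float = 70.0
    growth_forms: tuple[str, ...] = ("linear", "quadratic", "logarithmic")
    quadrature_nodes: int = 15
    adaptive_quadrature: bool = True
    gtol: float = 1e-5
    ll_rtol: float = 1e-8
    include_amyloid: bool = False
    std_binary: str = "stdyx"            # or "stdy": binary covariates raw
    rmsea_n_convention: str = "n"        # or "n-1"
    score_method: str = "bartlett"
    seed: int = 0

    def validate(self) -> None:
        if self.quadrature_nodes < 3:
            raise ConfigError("quadrature_nodes must be >= 3")
        if self.gtol <= 0 or self.ll_rtol <= 0:
            raise ConfigError("tolerances must be > 0")
        if self.time_unit not in ("visit", "month"):
            raise ConfigError("time_unit must be 'visit' or 'month'")
        if self.std_binary not in ("stdyx", "stdy"):
            raise ConfigError("std_binary must be 'stdyx' or 'stdy'")
        if self.rmsea_n_convention not in ("n", "n-1"):
            raise ConfigError("rmsea_n_convention must be 'n' or 'n-1'")
        unknown = set(self.growth_forms) - {"linear", "quadratic",
                                            "logarithmic"}
        if unknown:
            raise ConfigError(f"unknown growth forms: {sorted(unknown)}")
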