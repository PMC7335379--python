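"""Per-tendon read-out generation with the study's effect structure.

The generative model inverts the fitted regression layer:

* relative surface area at 48 h: affine in age (plus optional gender and
  tendon terms) with Gaussian noise;
* pro-collagen I: a logistic step between a high (young) and low (old)
  plateau centered at the threshold age, with Gaussian noise;
* intact/released: Bernoulli with logit(intact) linear in age, gender and
  tendon type;
* tenomodulin/tubulin and alpha-SMA/tubulin: age-independent lognormal;
* active MMP2 intensity: affine in age with Gaussian noise; MMP2 active
  fraction: Gaussian clipped to [0, 1].

Released tendons receive missing values for all post-release biochemical
read-outs, mirroring the exclusion of released micro-tissues from further
analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .cohort import PatientRecord, generate_cohort
from .params import PROCOL_TRANSITION_WIDTH_Y, CohortParams, EffectParams

BIOCHEM_COLUMNS = (
    "pro_collagen_ng_ml",
    "tenomodulin_ratio",
    "asma_ratio",
    "mmp2_active_au",
    "mmp2_active_fraction",
)


def _covariates(cohort: list[PatientRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    age = np.array([r.age_y for r in cohort])
    male = np.array([1.0 if r.gender == "M" else 0.0 for r in cohort])
    semit = np.array([1.0 if r.tendon == "ST" else 0.0 for r in cohort])
    return age, male, semit


def procollagen_mean(age: np.ndarray, effects: EffectParams) -> np.ndarray:
    """Noise-free pro-collagen concentration (ng/ml) at the given ages."""
    step = expit((effects.procol_threshold_age - np.asarray(age)) / PROCOL_TRANSITION_WIDTH_Y)
    return effects.procol_low_plateau + (
        effects.procol_high_plateau - effects.procol_low_plateau
    ) * step


def intact_logit(age, male, semit, effects: EffectParams) -> np.ndarray:
    return (
        effects.release_intercept
        + effects.release_age_coef * np.asarray(age)
        + effects.release_male_coef * np.asarray(male)
        + effects.release_semitend_coef * np.asarray(semit)
    )


def generate_readouts(
    cohort: list[PatientRecord], effects: EffectParams, seed: int
) -> pd.DataFrame:
    """Simulate one read-out table (one row per tendon) for a cohort."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(seed)
    age, male, semit = _covariates(cohort)
    n = len(cohort)

    rel_area = (
        effects.area_intercept
        + effects.area_age_slope * age
        + effects.area_gender_coef * male
        + effects.area_tendon_coef * semit
        + rng.normal(0.0, effects.area_noise_sd, n)
    )
    intact = rng.random(n) < expit(intact_logit(age, male, semit, effects))
    procol = procollagen_mean(age, effects) + rng.normal(0.0, effects.procol_noise_sd, n)
    mu_a, sd_a = effects.asma_lognormal_params
    asma = rng.lognormal(mu_a, sd_a, n)
    mu_t, sd_t = effects.tnmd_lognormal_params
    tnmd = rng.lognormal(mu_t, sd_t, n)
    mmp2 = (
        effects.mmp2_intensity_intercept
        + effects.mmp2_intensity_age_slope * age
        + rng.normal(0.0, effects.mmp2_intensity_noise_sd, n)
    )
    frac = np.clip(
        rng.normal(effects.mmp2_active_fraction_mean, effects.mmp2_active_fraction_sd, n),
        0.0,
        1.0,
    )

    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in cohort],
            "tendon_id": [r.tendon_id for r in cohort],
            "age_y": age,
            "gender": [r.gender for r in cohort],
            "tendon": [r.tendon for r in cohort],
            "relative_area_pct": rel_area,
            "intact": intact.astype(int),
            "pro_collagen_ng_ml": procol,
            "tenomodulin_ratio": tnmd,
            "asma_ratio": asma,
            "mmp2_active_au": mmp2,
            "mmp2_active_fraction": frac,
        }
    )
    df.loc[~intact, list(BIOCHEM_COLUMNS)] = np.nan
    return df


def solve_release_intercept(
    effects: EffectParams,
    cohort_params: CohortParams | None = None,
    target_release_rate: float = 10.0 / 41.0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Intercept making the expected release rate equal the target.

    Monte-Carlo average of ``1 - sigmoid(logit(intact))`` over a large
    simulated cohort, solved for the intercept by bracketing.
    """
    cp = cohort_params or CohortParams()
    big = CohortParams(
        n_patients=max(1, n_mc),
        age_range=cp.age_range,
        mean_age=cp.mean_age,
        sd_age=cp.sd_age,
        p_male=cp.p_male,
        p_semitendinosus=cp.p_semitendinosus,
        p_second_tendon=cp.p_second_tendon,
        seed=seed,
    )
    age, male, semit = _covariates(generate_cohort(big))
    lp0 = (
        effects.release_age_coef * age
        + effects.release_male_coef * male
        + effects.release_semitend_coef * semit
    )

    def release_rate(c: float) -> float:
        return float(np.mean(1.0 - expit(c + lp0)))

    return float(optimize.brentq(lambda c: release_rate(c) - target_release_rate, -40.0, 20.0))


def expected_release_rate(
    effects: EffectParams,
    cohort_params: CohortParams | None = None,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expected release rate under the cohort distribution."""
    cp = cohort_params or CohortParams()
    big = CohortParams(**{**cp.__dict__, "n_patients": max(1, n_mc), "seed": seed})
    age, male, semit = _covariates(generate_cohort(big))
    return float(np.mean(1.0 - expit(intact_logit(age, male, semit, effects))))


def induced_procollagen_slope(
    effects: EffectParams,
    cohort_params: CohortParams | None = None,
    n_mc: int = 200_000,
    seed: int = 0,
    intact_only: bool = True,
) -> float:
    """Population age slope of a linear fit to the pro-collagen step model.

    The two-plateau model is not linear in age; a multiple linear
    regression estimates its population projection coefficient, which
    therefore depends on the covariate distribution of the analyzed
    sample.  Because released micro-tissues (disproportionately young)
    yield no biochemical read-outs, the default computes the projection
    under the *intact-selected* covariate distribution — the population
    the pro-collagen regression actually sees.  Computed on noise-free
    responses (noise is mean-zero and does not move the projection).
    """
    cp = cohort_params or CohortParams()
    big = CohortParams(**{**cp.__dict__, "n_patients": max(10, n_mc), "seed": seed})
    age, male, semit = _covariates(generate_cohort(big))
    if intact_only:
        rng = np.random.default_rng(seed + 1)
        keep = rng.random(len(age)) < expit(intact_logit(age, male, semit, effects))
        age, male, semit = age[keep], male[keep], semit[keep]
    y = procollagen_mean(age, effects)
    X = np.column_stack([np.ones_like(age), age, male, semit])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])
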