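"""Seeded cohort generation.

Ages are drawn from a truncated normal whose *truncated* moments are fitted
to the target mean/sd within the admissible range.  Note that on a finite
interval the truncated-normal sd has a supremum (about 11.6 y at mean
27.9 y on [12, 55]); when the target sd exceeds it the solver returns the
least-squares-closest attainable pair, which keeps the mean essentially
exact and the sd as large as the family allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .params import CohortParams


@dataclass
class PatientRecord:
    """One tendon sample's covariates; two-tendon patients share
    patient_id, age and gender across their two records."""

    patient_id: int
    tendon_id: int
    age_y: float
    gender: str          # 'M' or 'F'
    tendon: str          # 'ST' (semitendinosus) or 'G' (gracilis)


@lru_cache(maxsize=64)
def _truncnorm_base(lo: float, hi: float, mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncation to [lo, hi] best matches the
    target truncated mean/sd (least squares; sigma bounded at 150)."""

    def resid(p):
        mu, sig = p
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(
        resid, x0=[mean, sd], bounds=([lo - 400.0, 1.0], [hi + 400.0, 150.0])
    )
    return float(sol.x[0]), float(sol.x[1])


def _draw_ages(rng: np.random.Generator, n: int, params: CohortParams) -> np.ndarray:
    lo, hi = params.age_range
    mu, sig = _truncnorm_base(lo, hi, params.mean_age, params.sd_age)
    a, b = (lo - mu) / sig, (hi - mu) / sig
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Generate one tendon-level record list for a seeded cohort.

    Each patient contributes one tendon (semitendinosus with probability
    ``p_semitendinosus``) or, with probability ``p_second_tendon``, both a
    semitendinosus and a gracilis tendon.  Identical params (including
    seed) yield identical record lists.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    ages = _draw_ages(rng, n, params)
    male = rng.random(n) < params.p_male
    dual = rng.random(n) < params.p_second_tendon
    single_st = rng.random(n) < params.p_semitendinosus

    records: list[PatientRecord] = []
    tendon_id = 1
    for i in range(n):
        gender = "M" if male[i] else "F"
        kinds = ("ST", "G") if dual[i] else (("ST",) if single_st[i] else ("G",))
        for kind in kinds:
            records.append(
                PatientRecord(
                    patient_id=i + 1,
                    tendon_id=tendon_id,
                    age_y=float(ages[i]),
                    gender=gender,
                    tendon=kind,
                )
            )
            tendon_id += 1
    return records


def cohort_summary(records: list[PatientRecord]) -> dict:
    """Census-style summary (patient-level ages, tendon-level proportions)."""
    by_patient: dict[int, PatientRecord] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, r)
    ages = np.array([r.age_y for r in by_patient.values()])
    return {
        "n_patients": len(by_patient),
        "n_tendons": len(records),
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        "age_min": float(ages.min()),
        "age_max": float(ages.max()),
        "frac_male_tendons": float(np.mean([r.gender == "M" for r in records])),
        "frac_semitendinosus": float(np.mean([r.tendon == "ST" for r in records])),
    }
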