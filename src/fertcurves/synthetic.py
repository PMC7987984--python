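"""Seeded generators of synthetic fertility data.

Two generators make every pipeline stage testable without survey microdata:

* :func:`generate_schedule` draws a noisy single-year ASFR schedule around
  a chosen model curve — Gaussian measurement noise, or binomial sampling
  noise for a given number of women observed per age;
* :func:`simulate_birth_histories` draws DHS-style birth histories whose
  underlying age-specific hazards follow a chosen schedule: interview ages
  are uniform over 15–49 at month resolution, and in every month lived from
  exact age 15 a birth occurs independently with probability f(age)/12.

The monthly Bernoulli hazard carries no gestation or birth-interval
constraint — a deliberate simplification that keeps the implied rates
exactly equal to the target schedule (at the rates involved, < 0.25/yr,
interval structure is immaterial for events/exposure estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import families as fam_mod
from .schedules import AGE_MIN, AGE_MAX, BirthHistory, FertilitySchedule

__all__ = [
    "GaussianNoise",
    "BinomialNoise",
    "SimulationConfig",
    "generate_schedule",
    "simulate_birth_histories",
    "DEFAULT_INTERVIEW_CMC",
]

# NFHS-4 fieldwork era (April 2016)
DEFAULT_INTERVIEW_CMC = 1396


@dataclass(frozen=True)
class GaussianNoise:
    """Additive N(0, sd²) measurement noise, truncated at zero."""

    sd: float = 0.002

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class BinomialNoise:
    """Rates observed as births/women with ``women_per_age`` women per age."""

    women_per_age: int = 10_000

    def __post_init__(self):
        if self.women_per_age < 1:
            raise ValueError("women_per_age must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Truth curve and sampling conditions for the generators."""

    family: str
    params: dict
    n_women: int = 200_000
    seed: int = 20210323
    noise: object = field(default_factory=GaussianNoise)
    window_months: int = 36
    interview_cmc: int = DEFAULT_INTERVIEW_CMC

    def __post_init__(self):
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        fam_mod.get_family(self.family)  # validate the name early


def _truth_rates(config: SimulationConfig) -> np.ndarray:
    fam = fam_mod.get_family(config.family)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    return np.asarray(fam(ages, config.params), dtype=float)


def generate_schedule(config: SimulationConfig) -> FertilitySchedule:
    """A noisy schedule around the configured truth curve."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    truth = _truth_rates(config)
    rng = np.random.default_rng(config.seed)
    if isinstance(config.noise, GaussianNoise):
        rates = truth + rng.normal(0.0, config.noise.sd, truth.size)
        rates = np.clip(rates, 0.0, None)
    elif isinstance(config.noise, BinomialNoise):
        if np.any(truth > 1):
            raise ValueError("truth rate > 1: not a valid binomial probability")
        m = config.noise.women_per_age
        rates = rng.binomial(m, truth) / m
    else:
        raise TypeError(f"unknown noise model {config.noise!r}")
    return FertilitySchedule(ages, rates,
                             region_label=f"synthetic:{config.family}")


def simulate_birth_histories(config: SimulationConfig) -> list[BirthHistory]:
    """Birth histories whose hazards follow the configured truth curve.

    Deterministic given the seed.  Women are independent; each month lived
    at completed age x (from exact age 15 up to the month before the
    interview) carries birth probability f(x)/12, zero outside 15–49.
    """
    truth = _truth_rates(config)
    monthly = truth / 12.0
    if np.any(monthly >= 1):
        raise ValueError("monthly hazard f(age)/12 must be < 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_women
    iv = config.interview_cmc

    # interview ages uniform over 15..49 completed years, month resolution
    age_months = rng.integers(AGE_MIN * 12, (AGE_MAX + 1) * 12, size=n)
    dob = iv - age_months

    births_per_woman: list[list[int]] = [[] for _ in range(n)]
    for age in range(AGE_MIN, AGE_MAX + 1):
        p = monthly[age - AGE_MIN]
        start = dob + 12 * age  # first month at this completed age
        n_months = np.clip(iv - start, 0, 12).astype(int)
        active = n_months > 0
        if p == 0 or not active.any():
            continue
        u = rng.random((n, 12))
        hit = u < p
        hit[np.arange(12)[None, :] >= n_months[:, None]] = False
        hit[~active] = False
        wi, mi = np.nonzero(hit)
        for w, mth in zip(wi, mi):
            births_per_woman[w].append(int(dob[w] + 12 * age + mth))

    return [
        BirthHistory(
            woman_dob_cmc=int(dob[i]),
            interview_cmc=iv,
            child_dob_cmc_list=tuple(sorted(births_per_woman[i])),
            woman_id=str(i),
        )
        for i in range(n)
    ]
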