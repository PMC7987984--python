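"""Single-year fertility schedules and their computation from birth histories.

A fertility schedule pairs single years of age (15–49) with age-specific
fertility rates f(x), births per woman per year.  Schedules are either read
from two-column tables or computed from DHS-style retrospective birth
histories: each woman contributes person-months of exposure at each completed
age during a reference window before her interview, and births in that window
are tallied against the mother's completed age at delivery.

Dates use the DHS century-month code (CMC): 12*(year - 1900) + month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_MIN = 15
AGE_MAX = 49

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "FertilitySchedule",
    "BirthHistory",
    "RegionSummary",
    "compute_asfr",
    "summarize",
    "read_schedule",
    "write_schedule",
    "read_birth_histories",
    "write_birth_histories",
]


@dataclass(frozen=True)
class FertilitySchedule:
    """Ages paired with age-specific fertility rates.

    Parameters
    ----------
    ages : array-like of int
        Consecutive single years of age, strictly increasing.
    rates : array-like of float
        Fertility rate per woman per year at each age; nonnegative, finite.
    region_label : str
        Free-text label for the population the schedule describes.
    zero_exposure_ages : tuple of int
        Ages at which no exposure was observed when the schedule was
        computed from microdata (their rate is 0 by convention).
    """

    ages: np.ndarray
    rates: np.ndarray
    region_label: str = ""
    zero_exposure_ages: tuple = ()

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        if ages.ndim != 1 or rates.ndim != 1 or ages.size != rates.size:
            raise ValueError("ages and rates must be 1-d arrays of equal length")
        if ages.size == 0:
            raise ValueError("schedule must contain at least one age")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be consecutive integers")
        if not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        if np.any(rates < 0):
            raise ValueError("rates must be nonnegative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)

    @property
    def n(self) -> int:
        """Number of age points."""
        return int(self.ages.size)

    @property
    def tfr(self) -> float:
        """Total fertility rate: the sum of the single-year rates."""
        return float(self.rates.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "asfr": self.rates})


@dataclass(frozen=True)
class BirthHistory:
    """One woman's retrospective birth history, in century-month codes."""

    woman_dob_cmc: int
    interview_cmc: int
    child_dob_cmc_list: tuple = ()
    weight: float = 1.0
    woman_id: str | None = None

    def __post_init__(self):
        if self.interview_cmc <= self.woman_dob_cmc:
            raise ValueError(
                f"interview before woman's own birth (record {self.woman_id!r})"
            )
        if self.weight < 0:
            raise ValueError(f"negative weight (record {self.woman_id!r})")
        object.__setattr__(
            self, "child_dob_cmc_list", tuple(int(c) for c in self.child_dob_cmc_list)
        )
        for c in self.child_dob_cmc_list:
            if c > self.interview_cmc:
                raise ValueError(
                    f"child born after the interview (record {self.woman_id!r})"
                )


@dataclass(frozen=True)
class RegionSummary:
    """Empirical summaries of one schedule."""

    tfr_observed: float
    peak_rate: float
    peak_age: int
    late_age_rate: float


def compute_asfr(histories, window_months: int = 36) -> FertilitySchedule:
    """Single-year ASFR over a retrospective window before the interview.

    For each completed age x in 15..49, the rate is the (weighted) count of
    births to women aged x at delivery within the window, divided by the
    (weighted) woman-years lived at completed age x within the window.
    Exposure is counted month by month: a woman contributes 1/12 woman-year
    at age x for every month in ``[interview - window_months, interview - 1]``
    during which her completed age is x.  The interview month itself is
    excluded.  Ages with zero exposure get rate 0 and are recorded in
    ``zero_exposure_ages``.

    Parameters
    ----------
    histories : iterable of BirthHistory
    window_months : int
        Length of the reference window in months (default 36, i.e. the
        three years preceding the survey).
    """
    histories = list(histories)
    if not histories:
        raise ValueError("no birth histories supplied")
    if window_months < 1:
        raise ValueError("window_months must be >= 1")

    for h in histories:
        for c in h.child_dob_cmc_list:
            if c < h.woman_dob_cmc:
                raise ValueError(
                    f"child born before mother's own birth (record {h.woman_id!r})"
                )

    dob = np.array([h.woman_dob_cmc for h in histories], dtype=np.int64)
    interview = np.array([h.interview_cmc for h in histories], dtype=np.int64)
    weight = np.array([h.weight for h in histories], dtype=float)

    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    exposure = np.zeros(ages.size)  # woman-years
    births = np.zeros(ages.size)

    # months interview - window .. interview - 1, accumulated age-block-wise
    for t in range(1, window_months + 1):
        cmc = interview - t
        age = (cmc - dob) // 12
        ok = (age >= AGE_MIN) & (age <= AGE_MAX) & (cmc >= dob)
        if ok.any():
            np.add.at(exposure, age[ok] - AGE_MIN, weight[ok] / 12.0)

    for h, d, iv, w in zip(histories, dob, interview, weight):
        for c in h.child_dob_cmc_list:
            if iv - window_months <= c <= iv - 1:
                age = (c - d) // 12
                if AGE_MIN <= age <= AGE_MAX:
                    births[age - AGE_MIN] += w

    zero = exposure == 0
    rates = np.zeros(ages.size)
    rates[~zero] = births[~zero] / exposure[~zero]
    zero_ages = tuple(int(a) for a in ages[zero])
    if zero_ages:
        warnings.warn(
            f"zero exposure at ages {zero_ages}; their rates are set to 0",
            stacklevel=2,
        )
    return FertilitySchedule(ages, rates, zero_exposure_ages=zero_ages)


def summarize(schedule: FertilitySchedule) -> RegionSummary:
    """TFR, peak rate, peak age (smallest age on ties) and mean 45–49 rate."""
    i = int(np.argmax(schedule.rates))  # argmax takes the first on ties
    late = (schedule.ages >= 45) & (schedule.ages <= 49)
    late_rate = float(schedule.rates[late].mean()) if late.any() else 0.0
    return RegionSummary(
        tfr_observed=schedule.tfr,
        peak_rate=float(schedule.rates[i]),
        peak_age=int(schedule.ages[i]),
        late_age_rate=late_rate,
    )


def read_schedule(
    path, region_label: str = "", allow_any_age: bool = False
) -> FertilitySchedule:
    """Read a schedule from a CSV with header ``age,asfr``."""
    df = pd.read_csv(path)
    for col in ("age", "asfr"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    if df["asfr"].isna().any():
        bad = df.index[df["asfr"].isna()][0]
        raise ValueError(f"non-numeric or missing rate in row {bad} of {path}")
    rates = pd.to_numeric(df["asfr"], errors="coerce")
    if rates.isna().any():
        bad = df.index[rates.isna()][0]
        raise ValueError(f"non-numeric rate in row {bad} of {path}")
    ages = df["age"].to_numpy()
    dup = pd.Index(ages)[pd.Index(ages).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate age {int(dup[0])} in {path}")
    if not allow_any_age:
        out = (ages < AGE_MIN) | (ages > AGE_MAX)
        if out.any():
            raise ValueError(
                f"age {int(ages[out][0])} outside {AGE_MIN}-{AGE_MAX} "
                f"(pass allow_any_age=True to accept)"
            )
    order = np.argsort(ages)
    return FertilitySchedule(ages[order], rates.to_numpy()[order], region_label)


def write_schedule(schedule: FertilitySchedule, path) -> None:
    """Write a schedule as CSV with header ``age,asfr``."""
    schedule.to_frame().to_csv(path, index=False)


def read_birth_histories(path) -> list[BirthHistory]:
    """Read birth histories from CSV: one row per (woman, child).

    Header ``woman_id,woman_dob_cmc,interview_cmc,child_dob_cmc,weight``;
    childless women appear with an empty child field.
    """
    df = pd.read_csv(path, dtype={"woman_id": str})
    need = {"woman_id", "woman_dob_cmc", "interview_cmc", "child_dob_cmc"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)} in {path}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    out = []
    for wid, grp in df.groupby("woman_id", sort=False):
        kids = grp["child_dob_cmc"].dropna()
        out.append(
            BirthHistory(
                woman_dob_cmc=int(grp["woman_dob_cmc"].iloc[0]),
                interview_cmc=int(grp["interview_cmc"].iloc[0]),
                child_dob_cmc_list=tuple(int(c) for c in kids),
                weight=float(grp["weight"].iloc[0]),
                woman_id=str(wid),
            )
        )
    return out


def write_birth_histories(histories, path) -> None:
    rows = []
    for i, h in enumerate(histories):
        wid = h.woman_id if h.woman_id is not None else str(i)
        if h.child_dob_cmc_list:
            for c in h.child_dob_cmc_list:
                rows.append((wid, h.woman_dob_cmc, h.interview_cmc, c, h.weight))
        else:
            rows.append((wid, h.woman_dob_cmc, h.interview_cmc, None, h.weight))
    pd.DataFrame(
        rows,
        columns=["woman_id", "woman_dob_cmc", "interview_cmc", "child_dob_cmc", "weight"],
    ).to_csv(path, index=False)
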