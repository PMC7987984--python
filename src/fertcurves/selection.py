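"""Goodness of fit and model selection for fertility-curve fits.

The selection statistic is the small-sample corrected Akaike information
criterion computed from the least-squares objective:

    AIC  = 2k + n*ln(SSE/(n-k))
    AICc = AIC + 2k(k+1)/(n-k-1)

with n the number of ages and k the number of curve parameters.  Note the
``n - k`` denominator inside the logarithm: this degrees-of-freedom variant
(rather than SSE/n) is the convention this package standardises on, and all
bundled reference AICc values are on this scale.  Smaller is better; when
two families differ by less than a tie threshold, the one with fewer
parameters is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import families as fam_mod
from .schedules import FertilitySchedule

__all__ = [
    "aic_aicc",
    "sse",
    "r_squared",
    "ModelComparison",
    "compare_models",
    "correlate_params",
    "AICC_TIE_THRESHOLD",
]

AICC_TIE_THRESHOLD = 0.01


def sse(schedule: FertilitySchedule, family, params) -> float:
    """Sum of squared differences between observed and model rates."""
    fam = fam_mod.get_family(family)
    fitted = np.asarray(fam(schedule.ages, params), dtype=float)
    return float(np.sum((schedule.rates - fitted) ** 2))


def aic_aicc(sse_value: float, n: int, k: int) -> tuple[float, float]:
    """AIC and AICc from a least-squares fit.

    A perfect fit (sse = 0) returns ``-inf`` for both with a warning;
    ``n <= k + 1`` leaves the correction undefined and is an error.
    """
    if sse_value < 0:
        raise ValueError("sse must be nonnegative")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (got n={n}, k={k})")
    if sse_value == 0:
        warnings.warn("sse = 0: AIC/AICc are -inf", stacklevel=2)
        return float("-inf"), float("-inf")
    aic = 2 * k + n * np.log(sse_value / (n - k))
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    return float(aic), float(aicc)


def r_squared(schedule: FertilitySchedule, family, params) -> float:
    """Coefficient of determination 1 - SSE/TSS about the mean rate."""
    if np.ptp(schedule.rates) == 0:
        raise ValueError("observed rates are constant; R^2 undefined")
    tss = float(np.sum((schedule.rates - schedule.rates.mean()) ** 2))
    return 1.0 - sse(schedule, family, params) / tss


@dataclass(frozen=True)
class ModelComparison:
    """Fits of several families to one schedule, ranked by AICc."""

    region_label: str
    rows: tuple  # of FitResult-like objects, ascending AICc
    best_family: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "family": r.family,
                    "k": r.k,
                    "sse": r.sse,
                    "aic": r.aic,
                    "aicc": r.aicc,
                    "r_squared": r.rsquared,
                }
                for r in self.rows
            ]
        )
        df["best"] = df["family"] == self.best_family
        return df


def compare_models(fits, region_label: str = "") -> ModelComparison:
    """Rank fits of different families to the same schedule by AICc.

    The winner has minimal AICc; among families within
    ``AICC_TIE_THRESHOLD`` of the minimum, the fewest parameters win
    (then the lower AICc).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different numbers of ages: {sorted(ns)}")
    rows = tuple(sorted(fits, key=lambda f: (f.aicc, f.k, f.family)))
    best_aicc = rows[0].aicc
    candidates = [f for f in rows if abs(f.aicc - best_aicc) < AICC_TIE_THRESHOLD]
    best = min(candidates, key=lambda f: (f.k, f.aicc, f.family))
    return ModelComparison(region_label=region_label, rows=rows,
                           best_family=best.family)


def correlate_params(x, y) -> float:
    """Pearson product-moment correlation between two paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)
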