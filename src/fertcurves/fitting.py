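"""Nonlinear least-squares fitting of fertility curves.

The modelling interface follows the Model/Results convention: build a
:class:`FertilityCurveModel` from a schedule and a family, call
:meth:`~FertilityCurveModel.fit`, and work with the returned
:class:`FertilityCurveResults` (parameters, SSE, AIC/AICc, R²,
``summary()``, ``predict()``, ``plot()``).

Estimation minimises the sum of squared errors between observed and model
rates with a bounded trust-region-reflective least-squares solver, from a
data-driven start plus seeded multi-start jitters.  For a modified family
that nests an original one, the fitted base solution extended with the
neutral extra parameter (a=0, gamma=1, s=0) is always among the starts, so
for true nestings (modified P-K, modified Gompertz) the modified family's
SSE can never exceed the base family's by more than the solver tolerance.

Asymptotic standard errors are available (Gauss–Newton approximation) but
are not printed by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import families as fam_mod
from . import selection
from .families import Family, get_family
from .schedules import FertilitySchedule
from .smoothing import SmoothingConfig, loess_smooth

__all__ = [
    "FitConfig",
    "FitResult",
    "FertilityCurveResults",
    "FertilityCurveModel",
    "initialize_params",
    "fit_model",
    "sse",
]

DEFAULT_SEED = 20210323

sse = selection.sse  # re-exported: the objective lives with the statistics


@dataclass(frozen=True)
class FitConfig:
    """Multi-start estimation settings.

    n_starts : data-driven start plus ``n_starts - 1`` seeded jitters.
    seed : seed for the jitter stream.
    bounds : per-parameter ``{name: (lo, hi)}`` overrides of the family's
        defaults.
    tol : solver tolerance on the SSE (ftol/xtol/gtol scale).
    max_iter : cap on residual evaluations per start.
    """

    n_starts: int = 20
    seed: int = DEFAULT_SEED
    bounds: dict = field(default_factory=dict)
    tol: float = 1e-12
    max_iter: int = 2000

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


def initialize_params(schedule: FertilitySchedule, family) -> dict:
    """Deterministic data-driven starting values for any family.

    Peak-shaped families start at the empirical peak: height = max rate,
    location = argmax age, pre/post spreads 3 and 9 years, late-age
    constants at the mean 45–49 rate.  The Gompertz family starts at
    m = min age - 1, alpha = beta = 4, gamma = 10; Hadwiger at
    c = argmax age, a = TFR/2, b = 3.5.  The beta-kernel families place the
    kernel mode at the argmax age.  All values are clipped to the family's
    bounds.
    """
    fam = get_family(family)
    if np.all(schedule.rates == 0):
        raise ValueError("all rates are zero: no peak to initialise from")
    peak_rate = float(schedule.rates.max())
    peak_age = int(schedule.ages[int(np.argmax(schedule.rates))])
    late = schedule.rates[(schedule.ages >= 45) & (schedule.ages <= 49)]
    late_mean = float(late.mean()) if late.size else 0.0

    if fam.name in ("pk", "modified_pk"):
        p = {"b": peak_rate, "mu": float(peak_age), "sigma1": 3.0, "sigma2": 9.0}
        if fam.name == "modified_pk":
            p["a"] = late_mean
    elif fam.name in ("gompertz", "modified_gompertz"):
        p = {"alpha": 4.0, "beta": 4.0, "m": float(schedule.ages.min() - 1)}
        if fam.name == "modified_gompertz":
            p["gamma"] = 10.0
    elif fam.name == "skew_normal":
        p = {"lambda": float(peak_age), "sigma": 6.0, "delta": 2.0}
    elif fam.name == "modified_skew_normal":
        p = {"theta": peak_rate, "lambda": float(peak_age), "s1": 3.0,
             "s2": 9.0, "delta": 2.0}
    elif fam.name == "hadwiger":
        p = {"a": schedule.tfr / 2.0, "b": 3.5, "c": float(peak_age)}
    elif fam.name == "gp":
        # place the kernel mode x* = 49 q/(q+r) at the observed peak age
        q = 2.5
        r = q * (49.0 - peak_age) / peak_age
        u = peak_age / 49.0
        p = {"p": peak_rate / (peak_age**q * (1 - u) ** r), "q": q, "r": r}
    elif fam.name == "modified_gp":
        u = (peak_age - 15.0) / 49.0
        u = min(max(u, 0.02), 0.98)
        q = 2.5
        r = q * (1 - u) / u
        p = {"p": max(peak_rate - late_mean, 1e-4) / (u**q * (1 - u) ** r),
             "q": q, "r": r, "s": late_mean}
    else:  # pragma: no cover - registry and initialiser kept in sync
        raise ValueError(f"no initialiser for family {fam.name!r}")

    for name, (lo, hi) in fam.bounds.items():
        p[name] = float(np.clip(p[name], lo, hi))
    return p


@dataclass(frozen=True)
class FertilityCurveResults:
    """A fitted fertility curve and its fit statistics."""

    family: str
    params: dict
    sse: float
    n: int
    k: int
    aic: float
    aicc: float
    rsquared: float
    converged: bool
    start_index: int
    schedule: FertilitySchedule | None = None
    n_starts_tried: int = 0

    def predict(self, ages=None) -> np.ndarray:
        """Model rates at the given ages (default: the fitted schedule's)."""
        if ages is None:
            if self.schedule is None:
                raise ValueError("no schedule attached; pass ages explicitly")
            ages = self.schedule.ages
        return np.asarray(get_family(self.family)(ages, self.params), float)

    def peak(self, age_range=(15, 49)):
        """(peak age, peak rate) of the fitted curve."""
        return fam_mod.model_peak(self.family, self.params, age_range)

    def implied_tfr(self) -> float:
        """Total fertility implied by the fitted curve (sum over 15..49)."""
        return fam_mod.model_implied_tfr(self.family, self.params)

    def bse(self) -> dict:
        """Gauss–Newton asymptotic standard errors of the parameters.

        Computed from the residual Jacobian at the optimum,
        ``cov = s² (JᵀJ)⁻¹`` with ``s² = SSE/(n-k)``; not shown by
        ``summary()`` unless requested, following the convention of
        reporting only point estimates for fertility-curve fits.
        """
        if self.schedule is None:
            raise ValueError("standard errors need the fitted schedule")
        fam = get_family(self.family)
        theta = fam.params_to_array(self.params)
        x = self.schedule.ages.astype(float)

        def f(vec):
            return np.asarray(fam(x, fam.array_to_params(vec)), float)

        J = np.empty((x.size, theta.size))
        h = 1e-6 * np.maximum(np.abs(theta), 1e-3)
        for j in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[j] += h[j]
            dn[j] -= h[j]
            J[:, j] = (f(up) - f(dn)) / (2 * h[j])
        s2 = self.sse / max(self.n - self.k, 1)
        cov = s2 * np.linalg.pinv(J.T @ J)
        return dict(zip(fam.param_names, np.sqrt(np.clip(np.diag(cov), 0, None))))

    def summary(self, show_se: bool = False) -> str:
        lines = [
            f"Fertility curve fit: {self.family}",
            "=" * 44,
            f"No. observations (ages): {self.n:>6d}",
            f"No. parameters (k):      {self.k:>6d}",
            f"SSE:       {self.sse:>14.6g}",
            f"AIC:       {self.aic:>14.4f}",
            f"AICc:      {self.aicc:>14.4f}",
            f"R-squared: {self.rsquared:>14.6f}",
            f"Converged: {str(self.converged):>6s}  (best of "
            f"{self.n_starts_tried} starts, start #{self.start_index})",
            "-" * 44,
        ]
        se = self.bse() if show_se and self.schedule is not None else {}
        for name in get_family(self.family).param_names:
            row = f"{name:>8s}  {self.params[name]:>12.6g}"
            if name in se:
                row += f"  (se {se[name]:.2g})"
            lines.append(row)
        peak_age, peak_rate = self.peak()
        lines += [
            "-" * 44,
            f"Peak rate {peak_rate:.4f} at age {peak_age:.2f}; "
            f"implied TFR {self.implied_tfr():.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {n: self.params[n]
                       for n in get_family(self.family).param_names},
            "sse": self.sse,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
            "aicc": self.aicc,
            "r_squared": self.rsquared,
            "converged": self.converged,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def plot(self, ax=None):
        """Observed vs fitted rates on one axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.schedule is not None:
            ax.plot(self.schedule.ages, self.schedule.rates, "o",
                    label="observed", color="0.3")
            grid = np.linspace(self.schedule.ages.min(),
                               self.schedule.ages.max(), 300)
        else:
            grid = np.linspace(15, 49, 300)
        ax.plot(grid, self.predict(grid), label=f"fitted {self.family}")
        ax.set_xlabel("age")
        ax.set_ylabel("ASFR (births per woman per year)")
        ax.legend()
        return ax


FitResult = FertilityCurveResults


class FertilityCurveModel:
    """A parametric fertility curve to be fitted to one schedule.

    Parameters
    ----------
    schedule : FertilitySchedule
        Observed single-year rates.
    family : str or Family
        One of the nine registered families.
    fit_to_smoothed : bool
        Fit to the loess-smoothed schedule instead of the raw one.
    smoothing : SmoothingConfig, optional
        Settings for the pre-fit smoothing (span 0.2, degree 2 by default).
    """

    def __init__(self, schedule: FertilitySchedule, family,
                 fit_to_smoothed: bool = False,
                 smoothing: SmoothingConfig | None = None):
        self.family = get_family(family)
        self.raw_schedule = schedule
        if fit_to_smoothed:
            self.schedule = loess_smooth(schedule,
                                         smoothing or SmoothingConfig())
        else:
            self.schedule = schedule

    @classmethod
    def from_dataframe(cls, df, family, age_col="age", rate_col="asfr",
                       region_label: str = "", **kwargs):
        sched = FertilitySchedule(df[age_col].to_numpy(),
                                  df[rate_col].to_numpy(), region_label)
        return cls(sched, family, **kwargs)

    # ------------------------------------------------------------ internals

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        params = self.family.array_to_params(theta)
        with np.errstate(all="ignore"):
            fitted = np.asarray(self.family(self.schedule.ages, params), float)
        r = fitted - self.schedule.rates
        return np.clip(np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6),
                       -1e6, 1e6)

    def _bounds(self, config: FitConfig):
        merged = dict(self.family.bounds)
        merged.update(config.bounds)
        lo = np.array([merged[n][0] for n in self.family.param_names])
        hi = np.array([merged[n][1] for n in self.family.param_names])
        return lo, hi

    def _starts(self, config: FitConfig, lo, hi):
        """Heuristic start, seeded jitters, and the extended base fit."""
        names = self.family.param_names
        x0 = self.family.params_to_array(
            initialize_params(self.schedule, self.family))
        starts = [x0]
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_starts - 1):
            jit = x0.copy()
            for j, name in enumerate(names):
                if name in self.family.location:
                    jit[j] += rng.uniform(-3.0, 3.0)
                elif lo[j] >= 0:
                    jit[j] *= np.exp(rng.normal(0.0, 0.3))
                else:  # signed parameter (skewness)
                    jit[j] += rng.normal(0.0, 1.0)
            starts.append(jit)
        if self.family.base is not None:
            base_fit = FertilityCurveModel(self.schedule, self.family.base).fit(
                replace(config, n_starts=max(config.n_starts // 2, 5)))
            ext = dict(base_fit.params)
            ext.update(self.family.neutral)
            starts.append(self.family.params_to_array(ext))
        eps = 1e-12
        return [np.clip(s, lo + eps, hi - eps) for s in starts]

    # ------------------------------------------------------------------ fit

    def fit(self, config: FitConfig | None = None, **kwargs
            ) -> FertilityCurveResults:
        """Minimise the SSE by bounded multi-start least squares.

        Keyword arguments (``n_starts``, ``seed`` ...) override fields of
        ``config``.  Returns the best local optimum found across starts.
        Deterministic for a given schedule, family and seed.
        """
        config = replace(config or FitConfig(), **kwargs)
        lo, hi = self._bounds(config)
        starts = self._starts(config, lo, hi)

        best = None
        best_sse = np.inf
        best_idx = -1
        any_ok = False
        for idx, x0 in enumerate(starts):
            try:
                res = least_squares(
                    self._residuals, x0, bounds=(lo, hi), method="trf",
                    ftol=config.tol, xtol=config.tol, gtol=config.tol,
                    max_nfev=config.max_iter,
                )
            except Exception:
                continue
            this_sse = float(2 * res.cost)
            if np.isfinite(this_sse):
                any_ok = True
                if this_sse < best_sse:
                    best, best_sse, best_idx = res, this_sse, idx
        if not any_ok or best is None:
            raise RuntimeError(
                f"no start converged for family {self.family.name!r} "
                f"({len(starts)} starts tried)"
            )

        params = self.family.array_to_params(best.x)
        n, k = self.schedule.n, self.family.k
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            aic, aicc = selection.aic_aicc(best_sse, n, k)
        rsq = selection.r_squared(self.schedule, self.family, params)
        return FertilityCurveResults(
            family=self.family.name,
            params=params,
            sse=best_sse,
            n=n,
            k=k,
            aic=aic,
            aicc=aicc,
            rsquared=rsq,
            converged=bool(best.status > 0),
            start_index=best_idx,
            schedule=self.schedule,
            n_starts_tried=len(starts),
        )


def fit_model(schedule: FertilitySchedule, family,
              config: FitConfig | None = None, **kwargs
              ) -> FertilityCurveResults:
    """Functional wrapper: ``FertilityCurveModel(schedule, family).fit(...)``."""
    return FertilityCurveModel(schedule, family).fit(config, **kwargs)
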