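"""The nine parametric families of age-specific fertility curves.

Four classical unimodal, right-skewed fertility curves — the two-sided
Gaussian ("P-K") curve, the Gompertz curve, the skew-normal density curve
and the beta-kernel ("G-P") curve — together with a modified version of
each, plus the Hadwiger curve.  Each modification adds one parameter:

* modified P-K:        a constant ``a`` lifting the late-age (45–49) tail;
* modified Gompertz:   a scale exponent ``gamma`` freeing the peak height;
* modified skew normal: separate pre-/post-peak spreads ``s1``/``s2`` with
  an explicit peak level ``theta``;
* modified G-P:        a constant ``s`` for the late-age tail, with the age
  axis shifted to start at 15.

The P-K exponents are implemented with the negative sign,
``b*exp(-((x-mu)/sigma)^2)``, the bounded bell form; the variant without the
minus sign (occasionally seen in print) diverges and cannot describe a
fertility schedule.

The modified skew-normal Phi factor uses the argument ``(delta*x - lambda)/s``
by default (``phi_arg="shifted"``); the centred reading
``delta*(x - lambda)/s`` is available with ``phi_arg="centered"``.

Parameters are plain ``{name: value}`` dicts keyed by ASCII symbol names
(``mu``, ``sigma1``, ``lambda``, ``theta`` ...), which also serve as the
JSON serialisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .schedules import AGE_MIN, AGE_MAX

__all__ = [
    "Family",
    "FAMILIES",
    "get_family",
    "eval_family",
    "eval_hadwiger",
    "eval_pk_family",
    "eval_gompertz_family",
    "eval_skewnormal_family",
    "eval_gp_family",
    "model_peak",
    "model_implied_tfr",
    "params_to_json",
    "params_from_json",
    "validate_params",
]


# ---------------------------------------------------------------- evaluation

def eval_hadwiger(x, params):
    """Hadwiger curve (a*b/c)*(c/x)^(3/2)*exp{-b^2*(c/x + x/c - 2)}.

    ``a`` scales with total fertility, ``b`` with the height of the curve
    and ``c`` with the mean age of childbearing.  Requires x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Hadwiger curve requires x > 0")
    a, b, c = params["a"], params["b"], params["c"]
    return (a * b / c) * (c / x) ** 1.5 * np.exp(-(b**2) * (c / x + x / c - 2.0))


def eval_pk_family(x, params):
    """Two-sided Gaussian fertility curve, optionally with a late-age floor.

    ``a + b*exp(-((x-mu)/sigma1)^2)`` for x <= mu and with ``sigma2`` for
    x > mu; the original family is the special case a = 0 (omit ``a``).
    """
    x = np.asarray(x, dtype=float)
    a = params.get("a", 0.0)
    b, mu = params["b"], params["mu"]
    sigma = np.where(x <= mu, params["sigma1"], params["sigma2"])
    return a + b * np.exp(-(((x - mu) / sigma) ** 2))


def eval_gompertz_family(x, params):
    """Gompertz fertility curve (alpha/beta)^gamma * exp[-z - alpha*exp(-z)].

    z = (x - m)/beta; the original family fixes gamma = 1 (omit ``gamma``).
    The curve peaks at x* = m + beta*ln(alpha).
    """
    x = np.asarray(x, dtype=float)
    alpha, beta, m = params["alpha"], params["beta"], params["m"]
    gamma = params.get("gamma", 1.0)
    z = (x - m) / beta
    return (alpha / beta) ** gamma * np.exp(-z - alpha * np.exp(-z))


def eval_skewnormal_family(x, params, phi_arg: str = "shifted"):
    """Skew-normal fertility curves.

    Original (params lambda, sigma, delta):
        2/sigma * phi((x-lambda)/sigma) * Phi(delta*(x-lambda)/sigma)
    Modified (params theta, lambda, s1, s2, delta): a two-sided Gaussian of
    height theta with spreads s1 (x <= lambda) and s2 (x > lambda), each
    branch multiplied by Phi((delta*x - lambda)/s) — or, with
    ``phi_arg="centered"``, Phi(delta*(x - lambda)/s).
    """
    x = np.asarray(x, dtype=float)
    lam, delta = params["lambda"], params["delta"]
    if "theta" not in params:
        sigma = params["sigma"]
        z = (x - lam) / sigma
        return 2.0 / sigma * norm.pdf(z) * norm.cdf(delta * z)
    theta = params["theta"]
    s = np.where(x <= lam, params["s1"], params["s2"])
    bell = theta * np.exp(-0.5 * ((x - lam) / s) ** 2)
    if phi_arg == "shifted":
        arg = (delta * x - lam) / s
    elif phi_arg == "centered":
        arg = delta * (x - lam) / s
    else:
        raise ValueError(f"unknown phi_arg {phi_arg!r}")
    return bell * norm.cdf(arg)


def eval_gp_family(x, params):
    """Beta-kernel fertility curves.

    Original (p, q, r): p * x^q * (1 - x/49)^r on 0 < x <= 49.
    Modified (p, q, r, s): s + p * u^q * (1-u)^r with u = (x-15)/49 on
    15 <= x <= 64; the late-age floor is s and the peak sits at
    x* = 15 + 49*q/(q+r).
    """
    x = np.asarray(x, dtype=float)
    p, q, r = params["p"], params["q"], params["r"]
    if "s" in params:
        if np.any((x < 15) | (x > 64)):
            raise ValueError("modified G-P curve requires 15 <= x <= 64")
        u = (x - 15.0) / 49.0
        return params["s"] + p * u**q * (1.0 - u) ** r
    if np.any((x <= 0) | (x > 49)):
        raise ValueError("G-P curve requires 0 < x <= 49")
    return p * x**q * (1.0 - x / 49.0) ** r


# ------------------------------------------------------------------ registry

@dataclass(frozen=True)
class Family:
    """One parametric family: names, bounds and vectorised evaluation.

    ``bounds`` are the box constraints used by the fitter; ``location``
    marks parameters measured in years of age (jittered additively during
    multi-start).  ``base``/``neutral`` link a modified family to the
    original it nests: extending a base fit with the neutral values leaves
    the curve unchanged.
    """

    name: str
    param_names: tuple
    bounds: dict
    location: tuple = ()
    base: str | None = None
    neutral: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.param_names)

    def __call__(self, x, params):
        return eval_family(self.name, x, params, **self.options)

    def array_to_params(self, values) -> dict:
        return dict(zip(self.param_names, (float(v) for v in values)))

    def params_to_array(self, params) -> np.ndarray:
        return np.array([params[name] for name in self.param_names], dtype=float)


_EVAL = {
    "hadwiger": eval_hadwiger,
    "pk": eval_pk_family,
    "modified_pk": eval_pk_family,
    "gompertz": eval_gompertz_family,
    "modified_gompertz": eval_gompertz_family,
    "skew_normal": eval_skewnormal_family,
    "modified_skew_normal": eval_skewnormal_family,
    "gp": eval_gp_family,
    "modified_gp": eval_gp_family,
}

_RATE = (1e-6, 1.0)       # parameters on the rate scale (curve heights)
_CONST = (0.0, 0.05)      # late-age constant floors
_LOC = (10.0, 49.0)       # ages in years
_SPREAD = (0.1, 30.0)     # spreads in years
_DELTA = (-30.0, 30.0)    # skewness

FAMILIES: dict[str, Family] = {}


def _register(fam: Family) -> None:
    FAMILIES[fam.name] = fam


_register(Family(
    name="hadwiger",
    param_names=("a", "b", "c"),
    bounds={"a": (0.01, 10.0), "b": (0.1, 20.0), "c": (15.0, 45.0)},
    location=("c",),
))
_register(Family(
    name="pk",
    param_names=("b", "mu", "sigma1", "sigma2"),
    bounds={"b": _RATE, "mu": _LOC, "sigma1": _SPREAD, "sigma2": _SPREAD},
    location=("mu",),
))
_register(Family(
    name="modified_pk",
    param_names=("b", "mu", "sigma1", "sigma2", "a"),
    bounds={"b": _RATE, "mu": _LOC, "sigma1": _SPREAD, "sigma2": _SPREAD,
            "a": _CONST},
    location=("mu",),
    base="pk",
    neutral={"a": 0.0},
))
_register(Family(
    name="gompertz",
    param_names=("alpha", "beta", "m"),
    bounds={"alpha": (0.1, 30.0), "beta": (0.1, 30.0), "m": _LOC},
    location=("m",),
))
_register(Family(
    name="modified_gompertz",
    param_names=("alpha", "beta", "gamma", "m"),
    bounds={"alpha": (0.1, 30.0), "beta": (0.1, 30.0), "gamma": (0.1, 50.0),
            "m": _LOC},
    location=("m",),
    base="gompertz",
    neutral={"gamma": 1.0},
))
_register(Family(
    name="skew_normal",
    param_names=("lambda", "sigma", "delta"),
    bounds={"lambda": _LOC, "sigma": _SPREAD, "delta": _DELTA},
    location=("lambda",),
))
_register(Family(
    name="modified_skew_normal",
    param_names=("lambda", "s1", "delta", "s2", "theta"),
    bounds={"lambda": _LOC, "s1": _SPREAD, "delta": _DELTA, "s2": _SPREAD,
            "theta": _RATE},
    location=("lambda",),
))
_register(Family(
    name="gp",
    param_names=("p", "q", "r"),
    bounds={"p": (1e-6, 1e6), "q": (0.01, 50.0), "r": (0.01, 50.0)},
))
_register(Family(
    name="modified_gp",
    param_names=("p", "q", "r", "s"),
    bounds={"p": (1e-6, 1e6), "q": (0.01, 50.0), "r": (0.01, 50.0),
            "s": _CONST},
    base="gp",  # nests the shifted/scaled kernel with s = 0, not the raw G-P
    neutral={"s": 0.0},
))


def get_family(name) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def eval_family(family, x, params, **options):
    """Evaluate any registered family at ages ``x``."""
    name = family.name if isinstance(family, Family) else family
    if name not in _EVAL:
        raise ValueError(f"unknown family {name!r}")
    return _EVAL[name](x, params, **options)


def validate_params(family, params) -> None:
    """Raise ValueError if params violate the family's sign constraints."""
    fam = get_family(family)
    missing = set(fam.param_names) - set(params)
    if missing:
        raise ValueError(f"{fam.name}: missing parameter(s) {sorted(missing)}")
    positive = {
        "a", "b", "c", "sigma", "sigma1", "sigma2", "alpha", "beta", "gamma",
        "theta", "s1", "s2", "p", "q", "r",
    }
    nonneg = {"s"}
    if fam.name == "modified_pk":
        positive = positive - {"a"}
        nonneg = nonneg | {"a"}
    for name in fam.param_names:
        v = params[name]
        if not np.isfinite(v):
            raise ValueError(f"{fam.name}: parameter {name} must be finite")
        if name in positive and v <= 0:
            raise ValueError(f"{fam.name}: parameter {name} must be > 0")
        if name in nonneg and v < 0:
            raise ValueError(f"{fam.name}: parameter {name} must be >= 0")


# ------------------------------------------------------- derived quantities

def model_peak(family, params, age_range=(AGE_MIN, AGE_MAX)):
    """Continuous maximizer and maximum of the curve over ``age_range``.

    Dense grid (1e-3 year steps) refined by bounded golden-section search;
    ties broken toward the younger age.
    """
    fam = get_family(family)
    lo, hi = float(age_range[0]), float(age_range[1])
    grid = np.arange(lo, hi + 5e-4, 1e-3)
    vals = np.asarray(fam(grid, params), dtype=float)
    i = int(np.argmax(vals))  # first index on exact ties -> younger age
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if a == b:
        return float(grid[i]), float(vals[i])
    res = minimize_scalar(
        lambda x: -float(fam(x, params)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    x_star, v_star = float(res.x), float(-res.fun)
    if v_star >= vals[i]:
        return x_star, v_star
    return float(grid[i]), float(vals[i])


def model_implied_tfr(family, params) -> float:
    """Total fertility implied by the curve: sum over integer ages 15..49."""
    fam = get_family(family)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    return float(np.sum(fam(ages, params)))


# --------------------------------------------------------------------- JSON

def params_to_json(family, params) -> str:
    fam = get_family(family)
    return json.dumps({"family": fam.name,
                       "params": {n: params[n] for n in fam.param_names}})


def params_from_json(text: str):
    """Return (family, params) from the JSON emitted by params_to_json."""
    obj = json.loads(text)
    fam = get_family(obj["family"])
    params = {n: float(obj["params"][n]) for n in fam.param_names}
    return fam, params
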