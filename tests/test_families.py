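"""Closed-form checks, reductions and invariants of the nine curve families."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import fertcurves as fc
from fertcurves import families, nfhs4

AGES = np.arange(15, 50, dtype=float)
GRID = np.linspace(15, 49, 341)


class TestHadwiger:
    def test_value_at_x_equals_c_is_ab_over_c(self):
        p = {"a": 2.0, "b": 3.0, "c": 25.0}
        assert fc.eval_hadwiger(25.0, p) == pytest.approx(2 * 3 / 25)

    def test_india_estimate_at_mean_childbearing_age(self):
        p = nfhs4.HADWIGER_ESTIMATES["India"]
        assert fc.eval_hadwiger(p["c"], p) == pytest.approx(0.18496, abs=5e-6)

    def test_vanishes_toward_zero_age(self):
        p = nfhs4.HADWIGER_ESTIMATES["India"]
        assert fc.eval_hadwiger(1e-3, p) < 1e-300

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            fc.eval_hadwiger(0.0, {"a": 1, "b": 1, "c": 25})


class TestPKFamily:
    def test_peak_value_at_mu_is_a_plus_b(self, india_modified_pk):
        p = india_modified_pk
        assert fc.eval_pk_family(p["mu"], p) == pytest.approx(
            p["a"] + p["b"])
        assert fc.eval_pk_family(p["mu"], p) == pytest.approx(0.1933, abs=1e-4)

    def test_symmetric_when_spreads_equal(self):
        p = {"b": 0.2, "mu": 22.0, "sigma1": 4.0, "sigma2": 4.0}
        for d in (1.0, 3.5, 7.0):
            assert fc.eval_pk_family(p["mu"] - d, p) == pytest.approx(
                fc.eval_pk_family(p["mu"] + d, p))

    def test_modified_with_a_zero_reduces_to_original(self):
        base = {"b": 0.19, "mu": 21.4, "sigma1": 3.4, "sigma2": 8.9}
        ext = dict(base, a=0.0)
        np.testing.assert_array_equal(
            fc.eval_pk_family(GRID, ext), fc.eval_pk_family(GRID, base))

    def test_branches_meet_exactly_at_mu(self, india_modified_pk):
        p = india_modified_pk
        eps = 1e-12
        left = fc.eval_pk_family(p["mu"] - eps, p)
        right = fc.eval_pk_family(p["mu"] + eps, p)
        assert left == pytest.approx(right, abs=1e-12)


class TestGompertzFamily:
    def test_gamma_one_reduces_to_original(self):
        base = {"alpha": 4.0, "beta": 4.0, "m": 16.0}
        ext = dict(base, gamma=1.0)
        np.testing.assert_array_equal(
            fc.eval_gompertz_family(GRID, ext),
            fc.eval_gompertz_family(GRID, base))

    def test_peak_matches_closed_form(self, india_modified_gompertz):
        # stationarity of the exponent gives x* = m + beta*ln(alpha) and
        # peak value (alpha/beta)^gamma * exp(-(1 + ln alpha))
        p = india_modified_gompertz
        x_star = p["m"] + p["beta"] * np.log(p["alpha"])
        v_star = (p["alpha"] / p["beta"]) ** p["gamma"] * np.exp(
            -(1 + np.log(p["alpha"])))
        age, rate = fc.model_peak("modified_gompertz", p)
        assert age == pytest.approx(x_star, abs=1e-3)
        assert rate == pytest.approx(v_star, rel=1e-9)
        assert x_star == pytest.approx(22.487, abs=1e-3)
        assert v_star == pytest.approx(0.19697, abs=1e-5)

    def test_implied_tfr_close_to_analytic_integral(self, india_modified_gompertz):
        # integral of the curve over all x is beta*(alpha/beta)^gamma/alpha;
        # the discrete 15-49 sum should agree within truncation error (2%)
        p = india_modified_gompertz
        integral = p["beta"] * (p["alpha"] / p["beta"]) ** p["gamma"] / p["alpha"]
        tfr = fc.model_implied_tfr("modified_gompertz", p)
        assert tfr == pytest.approx(integral, rel=0.02)


class TestSkewNormalFamily:
    def test_delta_zero_gives_symmetric_density(self):
        p = {"lambda": 22.0, "sigma": 5.0, "delta": 0.0}
        vals = fc.eval_skewnormal_family(GRID, p)
        expected = norm.pdf((GRID - 22.0) / 5.0) / 5.0
        np.testing.assert_allclose(vals, expected, rtol=1e-12)

    def test_modified_peak_level_at_lambda(self):
        p = nfhs4.MODIFIED_SKEW_NORMAL_ESTIMATES["India"]
        # Phi argument at x = lambda is ~16.6 sigma -> factor is 1
        val = fc.eval_skewnormal_family(p["lambda"], p)
        assert val == pytest.approx(p["theta"], rel=1e-9)

    def test_modified_large_delta_reduces_to_two_sided_gaussian(self):
        p = {"theta": 0.19, "lambda": 21.0, "s1": 2.4, "s2": 6.5,
             "delta": 1e6}
        vals = fc.eval_skewnormal_family(GRID, p)
        s = np.where(GRID <= 21.0, 2.4, 6.5)
        expected = 0.19 * np.exp(-0.5 * ((GRID - 21.0) / s) ** 2)
        np.testing.assert_allclose(vals, expected, rtol=1e-12)

    def test_junction_discontinuity_bounded_at_reference_estimates(self):
        # the two branches differ at lambda only through Phi((d*l-l)/s1) vs
        # Phi((d*l-l)/s2).  Where delta is large (India: ~16.6 vs ~6.2
        # sigma) both saturate at 1 and the curve is continuous to < 1e-9;
        # for the low-skewness regions (Gujarat, Karnataka, delta ~ 1.5)
        # the printed form carries a genuine small jump, bounded here.
        for region, p in nfhs4.MODIFIED_SKEW_NORMAL_ESTIMATES.items():
            lam, delta = p["lambda"], p["delta"]
            gap = abs(norm.cdf((delta * lam - lam) / p["s1"])
                      - norm.cdf((delta * lam - lam) / p["s2"]))
            jump = gap * p["theta"]
            if region == "India":
                assert gap < 1e-9
            if delta > 2.4:
                assert gap < 1e-7, region
            assert jump < 0.01, region

    def test_centered_phi_argument_variant(self):
        p = {"theta": 0.19, "lambda": 21.0, "s1": 2.4, "s2": 6.5, "delta": 2.9}
        shifted = fc.eval_skewnormal_family(18.0, p, phi_arg="shifted")
        centered = fc.eval_skewnormal_family(18.0, p, phi_arg="centered")
        expected_centered = (0.19 * np.exp(-0.5 * ((18 - 21) / 2.4) ** 2)
                             * norm.cdf(2.9 * (18 - 21) / 2.4))
        assert centered == pytest.approx(expected_centered, rel=1e-12)
        assert shifted != pytest.approx(centered, rel=1e-3)


class TestGPFamily:
    def test_original_vanishes_at_49(self):
        assert fc.eval_gp_family(49.0, {"p": 1e-4, "q": 2.0, "r": 3.0}) == 0.0

    def test_modified_equals_floor_at_15(self):
        p = {"p": 165.0, "q": 2.4, "r": 13.4, "s": 0.004}
        assert fc.eval_gp_family(15.0, p) == pytest.approx(0.004)

    def test_modified_peak_matches_beta_kernel_mode(self):
        p = nfhs4.MODIFIED_GP_ESTIMATES["India"]
        x_star = 15 + 49 * p["q"] / (p["q"] + p["r"])
        age, rate = fc.model_peak("modified_gp", p)
        assert age == pytest.approx(x_star, abs=1e-3)
        assert x_star == pytest.approx(22.52, abs=5e-3)
        assert rate == pytest.approx(0.19262, abs=1e-4)

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            fc.eval_gp_family(50.0, {"p": 1, "q": 1, "r": 1})
        with pytest.raises(ValueError):
            fc.eval_gp_family(14.0, {"p": 1, "q": 1, "r": 1, "s": 0})


class TestDerivedQuantities:
    def test_peak_of_modified_pk_is_mu_a_plus_b(self, india_modified_pk):
        age, rate = fc.model_peak("modified_pk", india_modified_pk)
        assert age == pytest.approx(india_modified_pk["mu"], abs=1e-3)
        assert rate == pytest.approx(
            india_modified_pk["a"] + india_modified_pk["b"], rel=1e-9)

    def test_implied_tfr_of_constant_curve(self):
        p = {"b": 0.0, "mu": 22.0, "sigma1": 3.0, "sigma2": 9.0, "a": 0.01}
        assert fc.model_implied_tfr("modified_pk", p) == pytest.approx(35 * 0.01)

    def test_implied_tfr_of_zero_curve(self):
        p = {"b": 0.0, "mu": 22.0, "sigma1": 3.0, "sigma2": 9.0, "a": 0.0}
        assert fc.model_implied_tfr("modified_pk", p) == 0.0


FAMILY_PARAM_STRATEGIES = {
    name: st.fixed_dictionaries({
        pname: st.floats(max(lo, -25.0), min(hi, 1e3),
                         allow_nan=False, allow_infinity=False,
                         exclude_min=lo == 0.0)
        for pname, (lo, hi) in fam.bounds.items()
    })
    for name, fam in fc.FAMILIES.items()
}


@pytest.mark.parametrize("family", sorted(fc.FAMILIES))
@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_families_nonnegative_on_domain(family, data):
    """Every family maps valid parameters to nonnegative rates on 15-49."""
    params = data.draw(FAMILY_PARAM_STRATEGIES[family])
    with np.errstate(over="ignore", under="ignore"):
        vals = np.asarray(fc.eval_family(family, AGES, params), float)
    assert np.all(vals[np.isfinite(vals)] >= 0)


@pytest.mark.parametrize("family,table", [
    ("modified_pk", nfhs4.MODIFIED_PK_ESTIMATES),
    ("modified_gompertz", nfhs4.MODIFIED_GOMPERTZ_ESTIMATES),
    ("modified_skew_normal", nfhs4.MODIFIED_SKEW_NORMAL_ESTIMATES),
    ("modified_gp", nfhs4.MODIFIED_GP_ESTIMATES),
    ("hadwiger", nfhs4.HADWIGER_ESTIMATES),
])
def test_params_json_round_trip(family, table):
    text = fc.params_to_json(family, table["India"])
    fam, params = fc.params_from_json(text)
    assert fam.name == family
    assert params == {k: table["India"][k] for k in params}
    json.loads(text)  # well-formed


def test_validate_params_flags_sign_violations():
    families.validate_params("hadwiger", {"a": 1.0, "b": 1.0, "c": 25.0})
    with pytest.raises(ValueError, match="b"):
        families.validate_params("hadwiger", {"a": 1.0, "b": -1.0, "c": 25.0})
    with pytest.raises(ValueError, match="missing"):
        families.validate_params("pk", {"b": 0.2})
    with pytest.raises(ValueError, match="a"):
        families.validate_params(
            "modified_pk",
            {"b": 0.2, "mu": 22, "sigma1": 3, "sigma2": 9, "a": -0.01})


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown family"):
        fc.get_family("brass")
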