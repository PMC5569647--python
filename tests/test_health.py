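"""Lifetable construction and both health-expectancy routes, checked
against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import demotime as dt
from demotime.exceptions import InvalidArgumentError, UndefinedExpectancyError


def random_lifetable(rng, omega=None):
    omega = int(rng.integers(3, 90)) if omega is None else omega
    q = rng.uniform(0.01, 0.6, omega + 1)
    return dt.build_lifetable(qx=q)


# --- oracles -----------------------------------------------------------

def sullivan_oracle(lt, pi_values, x0):
    """Spreadsheet-style summation over ages."""
    total = 0.0
    for a in range(x0, lt.omega + 1):
        total += lt.L[a] * pi_values[a - x0]
    return total / lt.l[x0]


def ttd_oracle(lt, g_values, x0):
    """Enumerate each death age separately: full years at every completed
    time-to-death below k plus half a year at k."""
    total = 0.0
    for a in range(x0, lt.omega + 1):
        k = a - x0
        unhealthy = sum(g_values[t] for t in range(k)) + 0.5 * g_values[k]
        total += lt.d[a] * unhealthy
    return total / lt.l[x0]


# --- lifetable construction -------------------------------------------

class TestBuildLifetable:
    def test_three_age_hand_computation(self, toy_lifetable):
        lt = toy_lifetable
        assert lt.l.tolist() == [1.0, 0.5, 0.25]
        assert lt.d.tolist() == [0.5, 0.25, 0.25]
        assert lt.L.tolist() == [0.75, 0.375, 0.125]
        assert lt.e[0] == pytest.approx(1.25)
        assert lt.e[1] == pytest.approx(1.0)
        assert lt.e[2] == pytest.approx(0.5)

    def test_certain_death_in_first_interval(self):
        lt = dt.build_lifetable(qx=[1.0])
        assert lt.e[0] == pytest.approx(0.5)

    def test_invariants_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lt = random_lifetable(rng)
            assert np.all(np.diff(lt.l) <= 0)
            assert np.all(lt.d >= 0)
            np.testing.assert_allclose(lt.d, lt.l - np.append(lt.l[1:], 0.0), atol=1e-15)
            # deaths above x exhaust survivors at x
            np.testing.assert_allclose(
                np.cumsum(lt.d[::-1])[::-1], lt.l, rtol=1e-12
            )

    def test_hazard_input(self):
        lt = dt.build_lifetable(hazard=[0.1, 0.1, 0.1])
        assert lt.l[1] == pytest.approx(np.exp(-0.1))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"qx": [0.5], "hazard": [0.5]},
            {},
            {"qx": [1.5]},
            {"qx": [-0.1]},
            {"hazard": [-1.0]},
            {"qx": [0.5], "radix": 0.0},
        ],
    )
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            dt.build_lifetable(**kwargs)

    def test_gompertz_survivorship_closed_form(self):
        params = dt.GompertzParams(a=1e-4, b=0.1)
        lt = dt.gompertz_lifetable(params, omega=110)
        x = np.arange(110 + 1)
        analytic = np.exp(-(params.a / params.b) * (np.exp(params.b * x) - 1.0))
        np.testing.assert_allclose(lt.l, analytic, atol=1e-12)

    def test_small_b_limit_is_exponential(self):
        # as the aging rate vanishes, e(0) approaches the exponential mean 1/a
        lt = dt.gompertz_lifetable(dt.GompertzParams(a=0.1, b=1e-9), omega=300)
        assert lt.e[0] == pytest.approx(1 / 0.1, abs=0.05)

    def test_lower_hazard_raises_expectancy(self):
        e_hi = dt.gompertz_lifetable(dt.GompertzParams(a=1e-4, b=0.1)).e[0]
        e_lo = dt.gompertz_lifetable(dt.GompertzParams(a=0.5e-4, b=0.1)).e[0]
        assert e_lo > e_hi


# --- Sullivan method ---------------------------------------------------

class TestSullivan:
    def test_zero_prevalence(self, toy_lifetable):
        hle, uhle = dt.sullivan(toy_lifetable, dt.AgePrevalence([0.0]), 0)
        assert (hle, uhle) == (pytest.approx(1.25), 0.0)

    def test_constant_prevalence_factors_out(self, toy_lifetable):
        hle, uhle = dt.sullivan(toy_lifetable, dt.AgePrevalence([0.3]), 0)
        assert uhle == pytest.approx(0.3 * 1.25, abs=1e-12)

    def test_toy_schedule_matches_oracle(self, toy_lifetable):
        pi = [0.1, 0.2, 0.5]
        hle, uhle = dt.sullivan(toy_lifetable, dt.AgePrevalence(pi), 0)
        assert uhle == pytest.approx(0.2125, abs=1e-15)  # hand value
        assert uhle == pytest.approx(sullivan_oracle(toy_lifetable, pi, 0))
        assert hle + uhle == pytest.approx(toy_lifetable.e[0])

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            lt = random_lifetable(rng)
            x0 = int(rng.integers(0, lt.omega))
            pi = rng.uniform(0, 1, lt.omega - x0 + 1)
            _, uhle = dt.sullivan(lt, dt.AgePrevalence(pi, age0=x0), x0)
            assert uhle == pytest.approx(sullivan_oracle(lt, pi, x0), rel=1e-12)

    def test_no_survivors(self):
        lt = dt.build_lifetable(qx=[1.0, 1.0])
        with pytest.raises(UndefinedExpectancyError):
            dt.sullivan(lt, dt.AgePrevalence([0.5]), 1)


# --- time-to-death method ----------------------------------------------

class TestTTDExpectancies:
    def test_zero_prevalence(self, toy_lifetable):
        hle, uhle = dt.ttd_expectancies(toy_lifetable, dt.TTDPrevalence([0.0]), 0)
        assert uhle == 0.0 and hle == pytest.approx(1.25)

    def test_constant_prevalence_closed_form(self, toy_lifetable):
        _, uhle = dt.ttd_expectancies(toy_lifetable, dt.TTDPrevalence([0.4]), 0)
        assert uhle == pytest.approx(0.4 * 1.25, abs=1e-15)

    def test_toy_schedule_matches_oracle(self, toy_lifetable):
        g = [1.0, 0.5, 0.0]
        _, uhle = dt.ttd_expectancies(toy_lifetable, dt.TTDPrevalence(g), 0)
        assert uhle == pytest.approx(0.9375, abs=1e-15)  # hand value
        assert uhle == pytest.approx(ttd_oracle(toy_lifetable, g, 0))

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            lt = random_lifetable(rng)
            x0 = int(rng.integers(0, lt.omega))
            g = rng.uniform(0, 1, lt.omega - x0 + 1)
            _, uhle = dt.ttd_expectancies(lt, dt.TTDPrevalence(g), x0)
            assert uhle == pytest.approx(ttd_oracle(lt, g, x0), rel=1e-12)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            lt = random_lifetable(rng)
            g = rng.uniform(0, 0.8, lt.omega + 1)
            bump = rng.uniform(0, 0.2, lt.omega + 1)
            _, u1 = dt.ttd_expectancies(lt, dt.TTDPrevalence(g), 0)
            _, u2 = dt.ttd_expectancies(lt, dt.TTDPrevalence(g + bump), 0)
            assert u2 >= u1 - 1e-12

    def test_complement_identity_both_methods(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            lt = random_lifetable(rng)
            x0 = int(rng.integers(0, lt.omega))
            g = rng.uniform(0, 1, lt.omega + 1)
            hle_t, uhle_t = dt.ttd_expectancies(lt, dt.TTDPrevalence(g), x0)
            hle_s, uhle_s = dt.sullivan(lt, dt.AgePrevalence(g, age0=0), x0)
            assert hle_t + uhle_t == pytest.approx(lt.e[x0], abs=1e-12)
            assert hle_s + uhle_s == pytest.approx(lt.e[x0], abs=1e-12)

    def test_prevalence_validation(self):
        with pytest.raises(InvalidArgumentError):
            dt.TTDPrevalence([1.2])
        with pytest.raises(InvalidArgumentError):
            dt.AgePrevalence([-0.1])


# --- implied age prevalence --------------------------------------------

class TestImpliedAgePrevalence:
    def test_constant_mixture_is_constant(self, gompertz_lifetable_default):
        pi = dt.implied_age_prevalence(gompertz_lifetable_default, dt.TTDPrevalence([0.3]))
        np.testing.assert_allclose(pi.pi, 0.3, atol=1e-12)

    def test_values_are_probabilities(self, gompertz_lifetable_default):
        rng = np.random.default_rng(5)
        g = rng.uniform(0, 1, 111)
        pi = dt.implied_age_prevalence(gompertz_lifetable_default, dt.TTDPrevalence(g))
        assert np.all((pi.pi >= 0) & (pi.pi <= 1))

    def test_older_mortality_lowers_fixed_age_prevalence(self):
        """With g falling in time-to-death, shifting deaths to higher ages
        puts any fixed age farther from death, so prevalence there drops."""
        g = dt.ttd_prevalence_schedule(dt.LogisticTTDParams())
        heavy = dt.gompertz_lifetable(dt.GompertzParams(a=2e-4, b=0.1))
        light = dt.gompertz_lifetable(dt.GompertzParams(a=0.5e-4, b=0.1))
        pi_heavy = dt.implied_age_prevalence(heavy, g)
        pi_light = dt.implied_age_prevalence(light, g)
        ages = np.arange(40, 90)
        assert np.all(pi_light.pi[ages] < pi_heavy.pi[ages])

    def test_sullivan_with_implied_curve_near_ttd(self):
        """On the *same* lifetable the Sullivan route through the implied
        curve agrees with the direct time-to-death route within the
        documented bound: half the total variation of g plus half the
        first-interval death share."""
        rng = np.random.default_rng(6)
        for _ in range(30):
            lt = random_lifetable(rng)
            gv = np.sort(rng.uniform(0, 1, lt.omega + 1))[::-1]
            g = dt.TTDPrevalence(gv)
            x0 = int(rng.integers(0, lt.omega))
            _, u_ttd = dt.ttd_expectancies(lt, g, x0)
            _, u_sul = dt.sullivan(lt, dt.implied_age_prevalence(lt, g), x0)
            bound = 0.5 * np.abs(np.diff(gv)).sum() + 0.5 * gv.max() * lt.d[x0] / lt.l[x0]
            assert abs(u_sul - u_ttd) <= bound


# --- scenario comparison ------------------------------------------------

class TestCompareScenarios:
    def test_identical_lifetables_give_zero_deltas(self, gompertz_lifetable_default):
        g = dt.ttd_prevalence_schedule(dt.LogisticTTDParams())
        rep = dt.compare_scenarios(
            gompertz_lifetable_default, gompertz_lifetable_default, g, 60
        )
        assert rep.d_le == 0.0 and rep.d_uhle_ttd == 0.0 and rep.d_uhle_fixed == 0.0

    def test_constant_g_collapses_both_methods(self, gompertz_lifetable_default):
        base = gompertz_lifetable_default
        new = dt.gompertz_lifetable(dt.GompertzParams(a=0.8e-4, b=0.1))
        rep = dt.compare_scenarios(base, new, dt.TTDPrevalence([0.25]), 60)
        assert rep.d_uhle_ttd == pytest.approx(0.25 * rep.d_le, abs=1e-10)
        assert rep.d_uhle_fixed == pytest.approx(0.25 * rep.d_le, abs=1e-10)

    def test_frozen_curve_overstates_unhealthy_growth(self):
        """Mortality improvement + prevalence concentrated near death:
        the frozen Sullivan curve projects more extra unhealthy years
        than the time-to-death model."""
        g = dt.ttd_prevalence_schedule(dt.LogisticTTDParams())
        base = dt.gompertz_lifetable(dt.GompertzParams(a=1e-4, b=0.1))
        new = dt.gompertz_lifetable(dt.GompertzParams(a=0.8e-4, b=0.1))
        rep = dt.compare_scenarios(base, new, g, 60)
        assert rep.d_le > 0
        assert rep.d_uhle_fixed > rep.d_uhle_ttd
        assert rep.d_hle_ttd == pytest.approx(rep.d_le - rep.d_uhle_ttd)

    def test_mismatched_grids_rejected(self, gompertz_lifetable_default):
        short = dt.gompertz_lifetable(dt.GompertzParams(), omega=90)
        with pytest.raises(InvalidArgumentError):
            dt.compare_scenarios(
                gompertz_lifetable_default, short, dt.TTDPrevalence([0.1]), 0
            )
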