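"""Competing-risk fracture probabilities: closed forms, numerical oracle,
monotonicity and decomposition properties."""

import math

import numpy as np
import pandas as pd
import pytest

import fraxepi as fx
from fraxepi.probability import HazardCurve, LifeTable, cumulative_incidence


def random_curve(rng, lo=0.0, hi=100.0, n=6, scale=0.05, terminal=110.0):
    knots = np.sort(rng.uniform(lo, hi - 1, n))
    knots[0] = lo
    hazards = rng.uniform(0.0, scale, n)
    return HazardCurve.from_arrays(knots, hazards, terminal_age=terminal)


def fine_grid_oracle(fracture, death, start, horizon, rr=1.0, step=1e-4):
    """Fine-grid midpoint quadrature of the cause-specific cumulative
    incidence, on a grid aligned to the hazard knots; independent of the
    closed-form segment path."""
    end = start + horizon
    cuts = sorted(
        {start, end}
        | {k for k in fracture.knots if start < k < end}
        | {k for k in death.knots if start < k < end}
    )
    prob, cumhaz = 0.0, 0.0
    for t0, t1 in zip(cuts, cuts[1:]):
        hf = rr * fracture.hazard_at(t0)
        total = hf + death.hazard_at(t0)
        n = max(int(math.ceil((t1 - t0) / step)), 1)
        dt = (t1 - t0) / n
        mids = cumhaz + total * (np.arange(n) + 0.5) * dt
        prob += float(np.sum(hf * np.exp(-mids)) * dt)
        cumhaz += total * (t1 - t0)
    return prob


class TestClosedForms:
    def test_zero_fracture_hazard_gives_zero(self):
        hf = HazardCurve.constant(0.0)
        hd = HazardCurve.constant(0.02)
        assert cumulative_incidence(hf, hd, 0, 10) == 0.0

    def test_constant_hazards_competing_death(self):
        hf = HazardCurve.constant(0.01)
        hd = HazardCurve.constant(0.02)
        expected = (0.01 / 0.03) * (1 - math.exp(-0.3))
        assert cumulative_incidence(hf, hd, 0, 10) == pytest.approx(
            expected, abs=1e-12)

    def test_no_competing_death_limit(self):
        hf = HazardCurve.constant(0.01)
        hd = HazardCurve.constant(0.0)
        assert cumulative_incidence(hf, hd, 0, 10) == pytest.approx(
            1 - math.exp(-0.1), abs=1e-12)

    def test_deathless_lifetime_is_one_minus_exp_cumhazard(self):
        # piecewise fracture hazard, zero mortality: P = 1 - e^{-H}
        hf = HazardCurve.from_arrays([50, 60, 70], [0.002, 0.005, 0.01],
                                     terminal_age=110)
        hd = HazardCurve.constant(0.0, start=50, terminal_age=110)
        H = 0.002 * 10 + 0.005 * 10 + 0.01 * 40
        assert cumulative_incidence(hf, hd, 50, 60) == pytest.approx(
            1 - math.exp(-H), abs=1e-12)


class TestNumericalOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_piecewise_curves_match_fine_grid(self, seed):
        rng = np.random.default_rng(seed)
        hf = random_curve(rng)
        hd = random_curve(rng)
        start = float(rng.uniform(1, 80))
        p = cumulative_incidence(hf, hd, start, 10.0, rr=1.5)
        assert p == pytest.approx(
            fine_grid_oracle(hf, hd, start, 10.0, rr=1.5), abs=1e-8)


class TestInvariants:
    def test_probability_bounds_and_horizon_monotonicity(self):
        rng = np.random.default_rng(7)
        hf, hd = random_curve(rng), random_curve(rng)
        probs = [cumulative_incidence(hf, hd, 40, T) for T in (1, 5, 10, 30, 60)]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_monotone_in_rr_and_hazards(self):
        rng = np.random.default_rng(11)
        hf, hd = random_curve(rng), random_curve(rng)
        p1 = cumulative_incidence(hf, hd, 45, 20, rr=1.0)
        p2 = cumulative_incidence(hf, hd, 45, 20, rr=2.0)
        assert p2 > p1
        hf_hi = HazardCurve.from_arrays(hf.knots,
                                        [h + 0.01 for h in hf.hazards])
        assert cumulative_incidence(hf_hi, hd, 45, 20) > p1
        hd_hi = HazardCurve.from_arrays(hd.knots,
                                        [h + 0.05 for h in hd.hazards])
        assert cumulative_incidence(hf, hd_hi, 45, 20) < p1

    def test_additivity_through_intermediate_age(self):
        # P(0->T) = P(0->s) + S(s) * P(s->T-s) with S the event-free survival
        rng = np.random.default_rng(13)
        hf, hd = random_curve(rng), random_curve(rng)
        start, s, T = 42.0, 6.0, 25.0
        full = cumulative_incidence(hf, hd, start, T)
        first = cumulative_incidence(hf, hd, start, s)
        rest = cumulative_incidence(hf, hd, start + s, T - s)
        log_s = 0.0
        from fraxepi.probability import _segments
        for t0, t1, a, b in _segments(hf, hd, start, start + s):
            log_s -= (a + b) * (t1 - t0)
        assert full == pytest.approx(first + math.exp(log_s) * rest,
                                     abs=1e-12)

    def test_uncovered_window_is_hard_error(self):
        hf = HazardCurve.from_arrays([50], [0.01], terminal_age=80)
        hd = HazardCurve.constant(0.02)
        with pytest.raises(ValueError, match="cover"):
            cumulative_incidence(hf, hd, 75, 10)
        with pytest.raises(ValueError, match="cover"):
            cumulative_incidence(hd, hf, 75, 10)


@pytest.fixture(scope="module")
def flat_life_table():
    ages = list(range(40, 111))
    return LifeTable.from_hazards(
        "female", ages, [0.001 * math.exp(0.09 * (a - 40)) for a in ages])


class TestEngine:
    def test_ten_year_rr_damped_by_competing_risk(self, printed_hip_rates,
                                                  flat_life_table):
        p1 = fx.ten_year_probability(printed_hip_rates, flat_life_table,
                                     age=75, sex="female", rr=1.0)
        p2 = fx.ten_year_probability(printed_hip_rates, flat_life_table,
                                     age=75, sex="female", rr=2.0)
        assert p1.probability < p2.probability < 2 * p1.probability

    def test_zero_incidence_table_gives_zero(self, flat_life_table):
        zero = pd.DataFrame([
            {"sex": "female", "age_lo": lo, "age_hi": lo + 5,
             "site": "hip", "rate": 0.0} for lo in range(40, 100, 5)
        ])
        result = fx.ten_year_probability(zero, flat_life_table,
                                         age=60, sex="female")
        assert result.probability == 0.0

    def test_lifetime_exceeds_ten_year(self, printed_hip_rates,
                                       flat_life_table):
        ten = fx.ten_year_probability(printed_hip_rates, flat_life_table,
                                      age=50, sex="female")
        life = fx.lifetime_risk(printed_hip_rates, flat_life_table,
                                sex="female", from_age=50)
        assert 0.0 < ten.probability < life.probability < 1.0

    def test_terminal_age_truncation_negligible(self, printed_hip_rates):
        # death hazard >= 0.3/y beyond 100 kills the integrand tail
        ages = list(range(40, 111))
        heavy = LifeTable.from_hazards(
            "female", ages,
            [0.01 if a < 100 else 0.35 for a in ages])
        p100 = fx.lifetime_risk(printed_hip_rates, heavy, sex="female",
                                terminal_age=100.0)
        p110 = fx.lifetime_risk(printed_hip_rates, heavy, sex="female",
                                terminal_age=110.0)
        assert abs(p110.probability - p100.probability) < 1e-4

    def test_death_probability_conversion(self):
        lt = LifeTable.from_death_probabilities("male", [60], [0.02])
        assert lt.hazards[0] == pytest.approx(-math.log(0.98))
        with pytest.raises(ValueError):
            LifeTable.from_death_probabilities("male", [60], [1.0])

    def test_rate_scale_is_per_hundred_thousand(self, flat_life_table):
        # a one-band table at 1000/100k must behave like hazard 0.01/y
        table = pd.DataFrame([{"sex": "female", "age_lo": 40,
                               "age_hi": math.inf, "site": "hip",
                               "rate": 1000.0}])
        curve = HazardCurve.from_incidence_table(table, "female")
        assert curve.hazard_at(70) == pytest.approx(0.01)
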