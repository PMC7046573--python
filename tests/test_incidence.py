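"""Rates, exact Poisson intervals, capture uplift, ratios, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import fraxepi as fx
from fraxepi.bands import AgeBand, HIP_BANDS, NONHIP_BANDS
from fraxepi.incidence import (
    StratumCount,
    poisson_ci_events,
    round_half_away,
)


def invert_poisson_tails(events: int, level: float = 0.95):
    """Independent oracle: event-scale Garwood limits by numerically
    inverting the Poisson tail probabilities (no gamma quantiles)."""
    alpha = 1.0 - level
    if events == 0:
        lower = 0.0
    else:
        lower = optimize.brentq(
            lambda lam: stats.poisson.sf(events - 1, lam) - alpha / 2.0,
            1e-12, 10.0 * events + 50.0, xtol=1e-12, rtol=1e-13,
        )
    upper = optimize.brentq(
        lambda lam: stats.poisson.cdf(events, lam) - alpha / 2.0,
        1e-12, 10.0 * events + 100.0, xtol=1e-12, rtol=1e-13,
    )
    return lower, upper


class TestCrudeRate:
    @pytest.mark.parametrize("events,py,expected", [
        (252, 106_880, 235.78),   # adjusted women 40+ over three years
        (0, 50_000, 0.0),
        (90, 24_590, 366.0),
    ])
    def test_rate_per_hundred_thousand(self, events, py, expected):
        assert fx.crude_rate(events, py) == pytest.approx(expected, abs=0.005)

    def test_non_positive_person_years_rejected(self):
        with pytest.raises(ValueError):
            fx.crude_rate(10, 0)

    @given(events=st.floats(0, 1e4), py=st.floats(1, 1e7),
           scale=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, events, py, scale):
        base = fx.crude_rate(events, py)
        scaled = fx.crude_rate(events * scale, py * scale)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestExactPoissonCI:
    def test_printed_men_forty_plus_interval(self):
        lo, hi = fx.exact_poisson_ci(141, 77_949, 0.95)
        assert (round_half_away(lo), round_half_away(hi)) == (152, 213)

    def test_zero_events_lower_bound_zero(self):
        lo, hi = fx.exact_poisson_ci(0, 10_000, 0.95)
        assert lo == 0.0 and hi > 0.0

    def test_event_scale_example(self):
        lo, hi = poisson_ci_events(5, 0.95)
        assert lo == pytest.approx(1.6235, abs=5e-5)
        assert hi == pytest.approx(11.668, abs=5e-4)

    @pytest.mark.parametrize("events", list(range(0, 51)))
    def test_agrees_with_tail_inversion_oracle(self, events):
        rng = np.random.default_rng(events)
        py = float(rng.uniform(1e3, 1e6))
        lo, hi = fx.exact_poisson_ci(events, py)
        olo, ohi = invert_poisson_tails(events)
        assert hi == pytest.approx(ohi / py * 1e5, rel=1e-6)
        if events > 0:
            assert lo == pytest.approx(olo / py * 1e5, rel=1e-6)

    def test_coverage_of_true_rate_is_conservative(self):
        # exact intervals over-cover slightly: 94-97% at nominal 95%
        rng = np.random.default_rng(20150101)
        true_rate, py = 180.0, 80_000.0
        counts = rng.poisson(true_rate / 1e5 * py, size=2000)
        covered = 0
        for k in counts:
            lo, hi = fx.exact_poisson_ci(int(k), py)
            covered += lo <= true_rate <= hi
        assert 0.94 <= covered / 2000 <= 0.97

    def test_upper_bound_strictly_increases_in_events(self):
        uppers = [fx.exact_poisson_ci(k, 50_000)[1] for k in range(30)]
        assert all(b > a for a, b in zip(uppers, uppers[1:]))

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 1.2])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            fx.exact_poisson_ci(5, 1000, level)


class TestCaptureAdjustment:
    def test_study_uplift_twenty_nine_percent(self):
        adj = fx.capture_adjustment_factor(65, 19)
        assert adj.factor == pytest.approx(84 / 65)
        assert adj.percent_uplift == 29

    @pytest.mark.parametrize("retro,extra,factor", [
        (65, 0, 1.0), (50, 10, 1.2),
    ])
    def test_factor_arithmetic(self, retro, extra, factor):
        assert fx.capture_adjustment_factor(retro, extra).factor == \
            pytest.approx(factor)

    def test_zero_retrospective_count_undefined(self):
        with pytest.raises(ValueError):
            fx.capture_adjustment_factor(0, 19)

    def test_uplift_applies_to_retrospective_years_only(self):
        adj = fx.capture_adjustment_factor(65, 19,
                                           applies_to_years=[2015, 2016])
        out = fx.apply_adjustment({2015: 65, 2016: 65, 2017: 84}, adj)
        assert out == pytest.approx({2015: 84.0, 2016: 84.0, 2017: 84.0})
        assert sum(out.values()) == pytest.approx(252.0)

    def test_identity_factor_passes_through(self):
        adj = fx.capture_adjustment_factor(65, 0, applies_to_years=[2015])
        assert fx.apply_adjustment({2015: 50}, adj) == {2015: 50.0}

    def test_fractions_carried_unrounded(self):
        adj = fx.capture_adjustment_factor(100, 8, applies_to_years=[2015])
        assert fx.apply_adjustment({2015: 50}, adj)[2015] == pytest.approx(54.0)


class TestFemaleMaleRatio:
    @pytest.mark.parametrize("female,male,expected", [
        (214, 134, 1.6),   # hip, all ages
        (70, 88, 0.8),     # hip below 70 years
        (144, 46, 3.1),    # hip at 70 and over
        (435, 101, 4.3),   # forearm
        (125, 49, 2.6),    # humerus
        (7, 7, 1.0),
    ])
    def test_reported_to_one_decimal(self, female, male, expected):
        assert round(fx.female_male_ratio(female, male), 1) == expected

    def test_absent_when_no_male_events(self):
        assert fx.female_male_ratio(10, 0) is None


class TestAggregateBands:
    def build_hip_table(self, tables, population):
        strata = [
            StratumCount(row.sex, AgeBand(row.age_lo, row.age_hi), "hip",
                         row.events, row.person_years)
            for row in tables["hip"].itertuples(index=False)
        ]
        return fx.incidence_table(strata)

    def test_person_years_sum_into_coarser_bands(self, tables, population):
        table = self.build_hip_table(tables, population)
        coarse = fx.aggregate_bands(table, NONHIP_BANDS)
        row = coarse[(coarse["sex"] == "female") & (coarse["age_lo"] == 40)]
        assert float(row["person_years"].iloc[0]) == pytest.approx(37_016)
        assert float(row["events"].iloc[0]) == 9  # 5 + 4

    def test_single_band_union_is_conservation(self, tables, population):
        table = self.build_hip_table(tables, population)
        total = fx.aggregate_bands(table, (AgeBand(40, math.inf),))
        women = total[total["sex"] == "female"].iloc[0]
        assert women["events"] == 214
        assert women["person_years"] == pytest.approx(106_880)
        assert women["rate"] == pytest.approx(214 / 106_880 * 1e5)

    def test_rate_and_interval_recomputed_from_sums(self, tables, population):
        table = self.build_hip_table(tables, population)
        coarse = fx.aggregate_bands(table, NONHIP_BANDS)
        for row in coarse.itertuples(index=False):
            lo, hi = fx.exact_poisson_ci(row.events, row.person_years)
            assert row.ci_low == pytest.approx(lo)
            assert row.ci_high == pytest.approx(hi)

    def test_non_nesting_scheme_rejected(self, tables, population):
        table = self.build_hip_table(tables, population)
        with pytest.raises(ValueError, match="nest"):
            fx.aggregate_bands(table, (AgeBand(42, math.inf),))


class TestCarePathway:
    def test_marginal_fixture_percentages(self, hip_records):
        cp = fx.care_pathway_summary(hip_records)
        assert cp.n_cases == 348 and cp.n_refused == 82
        assert cp.n_admitted == 266 and cp.n_surgical == 200
        assert cp.pct_refused == 24
        assert cp.pct_surgical_among_admitted == 75
        assert cp.pct_untreated_or_conservative == 43

    def test_surgical_proportion_absent_without_admissions(self):
        from conftest import make_record
        recs = [make_record(admitted="refused", surgical=False)]
        assert fx.care_pathway_summary(recs).pct_surgical_among_admitted is None
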