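"""Kinetic-competition model: examples, inverses, barrier equivalence, race oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from walkerstep.kinetics import (
    BarrierPair,
    KineticParams,
    NonInvertibleYieldError,
    StateLabel,
    UndefinedCompetitionError,
    barriers_from_rates,
    cumulative_walk_yield,
    fuel_binding_barrier,
    relative_stepping_rate,
    simulate_race,
    stepping_rate_from_yield,
    trapped_fraction,
    yield_from_barriers,
    yield_from_rates,
)

RATES = st.floats(min_value=1e-8, max_value=1e4)
CONCS = st.floats(min_value=1e-12, max_value=1e-3)
HYP = settings(max_examples=60, deadline=None, derandomize=True)


class TestYieldFromRates:
    def test_symmetric_race_gives_half(self):
        # k_s equals k_FB*[F1]: both channels equally likely.
        assert yield_from_rates(KineticParams(2.3e-4, 2.3e5, 1e-9)) == pytest.approx(0.5)

    def test_no_fuel_gives_unity(self):
        assert yield_from_rates(KineticParams(5.0, 2.3e5, 0.0)) == 1.0

    def test_trapping_dominated(self):
        # k_FB*F1 = 2.3 vs k_s = 1.
        assert yield_from_rates(KineticParams(1.0, 2.3e5, 1e-5)) == pytest.approx(
            1.0 / 3.3, abs=1e-4
        )

    def test_undefined_competition(self):
        with pytest.raises(UndefinedCompetitionError):
            yield_from_rates(KineticParams(0.0, 2.3e5, 0.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-1.0, 2.3e5, 1e-9)

    @HYP
    @given(k_s=RATES, k_fb=RATES, f1=CONCS)
    def test_normalization(self, k_s, k_fb, f1):
        p = KineticParams(k_s, k_fb, f1)
        assert yield_from_rates(p) + trapped_fraction(p) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_fuel_and_rate(self):
        f1_grid = np.logspace(-9, -4, 12)
        ys = [yield_from_rates(KineticParams(1.0, 2.3e5, f)) for f in f1_grid]
        assert all(a > b for a, b in zip(ys, ys[1:]))
        ks_grid = np.logspace(-4, 2, 12)
        ys = [yield_from_rates(KineticParams(k, 2.3e5, 1e-7)) for k in ks_grid]
        assert all(a < b for a, b in zip(ys, ys[1:]))


class TestSteppingRateFromYield:
    def test_symmetric_point(self):
        assert stepping_rate_from_yield(0.5, 2.3e5, 1e-9) == pytest.approx(2.3e-4)

    def test_low_yield_gives_slow_rate(self):
        # Y = 0.132 at 1 nM fuel corresponds to the ~3.5e-5 s^-1 regime.
        k = stepping_rate_from_yield(0.132, 2.3e5, 1e-9)
        assert k == pytest.approx(2.3e-4 * 0.132 / 0.868, rel=1e-12)
        assert k == pytest.approx(3.5e-5, rel=0.01)

    @HYP
    @given(k_s=RATES, k_fb=RATES, f1=st.floats(min_value=1e-12, max_value=1e-3))
    def test_exact_inverse(self, k_s, k_fb, f1):
        p = KineticParams(k_s, k_fb, f1)
        y = yield_from_rates(p)
        # The inversion is exact where it is well conditioned; at saturated
        # yields the 1 - Y cancellation destroys rate information, which is
        # why the pipeline flags such conditions instead of inverting them.
        if 1e-3 < y < 1.0 - 1e-3:
            assert stepping_rate_from_yield(y, k_fb, f1) == pytest.approx(k_s, rel=1e-12)

    def test_degenerate_yields_rejected(self):
        with pytest.raises(NonInvertibleYieldError):
            stepping_rate_from_yield(1.0, 2.3e5, 1e-9)
        with pytest.raises(NonInvertibleYieldError):
            stepping_rate_from_yield(0.0, 2.3e5, 1e-9)
        with pytest.raises(ValueError):
            stepping_rate_from_yield(1.2, 2.3e5, 1e-9)


class TestBarrierPicture:
    def test_reference_point_and_tenfold(self):
        b = BarrierPair(dG_s=5.0, dG_FB0=12.0, c0=1e-6)
        assert fuel_binding_barrier(1e-6, b) == pytest.approx(12.0)
        assert fuel_binding_barrier(1e-5, b) == pytest.approx(12.0 - math.log(10))
        with pytest.raises(ValueError):
            fuel_binding_barrier(0.0, b)

    def test_equal_barriers_give_half(self):
        b = BarrierPair(dG_s=7.0, dG_FB0=7.0, c0=1e-9)
        assert yield_from_barriers(b, 1e-9) == pytest.approx(0.5)

    def test_ln10_barrier_gap(self):
        b = BarrierPair(dG_s=7.0 + math.log(10), dG_FB0=7.0, c0=1e-9)
        assert yield_from_barriers(b, 1e-9) == pytest.approx(1.0 / 11.0, rel=1e-12)

    def test_infinite_placement_barrier(self):
        b = BarrierPair(dG_s=math.inf, dG_FB0=5.0)
        assert yield_from_barriers(b, 1e-9) == 0.0

    @HYP
    @given(k_s=RATES, k_fb=RATES, f1=st.floats(min_value=1e-12, max_value=1e-3),
           prefactor=st.floats(min_value=1e-2, max_value=1e6))
    def test_rate_barrier_equivalence(self, k_s, k_fb, f1, prefactor):
        """Eq-1/Eq-2 consistency: a common prefactor maps rates onto barriers
        reproducing the same yield to 10 significant digits."""
        p = KineticParams(k_s, k_fb, f1)
        b = barriers_from_rates(p, prefactor=prefactor)
        assert yield_from_barriers(b, f1) == pytest.approx(yield_from_rates(p), rel=1e-10)

    def test_barrier_yield_matches_rate_fuel_dependence(self):
        p0 = KineticParams(0.7, 2.3e5, 1.0)
        b = barriers_from_rates(p0, prefactor=100.0)
        for f1 in np.logspace(-9, -4, 7):
            expected = yield_from_rates(KineticParams(0.7, 2.3e5, f1))
            assert yield_from_barriers(b, f1) == pytest.approx(expected, rel=1e-10)


class TestRelativeRate:
    def test_identity_and_decade_scale(self):
        assert relative_stepping_rate(3.0, 3.0) == 1.0
        # An 11.5 kBT penalty is ~5 orders of magnitude in rate.
        assert relative_stepping_rate(14.5, 3.0) == pytest.approx(math.exp(-11.5), rel=1e-12)
        assert relative_stepping_rate(14.5, 3.0) == pytest.approx(1e-5, rel=0.02)
        assert relative_stepping_rate(math.inf, 3.0) == 0.0


class TestSimulateRace:
    def test_no_fuel_all_placed(self):
        res = simulate_race(KineticParams(2.0, 2.3e5, 0.0), n_motors=1000, seed=1)
        assert res.fraction_placed == 1.0

    def test_symmetric_race_binomial_bound(self):
        res = simulate_race(KineticParams(2.3e-4, 2.3e5, 1e-9), n_motors=100_000, seed=7)
        assert abs(res.fraction_placed - 0.5) <= 3 * math.sqrt(0.25 / 100_000)

    @pytest.mark.parametrize(
        "k_s,k_fb,f1",
        [(1.0, 2.3e5, 1e-5), (0.01, 1e4, 1e-6), (5.0, 2.3e5, 1e-5), (2e-4, 1e6, 1e-9),
         (0.5, 2.3e5, 4e-6)],
    )
    def test_agrees_with_analytic_yield(self, k_s, k_fb, f1):
        p = KineticParams(k_s, k_fb, f1)
        res = simulate_race(p, n_motors=100_000, seed=29)
        expected = yield_from_rates(p)
        se = max(res.stderr, math.sqrt(expected * (1 - expected) / res.n_motors))
        assert abs(res.fraction_placed - expected) <= 3 * se

    def test_deterministic_given_seed(self):
        p = KineticParams(1.0, 2.3e5, 1e-5)
        a = simulate_race(p, 5000, seed=11)
        b = simulate_race(p, 5000, seed=11)
        assert a.fraction_placed == b.fraction_placed


class TestCumulativeWalk:
    def test_perfect_and_single_step(self):
        assert cumulative_walk_yield(1.0, 32) == 1.0
        assert cumulative_walk_yield(0.5, 1) == 0.5

    def test_32_steps_compound_to_44_percent(self):
        assert cumulative_walk_yield(0.9747, 32) == pytest.approx(0.44, abs=0.005)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cumulative_walk_yield(1.1, 3)
        with pytest.raises(ValueError):
            cumulative_walk_yield(0.9, -1)


def test_state_labels_closed_set():
    assert {s.value for s in StateLabel} == {"S_LL", "S_LL_star", "S_LP", "S_Trap"}
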