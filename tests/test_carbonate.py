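"""Tests of the carbonate-system constants, speciation, and inverse solves."""

import math

import numpy as np
import pytest

from acidnit import carbonate as cs
from acidnit.errors import DomainError, NoSolutionError

ENV = cs.EnvConditions(25.0, 35.0)


def brute_force_ph(ta, dic, env, n_grid=1_000_001):
    """Grid-search oracle: pH in [2, 12] minimising |TA(ph, dic) - ta|.

    Evaluates the alkalinity expression directly with vectorised numpy,
    independent of the package's root-finding path.
    """
    k = cs.constants(env)
    tb = cs.total_boron(env.salinity) * 1e-6
    ph = np.linspace(2.0, 12.0, n_grid)
    h = 10.0**-ph
    dic_mol = dic * 1e-6
    denom = h * h + k.k1 * h + k.k1 * k.k2
    hco3 = dic_mol * k.k1 * h / denom
    co3 = dic_mol * k.k1 * k.k2 / denom
    ta_grid = (hco3 + 2 * co3 + tb * k.kb / (k.kb + h) + k.kw / h - h) * 1e6
    return ph[int(np.argmin(np.abs(ta_grid - ta)))]


class TestConstants:
    def test_pk1_pk2_at_reference_conditions(self):
        k = cs.constants(ENV)
        assert 5.8 <= -math.log10(k.k1) <= 6.1
        assert 8.9 <= -math.log10(k.k2) <= 9.3

    def test_k1_increases_with_temperature(self):
        assert cs.constants(ENV).k1 > cs.constants(cs.EnvConditions(5.0, 35.0)).k1

    def test_deterministic(self):
        assert cs.constants(ENV) == cs.constants(cs.EnvConditions(25.0, 35.0))

    def test_k1_greater_than_k2(self):
        for t in (0.0, 10.0, 25.0, 35.0):
            for s in (5.0, 20.0, 35.0):
                k = cs.constants(cs.EnvConditions(t, s))
                assert k.k1 > k.k2 > 0

    def test_out_of_range_env_rejected(self):
        with pytest.raises(DomainError):
            cs.EnvConditions(45.0, 35.0)
        with pytest.raises(DomainError):
            cs.EnvConditions(25.0, 50.0)


class TestTotalBoron:
    def test_zero_at_zero_salinity(self):
        assert cs.total_boron(0.0) == 0.0

    def test_reference_value(self):
        assert 410.0 <= cs.total_boron(35.0) <= 420.0

    def test_linear_in_salinity(self):
        assert cs.total_boron(17.5) == pytest.approx(cs.total_boron(35.0) / 2.0, rel=1e-12)


class TestSpeciation:
    def test_co2_equals_hco3_at_ph_equal_pk1(self):
        k = cs.constants(ENV)
        state = cs.speciate_from_ph_dic(-math.log10(k.k1), 2000.0, ENV, k)
        assert state.co2_star == pytest.approx(state.hco3, rel=1e-12)

    def test_zero_dic_leaves_borate_water_alkalinity(self):
        state = cs.speciate_from_ph_dic(8.1, 0.0, ENV)
        assert state.co2_star == state.hco3 == state.co3 == 0.0
        assert state.ta == pytest.approx(state.boh4 + state.oh - state.h, rel=1e-12)

    @pytest.mark.parametrize("ph", [7.0, 7.8, 8.1, 8.5])
    def test_closure_identities(self, ph):
        """DIC and TA component sums close to 1e-6 relative."""
        state = cs.speciate_from_ph_dic(ph, 2100.0, ENV)
        assert state.dic == pytest.approx(state.co2_star + state.hco3 + state.co3, rel=1e-6)
        assert state.ta == pytest.approx(
            state.hco3 + 2 * state.co3 + state.boh4 + state.oh - state.h, rel=1e-6
        )
        assert min(state.co2_star, state.hco3, state.co3, state.boh4, state.oh, state.h) >= 0

    def test_pco2_monotone_decreasing_in_ph_at_fixed_dic(self):
        phs = np.linspace(6.0, 10.0, 81)
        pco2 = [cs.speciate_from_ph_dic(ph, 2000.0, ENV).pco2 for ph in phs]
        assert all(a > b for a, b in zip(pco2, pco2[1:]))


class TestInverseSolves:
    def test_round_trip_ph_dic(self):
        env = cs.EnvConditions(25.0, 30.0)
        state = cs.speciate_from_ph_dic(8.10, 2000.0, env)
        back = cs.solve_ph_from_ta_dic(state.ta, state.dic, env)
        assert back.ph == pytest.approx(8.10, abs=1e-6)

    def test_round_trip_ta_pco2(self):
        state = cs.speciate_from_ph_dic(8.05, 2050.0, ENV)
        back = cs.solve_from_ta_pco2(state.ta, state.pco2, ENV)
        assert back.ph == pytest.approx(8.05, abs=1e-6)
        assert back.dic == pytest.approx(state.dic, rel=1e-6)

    def test_higher_ta_at_fixed_dic_gives_higher_ph(self):
        ref = cs.solve_ph_from_ta_dic(2300.0, 2100.0, ENV)
        doubled = cs.solve_ph_from_ta_dic(2800.0, 2100.0, ENV)
        assert doubled.ph > ref.ph

    def test_matches_brute_force_grid_oracle(self):
        """Bracketed root agrees with exhaustive grid search on random pairs."""
        rng = np.random.default_rng(42)
        resolution = 10.0 / 1_000_000
        for _ in range(8):
            ph_true = rng.uniform(7.2, 8.6)
            dic = rng.uniform(1600.0, 2400.0)
            ta = cs.speciate_from_ph_dic(ph_true, dic, ENV).ta
            solved = cs.solve_ph_from_ta_dic(ta, dic, ENV).ph
            assert abs(solved - brute_force_ph(ta, dic, ENV)) <= resolution

    def test_pairwise_consistency_on_random_grid(self):
        """All three solve directions agree on a seeded 100-point grid."""
        rng = np.random.default_rng(7)
        k = cs.constants(ENV)
        for _ in range(100):
            ph = rng.uniform(7.0, 8.8)
            dic = rng.uniform(1500.0, 2500.0)
            ref = cs.speciate_from_ph_dic(ph, dic, ENV, k)
            from_ta_dic = cs.solve_ph_from_ta_dic(ref.ta, ref.dic, ENV, k)
            from_ta_pco2 = cs.solve_from_ta_pco2(ref.ta, ref.pco2, ENV, k)
            assert from_ta_dic.ph == pytest.approx(ph, abs=1e-6)
            assert from_ta_pco2.ph == pytest.approx(ph, abs=1e-6)
            assert from_ta_dic.pco2 == pytest.approx(ref.pco2, abs=1e-3)
            assert from_ta_pco2.dic == pytest.approx(ref.dic, rel=1e-6)

    def test_ph_gap_of_doubled_pco2_matches_factorial_design(self):
        """Doubling pCO2 400 -> 800 µatm at fixed TA lowers pH by ~0.3,
        consistent with a 8.1/7.8 x 400/800 treatment factorial."""
        low = cs.solve_from_ta_pco2(2300.0, 400.0, ENV)
        high = cs.solve_from_ta_pco2(2300.0, 800.0, ENV)
        assert 0.25 <= low.ph - high.ph <= 0.35

    def test_ph_increases_as_pco2_falls(self):
        phs = [cs.solve_from_ta_pco2(2300.0, p, ENV).ph for p in (1200, 800, 400, 200, 50)]
        assert all(a < b for a, b in zip(phs, phs[1:]))

    def test_unbracketable_target_reports_no_solution(self):
        with pytest.raises(NoSolutionError):
            cs.solve_ph_from_ta_dic(-20000.0, 2000.0, ENV)


def test_nbs_sws_conversion_is_invertible():
    ph = 8.1
    assert cs.sws_to_nbs(cs.nbs_to_sws(ph, ENV), ENV) == pytest.approx(ph, abs=1e-12)
    # the two scales differ by order 0.1 at seawater conditions
    assert 0.05 < abs(cs.nbs_to_sws(ph, ENV) - ph) < 0.2
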