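"""Unit and property tests for the 15N tracer rate estimators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidnit import synthetic_data as sd
from acidnit import tracer_rates as tr
from acidnit.errors import DegenerateIntervalError, UndefinedInputError


def two_point_observations(series):
    """First/last NOx- and N2O observations of a simulated series."""
    d = series.data
    first, last = d.iloc[0], d.iloc[-1]
    nox = (
        tr.NoxObservation(first.time_h, first.nox_umol_L, first.r15_nox),
        tr.NoxObservation(last.time_h, last.nox_umol_L, last.r15_nox),
    )
    n2o = (
        tr.N2oObservation(first.time_h, first.n2o45_pmol, first.n2o46_pmol),
        tr.N2oObservation(last.time_h, last.n2o45_pmol, last.n2o46_pmol),
    )
    return nox, n2o


class TestAtomFraction:
    @pytest.mark.parametrize(
        "ambient, added, expected",
        [(8.0, 2.0, 0.2), (5.0, 0.0, 0.0), (1.0, 1.0, 0.5)],
    )
    def test_definition(self, ambient, added, expected):
        assert tr.atom_fraction(tr.TracerPool(ambient, added)) == pytest.approx(expected)

    def test_zero_pool_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            tr.atom_fraction(tr.TracerPool(0.0, 0.0))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            tr.TracerPool(-1.0, 2.0)


class TestNitrificationRate:
    def test_hand_example(self):
        obs0 = tr.NoxObservation(0.0, 10.0, 0.0)
        obs1 = tr.NoxObservation(24.0, 12.0, 0.05)
        result = tr.nitrification_rate(obs0, obs1, F=0.2)
        assert result.value == pytest.approx(125.0, rel=1e-12)
        assert result.estimator_id == "eq_two_point"
        assert not result.negative

    def test_no_accumulation_gives_zero(self):
        obs = tr.NoxObservation(0.0, 10.0, 0.01)
        assert tr.nitrification_rate(obs, tr.NoxObservation(24.0, 10.0, 0.01), 0.2).value == 0.0

    def test_label_decline_flagged_not_clamped(self):
        obs0 = tr.NoxObservation(0.0, 10.0, 0.05)
        obs1 = tr.NoxObservation(24.0, 10.0, 0.01)
        result = tr.nitrification_rate(obs0, obs1, 0.2)
        assert result.value < 0
        assert result.negative

    def test_zero_F_undefined(self):
        obs0 = tr.NoxObservation(0.0, 10.0, 0.0)
        obs1 = tr.NoxObservation(24.0, 12.0, 0.05)
        with pytest.raises(UndefinedInputError):
            tr.nitrification_rate(obs0, obs1, 0.0)

    def test_degenerate_interval(self):
        obs = tr.NoxObservation(5.0, 10.0, 0.0)
        with pytest.raises(DegenerateIntervalError):
            tr.nitrification_rate(obs, tr.NoxObservation(5.0, 12.0, 0.05), 0.2)

    @pytest.mark.parametrize("rate", [10.0, 100.0, 350.0])
    @pytest.mark.parametrize("f", [0.05, 0.2, 0.5, 0.9])
    def test_recovers_generating_rate_at_zero_noise(self, rate, f):
        """Constant-rate, constant-F forward simulation is inverted exactly."""
        added = 10.0 * f / (1.0 - f) if f < 1 else 1.0
        config = sd.SimulationConfig(
            true_nitrification_rate=rate,
            tracer=tr.TracerPool(10.0, added),
            noise_cv=0.0,
            seed=0,
        )
        series = sd.simulate_incubation(config)
        (obs0, obs1), _ = two_point_observations(series)
        recovered = tr.nitrification_rate(obs0, obs1, series.tracer.F)
        assert recovered.value == pytest.approx(rate, rel=1e-9)

    def test_exact_for_any_sampling_pair(self):
        """Any two timepoints of a zero-noise series give the same rate."""
        config = sd.SimulationConfig(
            true_nitrification_rate=80.0,
            sample_times=(0.0, 5.0, 8.0, 12.0, 24.0),
            noise_cv=0.0,
            seed=0,
        )
        series = sd.simulate_incubation(config)
        d = series.data
        obs = [tr.NoxObservation(r.time_h, r.nox_umol_L, r.r15_nox) for r in d.itertuples()]
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                assert tr.nitrification_rate(obs[i], obs[j], series.tracer.F).value == pytest.approx(
                    80.0, rel=1e-9
                )

    def test_regression_estimator_matches_two_point_at_zero_noise(self):
        config = sd.SimulationConfig(
            true_nitrification_rate=60.0,
            sample_times=(0.0, 5.0, 8.0, 12.0, 24.0),
            noise_cv=0.0,
            seed=0,
        )
        series = sd.simulate_incubation(config)
        obs = [
            tr.NoxObservation(r.time_h, r.nox_umol_L, r.r15_nox)
            for r in series.data.itertuples()
        ]
        result = tr.nitrification_rate_regression(obs, series.tracer.F)
        assert result.value == pytest.approx(60.0, rel=1e-9)
        assert result.estimator_id == "eq_regression"

    def test_nox_slope_rate(self):
        obs = [tr.NoxObservation(t, 10.0 + 0.1 * t, 0.0) for t in (0, 5, 8, 12, 24)]
        assert tr.nox_slope_rate(obs).value == pytest.approx(100.0, rel=1e-9)


class TestN2oEstimators:
    def test_isotopologue_hand_example(self):
        n0 = tr.N2oObservation(0.0, 0.0, 0.0)
        n1 = tr.N2oObservation(24.0, 48.0, 12.0)
        assert tr.n2o_rate_isotopologue(n0, n1, 0.2, 4.0).value == pytest.approx(8.75, rel=1e-12)

    def test_atom_balance_hand_example(self):
        n0 = tr.N2oObservation(0.0, 0.0, 0.0)
        n1 = tr.N2oObservation(24.0, 48.0, 12.0)
        assert tr.n2o_rate_atom_balance(n0, n1, 0.2, 4.0).value == pytest.approx(3.75, rel=1e-12)

    def test_no_accumulation_gives_zero(self):
        n0 = tr.N2oObservation(0.0, 3.0, 1.0)
        n1 = tr.N2oObservation(24.0, 3.0, 1.0)
        assert tr.n2o_rate_isotopologue(n0, n1, 0.2, 4.0).value == 0.0
        assert tr.n2o_rate_atom_balance(n0, n1, 0.2, 4.0).value == 0.0

    @pytest.mark.parametrize("bad", [{"F": 0.0}, {"volume": 0.0}])
    def test_undefined_inputs(self, bad):
        n0 = tr.N2oObservation(0.0, 0.0, 0.0)
        n1 = tr.N2oObservation(24.0, 48.0, 12.0)
        kwargs = {"F": 0.2, "volume": 4.0, **bad}
        with pytest.raises(UndefinedInputError):
            tr.n2o_rate_isotopologue(n0, n1, kwargs["F"], kwargs["volume"])
        with pytest.raises(UndefinedInputError):
            tr.n2o_rate_atom_balance(n0, n1, kwargs["F"], kwargs["volume"])

    @settings(derandomize=True, max_examples=50)
    @given(
        d45=st.floats(0.1, 1e4),
        d46=st.floats(0.1, 1e4),
        scale=st.floats(0.01, 100.0),
        f=st.floats(0.01, 1.0),
    )
    def test_linearity_in_isotopologue_increments(self, d45, d46, scale, f):
        """Scaling both increments by c scales both estimators by c."""
        base0 = tr.N2oObservation(0.0, 0.0, 0.0)
        one = tr.N2oObservation(24.0, d45, d46)
        scaled = tr.N2oObservation(24.0, d45 * scale, d46 * scale)
        for est in (tr.n2o_rate_isotopologue, tr.n2o_rate_atom_balance):
            assert est(base0, scaled, f, 4.0).value == pytest.approx(
                scale * est(base0, one, f, 4.0).value, rel=1e-9
            )

    @pytest.mark.parametrize("f", [0.05, 0.1, 0.2, 0.5])
    def test_estimator_ratio_is_two_minus_f_under_binomial_pairing(self, f):
        """The mass-45/46 formula overestimates the N-atom rate by (2 - F)."""
        added = 10.0 * f / (1.0 - f)
        config = sd.SimulationConfig(
            true_n2o_rate=40.0,
            tracer=tr.TracerPool(10.0, added),
            noise_cv=0.0,
            seed=0,
        )
        series = sd.simulate_incubation(config)
        _, (n0, n1) = two_point_observations(series)
        printed = tr.n2o_rate_isotopologue(n0, n1, series.tracer.F, config.volume).value
        balance = tr.n2o_rate_atom_balance(n0, n1, series.tracer.F, config.volume).value
        assert balance == pytest.approx(40.0, rel=1e-9)
        assert printed / balance == pytest.approx(2.0 - series.tracer.F, rel=1e-9)


class TestPercentChange:
    @pytest.mark.parametrize(
        "treatment, control, expected",
        [(75.0, 100.0, -25.0), (100.0, 100.0, 0.0), (123.0, 100.0, 23.0)],
    )
    def test_examples(self, treatment, control, expected):
        assert tr.percent_change(treatment, control) == pytest.approx(expected)

    def test_zero_control_undefined(self):
        with pytest.raises(UndefinedInputError):
            tr.percent_change(50.0, 0.0)


def test_parse_time_rejects_out_of_range_atom_fraction():
    with pytest.raises(ValueError):
        tr.NoxObservation(0.0, 10.0, 1.2)
    with pytest.raises(ValueError):
        tr.NoxObservation(0.0, 10.0, -0.1)
    with pytest.raises(ValueError):
        tr.NoxObservation(0.0, 10.0, math.nan)
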