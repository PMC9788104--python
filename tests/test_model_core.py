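"""Vital-rate kernels, fitness derivatives and regime certification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reefrescue import (
    CompetitionMatrix,
    CoralParams,
    MacroalgaeParams,
    competition_preset,
    coral_fitness,
    coral_growth_rate,
    coral_mortality_rate,
    fitness_curvature,
    fitness_gradient,
    free_space,
    macroalgal_fitness,
    selection_attenuation,
    verify_regime,
)

UNIT = CoralParams(r_C0=1.0, w=1.0, V=0.05)


class TestGrowthRate:
    def test_peak_at_optimum(self):
        p = CoralParams(r_C0=2.0, w=1.5)
        peak = coral_growth_rate(27.0, 27.0, p)
        assert peak == pytest.approx(p.r_C0 / np.sqrt(2 * np.pi * p.w**2))

    def test_unit_displacement_matches_closed_form(self):
        # exp(-1/2)/sqrt(2*pi) ~ 0.2420
        assert coral_growth_rate(28.0, 27.0, UNIT) == pytest.approx(0.24197, abs=1e-5)

    def test_tails_vanish_and_symmetry(self):
        d = np.linspace(0.0, 6.0, 25)
        up = coral_growth_rate(27.0 + d, 27.0, UNIT)
        down = coral_growth_rate(27.0 - d, 27.0, UNIT)
        np.testing.assert_allclose(up, down, rtol=1e-12)
        assert coral_growth_rate(27.0 + 40.0, 27.0, UNIT) < 1e-12
        assert np.all(up > 0)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            coral_growth_rate(np.nan, 27.0, UNIT)
        with pytest.raises(ValueError):
            coral_growth_rate(27.0, np.inf, UNIT)


class TestMortalityRate:
    def test_zero_at_and_below_optimum(self):
        assert coral_mortality_rate(27.0, 27.0, UNIT) == 0.0
        assert coral_mortality_rate(22.0, 27.0, UNIT) == 0.0

    def test_unit_excess_matches_closed_form(self):
        # 1 - exp(-1/2) ~ 0.3935
        assert coral_mortality_rate(28.0, 27.0, UNIT) == pytest.approx(0.39347, abs=1e-5)

    def test_monotone_and_bounded_above_optimum(self):
        d = np.linspace(0.01, 8.0, 50)
        m = coral_mortality_rate(27.0 + d, 27.0, UNIT)
        assert np.all(np.diff(m) > 0)
        assert np.all((m > 0) & (m < 1))

    def test_continuous_at_optimum(self):
        eps = 1e-8
        assert coral_mortality_rate(27.0 + eps, 27.0, UNIT) < 1e-12


class TestFreeSpace:
    @pytest.mark.parametrize(
        "C,M,expected", [(0.25, 0.0, 0.75), (0.0, 0.0, 1.0), (0.6, 0.4, 0.0)]
    )
    def test_values(self, C, M, expected):
        assert free_space(C, M) == pytest.approx(expected)

    def test_overfull_state_rejected(self):
        with pytest.raises(ValueError):
            free_space(0.7, 0.5)


class TestFitness:
    def test_no_competition_no_mortality_equals_peak_growth(self, bistable):
        p = CoralParams(r_C0=2.0, w=1.0)
        g = coral_fitness(27.0, 27.0, 0.0, 0.0, p, bistable)
        assert g == pytest.approx(p.r_C0 / np.sqrt(2 * np.pi))

    def test_growth_nulled_at_saturating_self_competition(self, bistable):
        C = 1.0 / bistable.alpha_CC
        assert coral_fitness(27.0, 27.0, C, 0.0, UNIT, bistable) == pytest.approx(0.0)

    @given(
        T=st.floats(20.0, 35.0),
        z=st.floats(20.0, 35.0),
        C=st.floats(0.0, 0.6),
        M=st.floats(0.0, 0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_compositional(self, T, z, C, M):
        a = competition_preset("bistable")
        expect = (
            coral_growth_rate(T, z, UNIT) * (1 - a.alpha_CM * M - a.alpha_CC * C)
            - coral_mortality_rate(T, z, UNIT)
        )
        assert coral_fitness(T, z, C, M, UNIT, a) == pytest.approx(expect, rel=1e-12)

    def test_macroalgal_fitness_values_and_temperature_independence(
        self, macroalgae, bistable
    ):
        assert macroalgal_fitness(0.0, 0.0, macroalgae, bistable) == pytest.approx(
            macroalgae.r_M0 - macroalgae.m_M0
        )
        expect = (
            macroalgae.r_M0
            * (1 - bistable.alpha_MC * 0.5 - bistable.alpha_MM * 0.2)
            - macroalgae.m_M0
        )
        assert macroalgal_fitness(0.5, 0.2, macroalgae, bistable) == pytest.approx(
            expect, rel=1e-12
        )
        # no temperature argument exists: the rate structure is constant


class TestTraitDerivatives:
    """Analytic gradient/curvature against central finite differences."""

    @pytest.mark.parametrize("offset", [-2.5, -1.0, -0.3, 0.3, 1.0, 2.5, 4.0])
    @pytest.mark.parametrize("cover", [(0.0, 0.0), (0.3, 0.2)])
    def test_gradient_matches_finite_difference(self, offset, cover, bistable):
        C, M = cover
        T, z = 27.0 + offset, 27.0
        h = 1e-5
        fd = (
            coral_fitness(T, z + h, C, M, UNIT, bistable)
            - coral_fitness(T, z - h, C, M, UNIT, bistable)
        ) / (2 * h)
        grad = fitness_gradient(T, z, C, M, UNIT, bistable)
        assert grad == pytest.approx(fd, rel=1e-6, abs=1e-10)

    @pytest.mark.parametrize("offset", [-2.0, -0.5, 0.5, 1.5])
    def test_curvature_matches_finite_difference_where_unclamped(self, offset, bistable):
        T, z = 27.0 + offset, 27.0
        h = 1e-4
        fd = (
            coral_fitness(T, z + h, 0.1, 0.1, UNIT, bistable)
            - 2 * coral_fitness(T, z, 0.1, 0.1, UNIT, bistable)
            + coral_fitness(T, z - h, 0.1, 0.1, UNIT, bistable)
        ) / h**2
        curv = fitness_curvature(T, z, 0.1, 0.1, UNIT, bistable)
        assert curv == pytest.approx(min(fd, 0.0), rel=1e-4, abs=1e-8)

    def test_gradient_zero_and_curvature_negative_at_optimum(self, bistable):
        assert fitness_gradient(27.0, 27.0, 0.0, 0.0, UNIT, bistable) == 0.0
        expect = -UNIT.r_C0 / (UNIT.w**2 * np.sqrt(2 * np.pi * UNIT.w**2))
        assert fitness_curvature(27.0, 27.0, 0.0, 0.0, UNIT, bistable) == pytest.approx(
            expect
        )

    def test_warming_selects_higher_optimum(self, bistable):
        d = np.linspace(0.05, 5.0, 40)
        g = fitness_gradient(27.0 + d, 27.0, 0.2, 0.2, UNIT, bistable)
        assert np.all(g > 0)

    @given(offset=st.floats(-6.0, 8.0))
    @settings(max_examples=60, deadline=None)
    def test_curvature_never_positive(self, offset):
        a = competition_preset("bistable")
        assert fitness_curvature(27.0 + offset, 27.0, 0.2, 0.3, UNIT, a) <= 0.0


class TestSelectionAttenuation:
    @pytest.mark.parametrize(
        "C,expected",
        [(1e-6, 0.0), (1e-5, 0.9), (0.25, 1 - 4e-6)],
    )
    def test_values(self, C, expected):
        assert selection_attenuation(C, 1e-6) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_bounded(self):
        C = np.logspace(-8, 0, 100)
        q = selection_attenuation(C, 1e-6)
        assert np.all(np.diff(q) >= 0)
        assert np.all((q >= 0) & (q < 1))


class TestVerifyRegime:
    def test_shipped_presets_certify_their_regimes(self, coral, macroalgae):
        assert (
            verify_regime(competition_preset("bistable"), coral, macroalgae).regime
            == "bistable"
        )
        assert (
            verify_regime(competition_preset("coexistence"), coral, macroalgae).regime
            == "coexistence"
        )

    def test_uncoupled_competitors_coexist(self, coral, macroalgae):
        a = CompetitionMatrix(alpha_CC=1.1, alpha_CM=0.0, alpha_MC=0.0, alpha_MM=1.1)
        report = verify_regime(a, coral, macroalgae)
        assert report.regime == "coexistence"
        (interior,) = [eq for eq in report.stable_equilibria]
        assert interior[0] > 0 and interior[1] > 0

    def test_nonviable_macroalgae_classified_other(self, coral, bistable):
        mp = MacroalgaeParams(r_M0=0.05, m_M0=0.1)
        report = verify_regime(bistable, coral, mp)
        assert report.regime == "other"
        stable = report.stable_equilibria
        assert len(stable) == 1
        assert stable[0][0] > 0 and stable[0][1] == pytest.approx(0.0, abs=1e-9)
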