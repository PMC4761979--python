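"""Coupled binding/dimerization equilibrium solver and its derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from znabeta.equilibria import (
    EquilibriumState,
    ExchangeRates,
    InfeasibleTargetError,
    SpeciesSystem,
    calibrate_kdim,
    dimer_chain_fraction,
    fraction_from_rates,
    predict_dimer_curve,
    solve_equilibrium,
)

MM = 1e-3


def quad_complex(Ka, P0, Zn0):
    """Independent closed-form [PZn] for the 1:1 (Kdim=0) limit."""
    a = P0 + Zn0 + 1.0 / Ka
    return (a - np.sqrt(a * a - 4.0 * P0 * Zn0)) / 2.0


class TestSolveEquilibrium:
    def test_no_binding_closed_form(self):
        st_ = solve_equilibrium(SpeciesSystem(0.0, 0.0, 1 * MM, 2 * MM))
        assert st_.conc_PZn == 0.0 and st_.conc_P2Zn == 0.0
        assert st_.conc_P == 1 * MM and st_.conc_Zn == 2 * MM

    def test_zero_zinc_closed_form(self):
        st_ = solve_equilibrium(SpeciesSystem(1e5, 1e4, 1 * MM, 0.0))
        assert st_.conc_PZn == 0.0 and st_.conc_P2Zn == 0.0
        assert st_.conc_P == 1 * MM

    def test_matches_1to1_quadratic_when_kdim_zero(self):
        st_ = solve_equilibrium(SpeciesSystem(1190.0, 0.0, 1 * MM, 1 * MM))
        expected = quad_complex(1190.0, 1 * MM, 1 * MM)
        assert st_.conc_PZn == pytest.approx(expected, rel=1e-9)
        assert st_.conc_PZn == pytest.approx(0.412 * MM, rel=1e-3)

    def test_brute_force_grid_oracle(self):
        # The solver's root coincides with the residual-norm minimum on a
        # dense grid over (free P, free Zn).
        sys_ = SpeciesSystem(2400.0, 330.0, 2.3 * MM, 1.15 * MM)
        st_ = solve_equilibrium(sys_)
        P = np.linspace(1e-7, sys_.P_total, 600)
        Zn = np.linspace(1e-9, sys_.Zn_total, 600)
        PP, ZZ = np.meshgrid(P, Zn)
        PZn = sys_.Ka_mono * PP * ZZ
        P2Zn = sys_.Kdim * PZn * PP
        rP = PP + PZn + 2 * P2Zn - sys_.P_total
        rZ = ZZ + PZn + P2Zn - sys_.Zn_total
        norm = np.hypot(rP, rZ)
        i, j = np.unravel_index(np.argmin(norm), norm.shape)
        assert st_.conc_P == pytest.approx(PP[i, j], abs=P[1] - P[0])
        assert st_.conc_Zn == pytest.approx(ZZ[i, j], abs=Zn[1] - Zn[0])

    def test_strong_binding_limit_consumes_peptide(self):
        st_ = solve_equilibrium(SpeciesSystem(1e12, 0.0, 1 * MM, 2 * MM))
        assert st_.conc_P < 1e-9
        assert st_.conc_PZn == pytest.approx(1 * MM, rel=1e-5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ka=st.floats(0.0, 1e7),
        kd=st.floats(0.0, 1e7),
        pt=st.floats(1e-6, 1e-1),
        zt=st.floats(0.0, 1e-1),
    )
    def test_mass_conservation_property(self, ka, kd, pt, zt):
        st_ = solve_equilibrium(SpeciesSystem(ka, kd, pt, zt))
        scale = max(pt, zt)
        assert abs(st_.conc_P + st_.conc_PZn + 2 * st_.conc_P2Zn - pt) <= 1e-10 * scale
        assert abs(st_.conc_Zn + st_.conc_PZn + st_.conc_P2Zn - zt) <= 1e-10 * scale
        # action-law consistency
        assert st_.conc_PZn == pytest.approx(
            ka * st_.conc_P * st_.conc_Zn, rel=1e-8, abs=1e-30)
        assert st_.conc_P2Zn == pytest.approx(
            kd * st_.conc_PZn * st_.conc_P, rel=1e-8, abs=1e-30)

    def test_invalid_system_rejected(self):
        with pytest.raises(ValueError):
            SpeciesSystem(-1.0, 0.0, 1 * MM, 1 * MM)
        with pytest.raises(ValueError):
            SpeciesSystem(1.0, 0.0, 0.0, 1 * MM)


class TestDimerFraction:
    def test_zero_kdim_gives_zero(self):
        st_ = solve_equilibrium(SpeciesSystem(2400.0, 0.0, 1 * MM, 0.5 * MM))
        assert dimer_chain_fraction(st_) == 0.0

    def test_monotone_in_peptide_total(self):
        fr = predict_dimer_curve(2400.0, 330.0,
                                 np.geomspace(0.1 * MM, 10 * MM, 12), 0.5)
        assert np.all(np.diff(fr) >= 0)
        assert np.all((fr >= 0) & (fr <= 1))

    def test_monotone_in_kdim(self):
        fracs = [
            dimer_chain_fraction(
                solve_equilibrium(SpeciesSystem(2400.0, kd, 2.3 * MM, 1.15 * MM)))
            for kd in [0.0, 10.0, 100.0, 1e3, 1e4]
        ]
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_single_point_curve_matches_direct_solve(self):
        direct = dimer_chain_fraction(
            solve_equilibrium(SpeciesSystem(2400.0, 330.0, 1 * MM, 0.5 * MM)))
        curve = predict_dimer_curve(2400.0, 330.0, [1 * MM], 0.5)
        assert curve[0] == pytest.approx(direct, rel=1e-12)


class TestFractionFromRates:
    def test_symmetry(self):
        assert fraction_from_rates(ExchangeRates(5.0, 5.0)) == 0.5

    def test_printed_rates_arithmetic(self):
        # 8.6 / (8.6 + 31.3) = 8.6 / 39.9
        f = fraction_from_rates(ExchangeRates(8.6, 31.3))
        assert f == pytest.approx(0.21554, abs=1e-5)

    def test_slow_forward_limit(self):
        assert fraction_from_rates(ExchangeRates(1e-9, 10.0)) < 1e-9

    def test_rates_must_be_positive(self):
        with pytest.raises(ValueError):
            ExchangeRates(0.0, 1.0)


class TestCalibrateKdim:
    def test_round_trip(self):
        kd = calibrate_kdim(2400.0, 2.3 * MM, 1.15 * MM, 0.2155)
        st_ = solve_equilibrium(SpeciesSystem(2400.0, kd, 2.3 * MM, 1.15 * MM))
        assert dimer_chain_fraction(st_) == pytest.approx(0.2155, abs=1e-6)

    def test_value_from_measured_exchange_rates(self):
        # frozen against an independent scipy.brentq solve of the same
        # fixed-point condition
        target = fraction_from_rates(ExchangeRates(8.6, 31.3))
        kd = calibrate_kdim(2400.0, 2.3 * MM, 1.15 * MM, target)
        assert kd == pytest.approx(327.97, rel=1e-3)

    def test_small_target_gives_small_kdim(self):
        kd = calibrate_kdim(2400.0, 2.3 * MM, 1.15 * MM, 1e-6)
        assert kd < 0.01

    def test_unattainable_target_raises(self):
        # with almost no zinc the dimer fraction is capped far below 0.9
        with pytest.raises(InfeasibleTargetError):
            calibrate_kdim(2400.0, 1 * MM, 1e-6, 0.9)


@pytest.fixture(scope="module")
def calibrated():
    """Kdim calibrated from the measured exchange-rate dimer fraction."""
    target = fraction_from_rates(ExchangeRates(8.6, 31.3))
    return calibrate_kdim(2400.0, 2.3 * MM, 1.15 * MM, target)


class TestConcentrationPredictions:
    """Calibrated model reproduces the measured concentration dependence."""

    def test_concentrated_solution_fraction(self, calibrated):
        # frozen from the model solve at 6.5 mM / half-equivalence zinc
        fr = predict_dimer_curve(2400.0, calibrated, [6.5 * MM], 0.5)[0]
        assert fr == pytest.approx(0.3888, abs=0.002)

    def test_dilute_solution_fraction(self, calibrated):
        fr = predict_dimer_curve(2400.0, calibrated, [0.2 * MM], 0.5)[0]
        assert fr == pytest.approx(0.0157, abs=0.001)
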