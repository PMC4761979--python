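"""Two-site longitudinal exchange: propagation, simulation, rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from znabeta.magtransfer import (
    ExchangeDataset,
    ExchangeModel,
    fit_exchange,
    propagate,
    simulate_inversion_recovery,
)
from znabeta.synthetic import NoiseSpec, gen_mt

DELAYS = np.geomspace(1e-3, 1.0, 12)


def rk4_oracle(model, m0, t_end, dt=1e-5):
    """Step-wise explicit 4th-order integration of the exchange ODE."""
    L = model.rate_matrix
    meq = model.m_eq
    m = np.asarray(m0, dtype=float).copy()
    n = int(round(t_end / dt))

    def f(y):
        return -L @ (y - meq)

    for _ in range(n):
        k1 = f(m)
        k2 = f(m + 0.5 * dt * k1)
        k3 = f(m + 0.5 * dt * k2)
        k4 = f(m + dt * k3)
        m = m + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return m


class TestPropagate:
    def test_identity_at_zero_delay(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.2)
        m0 = np.array([-0.7, 0.2])
        assert np.allclose(propagate(model, m0, 0.0), m0)

    def test_decoupled_limit_is_two_exponentials(self):
        model = ExchangeModel(0.0, 0.0, 2.0, 0.5, 1.0, 0.3)
        m0 = np.array([-1.0, 0.3])
        t = np.array([0.1, 0.5, 1.0])
        out = propagate(model, m0, t)
        expect_m = 1.0 + (m0[0] - 1.0) * np.exp(-2.0 * t)
        expect_d = 0.3 + (m0[1] - 0.3) * np.exp(-0.5 * t)
        assert np.allclose(out[:, 0], expect_m, rtol=1e-12)
        assert np.allclose(out[:, 1], expect_d, rtol=1e-12)

    def test_closed_form_matches_rk4_integrator(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        m0 = np.array([-model.M_eq_m, model.M_eq_d])
        for t_end in (0.01, 0.05, 0.2):
            closed = propagate(model, m0, t_end)
            stepped = rk4_oracle(model, m0, t_end)
            assert np.allclose(closed, stepped, rtol=1e-6, atol=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        kmd=st.floats(0.1, 100.0),
        kdm=st.floats(0.1, 100.0),
        r1m=st.floats(0.1, 10.0),
        r1d=st.floats(0.1, 10.0),
        t=st.floats(0.0, 2.0),
    )
    def test_closed_form_matches_expm_property(self, kmd, kdm, r1m, r1d, t):
        from scipy.linalg import expm

        model = ExchangeModel.from_rates(kmd, kdm, r1m, r1d)
        m0 = np.array([-model.M_eq_m, model.M_eq_d])
        closed = propagate(model, m0, t)
        ref = model.m_eq + expm(-model.rate_matrix * t) @ (m0 - model.m_eq)
        assert np.allclose(closed, ref, rtol=1e-8, atol=1e-12)

    def test_degenerate_eigenvalues_handled(self):
        # equal diagonal, zero exchange: L has a doubly degenerate eigenvalue
        model = ExchangeModel(0.0, 0.0, 1.5, 1.5, 0.6, 0.4)
        m0 = np.array([-0.6, 0.4])
        out = propagate(model, m0, 0.3)
        expect = model.m_eq + (m0 - model.m_eq) * np.exp(-1.5 * 0.3)
        assert np.allclose(out, expect, rtol=1e-10)

    def test_eigenvalues_positive_for_positive_rates(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        eig = np.linalg.eigvals(model.rate_matrix)
        assert np.all(eig.real > 0)

    def test_detailed_balance_enforced_at_construction(self):
        with pytest.raises(ValueError):
            ExchangeModel(8.6, 31.3, 1.5, 1.5, M_eq_m=1.0, M_eq_d=1.0)


class TestSimulateInversionRecovery:
    def test_no_inversion_stays_at_equilibrium(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5,
                                         inversion_efficiency=0.0)
        ds = simulate_inversion_recovery(model, DELAYS)
        assert np.allclose(ds.I_mono, model.M_eq_m)
        assert np.allclose(ds.I_dimer, model.M_eq_d)

    def test_transfer_dip_requires_exchange(self):
        delays = np.geomspace(1e-4, 2.0, 60)
        coupled = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        ds = simulate_inversion_recovery(coupled, delays)
        assert ds.I_dimer.min() < coupled.M_eq_d - 1e-3  # transient dip

        uncoupled = ExchangeModel(0.0, 0.0, 1.5, 1.5,
                                  coupled.M_eq_m, coupled.M_eq_d)
        ds0 = simulate_inversion_recovery(uncoupled, delays)
        assert np.allclose(ds0.I_dimer, uncoupled.M_eq_d)

    def test_long_delay_returns_to_equilibrium(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        ds = simulate_inversion_recovery(model, np.array([0.001, 50.0]))
        assert ds.I_mono[-1] == pytest.approx(model.M_eq_m, abs=1e-6)
        assert ds.I_dimer[-1] == pytest.approx(model.M_eq_d, abs=1e-6)


class TestFitExchange:
    def test_exact_recovery_zero_noise(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5,
                                         inversion_efficiency=0.95)
        ds = gen_mt(model, DELAYS, noise=NoiseSpec(0.0))
        res = fit_exchange(ds)
        assert res.model.k_md == pytest.approx(8.6, rel=1e-4)
        assert res.model.k_dm == pytest.approx(31.3, rel=1e-4)
        assert res.model.R1_m == pytest.approx(1.5, rel=1e-3)

    def test_recovery_at_published_design(self):
        # the printed rates with 1% noise at the 12-delay design
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        ds = gen_mt(model, DELAYS, noise=NoiseSpec(0.01, 42))
        res = fit_exchange(ds)
        assert res.model.k_md == pytest.approx(8.6, abs=0.6)
        assert res.model.k_dm == pytest.approx(31.3, abs=2.3)
        assert not res.ill_conditioned

    def test_median_recovery_over_noise_realizations(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        kmds, kdms = [], []
        for seed in range(100):
            ds = gen_mt(model, DELAYS, noise=NoiseSpec(0.01, seed))
            res = fit_exchange(ds)
            kmds.append(res.model.k_md)
            kdms.append(res.model.k_dm)
        assert abs(np.median(kmds) - 8.6) / 8.6 < 0.10
        assert abs(np.median(kdms) - 31.3) / 31.3 < 0.10

    def test_equilibrium_ratio_ties_to_rate_ratio(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        ds = gen_mt(model, DELAYS, noise=NoiseSpec(0.01, 7))
        res = fit_exchange(ds)
        m = res.model
        assert m.M_eq_d / m.M_eq_m == pytest.approx(m.k_md / m.k_dm, rel=1e-9)

    def test_uninformative_delays_flagged(self):
        # all delays far longer than the exchange timescale: rates cannot
        # be resolved, which must surface as an ill-conditioned covariance
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        delays = np.linspace(20.0, 40.0, 10)
        ds = gen_mt(model, delays, noise=NoiseSpec(0.01, 3))
        res = fit_exchange(ds)
        assert res.ill_conditioned

    def test_too_few_delays_rejected(self):
        model = ExchangeModel.from_rates(8.6, 31.3, 1.5, 1.5)
        ds = gen_mt(model, DELAYS[:5], noise=NoiseSpec(0.0))
        with pytest.raises(ValueError):
            fit_exchange(ds)

    def test_dataset_requires_increasing_delays(self):
        with pytest.raises(ValueError):
            ExchangeDataset(np.array([0.1, 0.1, 0.2]), np.zeros(3), np.zeros(3))
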