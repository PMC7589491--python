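"""Simulator physics: closed-form propagation, sampling events, mass balance."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from franzperm import (
    CellGeometry,
    SamplingSchedule,
    SimulationConfig,
    propagate_interval,
    simulate_permeation,
)

GEOM = CellGeometry(1.77, 1.0, 7.0, 1.0)


def ode_receiver_concentration(c_start, q_total, peff, geom, delta_t_s):
    """Independent oracle: integrate dC_r/dt = P·S·(C_d − C_r)/V_r numerically."""

    def rhs(_t, y):
        c_r = y[0]
        c_d = (q_total - c_r * geom.receiver_volume) / geom.donor_volume
        return [peff * geom.area * (c_d - c_r) / geom.receiver_volume]

    sol = solve_ivp(rhs, (0.0, delta_t_s), [c_start], rtol=1e-11, atol=1e-14)
    return sol.y[0, -1]


class TestPropagateInterval:
    def test_zero_permeability_is_identity(self):
        assert propagate_interval(3.0, 8000.0, 0.0, GEOM, 3600.0) == pytest.approx(3.0)

    def test_long_time_reaches_equilibrium(self):
        c = propagate_interval(0.0, 8000.0, 1e-5, GEOM, 1e12)
        assert c == pytest.approx(8000.0 / 8.0, rel=1e-12)

    @pytest.mark.parametrize("peff", [1e-7, 1e-6, 1e-5, 1e-4])
    @pytest.mark.parametrize("dt", [900.0, 3600.0, 14400.0])
    def test_matches_ode_integration(self, peff, dt):
        """Closed form equals step-size-refined numerical integration."""
        expected = ode_receiver_concentration(0.0, 8000.0, peff, GEOM, dt)
        got = propagate_interval(0.0, 8000.0, peff, GEOM, dt)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_example_one_hour_interval(self):
        # 1e-5 cm/s over one hour from an empty receiver, oracle-checked
        expected = ode_receiver_concentration(0.0, 8000.0, 1e-5, GEOM, 3600.0)
        assert propagate_interval(0.0, 8000.0, 1e-5, GEOM, 3600.0) == pytest.approx(
            expected, rel=1e-6
        )

    def test_negative_delta_t_rejected(self):
        with pytest.raises(ValueError):
            propagate_interval(0.0, 100.0, 1e-5, GEOM, -1.0)

    def test_monotonic_approach_to_equilibrium(self):
        c_eq = 8000.0 / 8.0
        values = [
            propagate_interval(0.0, 8000.0, 1e-5, GEOM, dt)
            for dt in np.linspace(0, 8e5, 40)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert all(v <= c_eq + 1e-9 for v in values)


def make_config(**kwargs):
    defaults = dict(
        true_peff=1e-5,
        geometry=GEOM,
        schedule=SamplingSchedule([0.25, 0.5, 1, 2, 3, 4, 5, 6, 10, 12]),
        donor_concentration_0=10_000.0,
        n_replicates=2,
        noise_cv=0.0,
        seed=7,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSimulatePermeation:
    def test_no_transport_gives_zero_series(self):
        exp = simulate_permeation(make_config(true_peff=0.0))
        for rep in exp.replicates:
            assert np.all(rep == 0.0)

    def test_noise_free_series_strictly_increasing_far_from_equilibrium(self):
        exp = simulate_permeation(make_config(true_peff=1e-6))
        for rep in exp.replicates:
            assert np.all(np.diff(rep) > 0)

    def test_same_seed_reproduces_different_seed_differs(self):
        a = simulate_permeation(make_config(noise_cv=0.05, seed=3))
        b = simulate_permeation(make_config(noise_cv=0.05, seed=3))
        c = simulate_permeation(make_config(noise_cv=0.05, seed=4))
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra, rb)
        assert any(
            not np.array_equal(ra, rc) for ra, rc in zip(a.replicates, c.replicates)
        )

    @pytest.mark.parametrize("peff", [1e-6, 1e-5, 1e-4])
    def test_mass_balance_and_dynamics_against_two_state_ode(self, peff):
        """Independent two-compartment ODE replay: the recorded series matches
        and donor + receiver + withdrawn mass equals the initial donor load."""
        geom = GEOM
        c0 = 10_000.0
        cfg = make_config(true_peff=peff, n_replicates=1)
        exp = simulate_permeation(cfg)
        rep = exp.replicates[0]
        total0 = geom.donor_volume * c0

        def rhs(_t, y):
            c_r, c_d = y
            j = peff * geom.area * (c_d - c_r)   # µg/s across the membrane
            return [j / geom.receiver_volume, -j / geom.donor_volume]

        c_r, c_d, withdrawn = 0.0, c0, 0.0
        for k, dt_h in enumerate(exp.schedule.intervals_h):
            sol = solve_ivp(rhs, (0.0, dt_h * 3600.0), [c_r, c_d],
                            rtol=1e-11, atol=1e-14)
            c_r, c_d = sol.y[:, -1]
            assert rep[k] == pytest.approx(c_r, rel=1e-6)
            # sampling event: withdraw at the true concentration, replace
            withdrawn += c_r * geom.sample_volume
            c_r *= geom.dilution_factor
            total = (c_d * geom.donor_volume
                     + c_r * geom.receiver_volume + withdrawn)
            assert total == pytest.approx(total0, rel=1e-9)

    def test_zero_sample_volume_sampling_is_identity(self):
        geom = CellGeometry(1.77, 1.0, 7.0, 0.0)
        cfg_a = make_config(geometry=geom, n_replicates=1)
        exp = simulate_permeation(cfg_a)
        rep = exp.replicates[0]
        # with no withdrawal the recorded series is the pure two-compartment
        # solution sampled at the schedule times
        c = 0.0
        q = geom.donor_volume * 10_000.0
        expected = []
        for dt_h in exp.schedule.intervals_h:
            c = propagate_interval(c, q, 1e-5, geom, dt_h * 3600.0)
            expected.append(c)
        np.testing.assert_allclose(rep, expected, rtol=1e-12)

    def test_noise_is_multiplicative_and_truncated_at_zero(self):
        exp = simulate_permeation(make_config(noise_cv=0.5, n_replicates=5, seed=11))
        for rep in exp.replicates:
            assert np.all(rep >= 0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            make_config(n_replicates=0)
        with pytest.raises(ValueError):
            make_config(noise_cv=-0.1)
        with pytest.raises(ValueError):
            make_config(donor_concentration_0=0.0)
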