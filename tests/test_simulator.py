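"""Element laws, network topology, tube identities, and passivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesbi.simulator import (
    FixedConstants,
    FrequencyGrid,
    MiddleEarParams,
    branch_impedance,
    characteristic_impedance,
    compute_absorbance,
    middle_ear_input_impedance,
    simulate_batch,
    simulate_spectra,
    tube_transform,
)

CONST = FixedConstants()
GRID = FrequencyGrid()


class TestBranchImpedance:
    def test_null_element_is_zero(self):
        assert branch_impedance(1234.5, 0.0, 0.0, 0.0) == 0

    def test_series_resonance_cancels(self):
        M, K = 3.0e3, 2.0e11
        z = branch_impedance(np.sqrt(K / M), M, K, 0.0)
        assert abs(z) < 1e-6 * K / np.sqrt(K / M)

    def test_hand_evaluated_element(self):
        # independent hand evaluation: Re = K*eta/omega, Im = omega*M - K/omega
        omega = 2 * np.pi * 1000.0
        M, K, eta = 4.5e3, 1.8e11, 0.1
        z = branch_impedance(omega, M, K, eta)
        assert z.real == pytest.approx(K * eta / omega, rel=1e-12)
        assert z.imag == pytest.approx(omega * M - K / omega, rel=1e-12)
        # magnitude scale of the frozen reference values
        assert z.real == pytest.approx(2.864e6, rel=1e-3)
        assert z.imag == pytest.approx(-3.7356e5, rel=1e-3)

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            branch_impedance(0.0, 1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            branch_impedance(np.array([100.0, -5.0]), 1.0, 1.0, 0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        f=st.floats(100, 10000),
        M=st.floats(0, 1e5),
        K=st.floats(0, 1e12),
        eta=st.floats(0, 1),
    )
    def test_real_part_is_dissipative(self, f, M, K, eta):
        z = branch_impedance(2 * np.pi * f, M, K, eta)
        assert z.real >= 0


class TestLadder:
    def test_matches_explicit_series_parallel_hand_computation(self, midpoint_params):
        """Explicit re-derivation of the fixed topology at one frequency."""
        omega = 2 * np.pi * 1500.0
        p, c = midpoint_params, CONST
        jw = 1j * omega

        def elem(M, K, eta):
            return jw * M + K * (1 + 1j * eta) / jw

        def par(a, b):
            return a * b / (a + b)

        eta = p.damping
        z_td = elem(c.m_td, c.g_td * p.e_drum * 1e6, eta)
        z_ml = elem(0, c.g_ml * p.e_mallear * 1e6, eta)
        z_j = elem(c.m_os, c.g_j * p.e_joint * 1e6, eta)
        z_s = elem(0, c.g_s * p.e_soft * 1e6, eta)
        z_sal = elem(0, c.g_sal * p.e_sal * 1e6, eta)
        b2 = z_sal + p.cochlear_load * 1e9 / c.transformer
        b1 = z_j + par(z_s, b2)
        z_expected = z_td + par(z_ml, b1)
        u_expected = (z_ml / (z_ml + b1)) * (z_s / (z_s + b2))

        z, u = middle_ear_input_impedance(p, c, omega)
        assert z == pytest.approx(z_expected, rel=1e-10)
        assert u == pytest.approx(u_expected, rel=1e-10)

    def test_open_cochlea_carries_no_flow(self, midpoint_params):
        theta = midpoint_params.to_array()
        theta[-1] = 1e12  # cochlear load -> infinity
        _, u = middle_ear_input_impedance(
            MiddleEarParams.from_array(theta), CONST, GRID.omega
        )
        assert np.all(np.abs(u) < 1e-6)

    def test_passive_and_bounded_flow_at_midpoints(self, midpoint_params):
        z, u = middle_ear_input_impedance(midpoint_params, CONST, GRID.omega)
        assert np.all(z.real > 0)
        assert np.all(np.abs(u) <= 1)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            MiddleEarParams(0.0, 0.1, 5, 5, 5, 0.1, 10)


class TestTube:
    def test_zero_length_is_identity(self):
        z = 3e7 + 4e6j
        assert tube_transform(z, 0.0, CONST, 2 * np.pi * 1000) == pytest.approx(z)

    def test_matched_line_is_invariant(self):
        z0 = characteristic_impedance(CONST)
        out = tube_transform(z0 + 0j, 0.0042, CONST, GRID.omega)
        assert np.allclose(out, z0, rtol=1e-12)

    def test_quarter_wave_inversion(self):
        f = 2000.0
        length = CONST.c_air / (4 * f)
        z0 = characteristic_impedance(CONST)
        z_load = 5e6 + 1e6j
        out = tube_transform(z_load, length, CONST, 2 * np.pi * f)
        assert out == pytest.approx(z0**2 / z_load, rel=1e-9)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            tube_transform(1e7, -0.001, CONST, 1000.0)


class TestAbsorbanceAndZ0:
    def test_characteristic_impedance_hand_value(self):
        # rho*c / (pi r^2) = 1.205*343/(pi*(3 mm)^2)
        assert characteristic_impedance(CONST) == pytest.approx(
            1.205 * 343.0 / (np.pi * 9e-6), rel=1e-12
        )
        assert characteristic_impedance(CONST) == pytest.approx(1.462e7, rel=1e-3)

    def test_radius_doubling_quarters_z0(self):
        c2 = FixedConstants(canal_radius=6e-3)
        assert characteristic_impedance(c2) == pytest.approx(
            characteristic_impedance(CONST) / 4, rel=1e-12
        )

    def test_unit_case(self):
        c1 = FixedConstants(rho_air=1.0, c_air=1.0, canal_radius=float(np.sqrt(1 / np.pi)))
        assert characteristic_impedance(c1) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "z_ratio,expected",
        [(1.0 + 0j, 1.0), (1j, 0.0), (3.0 + 0j, 0.75)],
    )
    def test_analytic_absorbance_values(self, z_ratio, expected):
        z0 = characteristic_impedance(CONST)
        assert compute_absorbance(z_ratio * z0, z0) == pytest.approx(expected, abs=1e-14)

    def test_active_load_rejected(self):
        with pytest.raises(ValueError):
            compute_absorbance(-1e6 + 1e7j, characteristic_impedance(CONST))

    def test_energy_identity_machine_precision(self, midpoint_params):
        s = simulate_spectra(midpoint_params)
        z0 = characteristic_impedance(CONST)
        gamma = (s.z_ec / z0 - 1) / (s.z_ec / z0 + 1)
        assert np.allclose(s.abs_ec + np.abs(gamma) ** 2, 1.0, rtol=0, atol=1e-14)


class TestSimulateSpectra:
    def test_deterministic_bit_identical(self, midpoint_params):
        a = simulate_spectra(midpoint_params)
        b = simulate_spectra(midpoint_params)
        assert np.array_equal(a.vst_over_pec, b.vst_over_pec)
        assert np.array_equal(a.z_ec, b.z_ec)
        assert np.array_equal(a.abs_ec, b.abs_ec)

    def test_passivity_over_prior_draws(self, prior):
        thetas = prior.sample(1000, seed=0)
        vst, zec, ab = simulate_batch(thetas)
        assert np.all(zec.real > 0)
        assert np.all((ab >= 0) & (ab <= 1))

    def test_closed_form_oracle_at_lowest_frequency(self, midpoint_params):
        """Independent scripted evaluation of ladder + line at one frequency."""
        p, c = midpoint_params, CONST
        omega = GRID.omega[0]
        jw = 1j * omega

        def elem(M, K):
            return jw * M + K * (1 + 1j * p.damping) / jw

        b2 = elem(0, c.g_sal * p.e_sal * 1e6) + p.cochlear_load * 1e9 / c.transformer
        z_s = elem(0, c.g_s * p.e_soft * 1e6)
        b1 = elem(c.m_os, c.g_j * p.e_joint * 1e6) + z_s * b2 / (z_s + b2)
        z_ml = elem(0, c.g_ml * p.e_mallear * 1e6)
        z_drum = elem(c.m_td, c.g_td * p.e_drum * 1e6) + z_ml * b1 / (z_ml + b1)
        z0 = c.rho_air * c.c_air / (np.pi * c.canal_radius**2)
        l2 = c.canal_length_probe_to_drum - c.plane_distance_from_probe
        kl = omega / c.c_air * l2
        z_ec = z0 * (z_drum * np.cos(kl) + 1j * z0 * np.sin(kl)) / (
            z0 * np.cos(kl) + 1j * z_drum * np.sin(kl)
        )
        s = simulate_spectra(p)
        assert abs(s.z_ec[0]) == pytest.approx(abs(z_ec), rel=1e-10)

    def test_stiffer_drum_raises_absorbance_peak_frequency(self, midpoint_params):
        theta = midpoint_params.to_array()
        hi = theta.copy()
        hi[0] *= 10
        f = GRID.values
        f_mid = f[np.argmax(simulate_spectra(midpoint_params).abs_ec)]
        f_hi = f[np.argmax(simulate_spectra(MiddleEarParams.from_array(hi)).abs_ec)]
        assert f_hi > f_mid

    def test_behavioral_calibration_at_prior_midpoints(self, midpoint_params):
        s = simulate_spectra(midpoint_params)
        f_peak = GRID.values[np.argmax(s.abs_ec)]
        assert 500 <= f_peak <= 4000
        assert 0.3 <= s.abs_ec.max() <= 1.0
        assert 5e7 <= abs(s.z_ec[0]) <= 1e10

    def test_batch_matches_single(self, prior):
        thetas = prior.sample(3, seed=42)
        vst, zec, ab = simulate_batch(thetas)
        for i in range(3):
            s = simulate_spectra(MiddleEarParams.from_array(thetas[i]))
            assert np.allclose(vst[i], s.vst_over_pec, rtol=1e-14)
            assert np.allclose(zec[i], s.z_ec, rtol=1e-14)
            assert np.allclose(ab[i], s.abs_ec, rtol=1e-14)

    def test_grid_is_logarithmic(self):
        v = GRID.values
        assert len(v) == 50 and v[0] == 250 and v[-1] == 8000
        ratios = v[1:] / v[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)
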