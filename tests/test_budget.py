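"""Discrete control-volume estimators against closed-form and analytic oracles."""

import math

import numpy as np
import pytest

import cvmr
from cvmr.budget import Waveform, periodic_derivative
from cvmr.core import (
    ConfigurationError,
    DegenerateMaskError,
    InsufficientDataError,
)
from conftest import fine_poiseuille_series

WATER = cvmr.WATER
GEOM = cvmr.PHANTOM_GEOMETRY


def uniform_series(v=1.0, n=10, n_phases=4):
    """32 in-lumen pixels carrying a uniform velocity on a 0.2 cm grid."""
    acq = cvmr.AcquisitionGeometry(
        field_of_view=0.2 * n, matrix_size=n, slice_thickness=1.0,
        n_phases=n_phases, cycle_period=1.0, venc=20.0,
    )
    mask = cvmr.lumen_mask(0.635, acq, cvmr.CORNER)
    assert mask.sum() == 32
    vel = np.where(mask, v, 0.0)
    vel = np.broadcast_to(vel, (n_phases, n, n)).copy()
    series = cvmr.VelocitySeries(
        velocity=vel,
        magnitude=np.where(np.broadcast_to(mask, vel.shape), 1.0, 0.2).copy(),
        acquisition=acq,
        timestamps=np.arange(n_phases) / n_phases,
    )
    return series, cvmr.RoiMask(mask, acq.pixel_spacing)


class TestFlowRate:
    def test_uniform_velocity(self):
        """1 cm/s over 32 pixels of 0.04 cm^2 integrates to 1.28 cm^3/s."""
        series, mask = uniform_series(v=1.0)
        q = cvmr.flow_rate(series, mask)
        assert np.allclose(q.values, 1.28)
        assert q.units == "cm^3/s"

    def test_phantom_amplitude_deficit_under_six_percent(
        self, centered_series, centered_mask
    ):
        """Pixel-centre sampling at 0.2 cm underestimates the 46 mL/min amplitude
        by a few percent (the spatial-resolution error of the method)."""
        q = cvmr.flow_rate(centered_series, centered_mask)
        deficit = 1.0 - q.amplitude / (46.0 / 60.0)
        assert 0.0 < deficit < 0.06

    def test_grid_refinement_converges(self, phantom_flow):
        """On a 0.02 cm grid the amplitude is within 0.5% of analytic."""
        acq = cvmr.AcquisitionGeometry(
            field_of_view=3.2, matrix_size=160, slice_thickness=1.0,
            n_phases=17, cycle_period=1.0, venc=20.0,
        )
        series = cvmr.render_series(phantom_flow, acq)
        mask = cvmr.RoiMask(
            cvmr.lumen_mask(0.635, acq, cvmr.CENTERED), acq.pixel_spacing
        )
        q = cvmr.flow_rate(series, mask)
        assert q.amplitude == pytest.approx(46.0 / 60.0, rel=0.005)

    def test_mask_shape_must_match(self, centered_series):
        small = np.zeros((4, 4), dtype=bool)
        small[1:3, 1:3] = True
        with pytest.raises(ConfigurationError):
            cvmr.flow_rate(centered_series, cvmr.RoiMask(small, 0.2))


class TestMassBalance:
    def test_single_inflow_identity(self):
        q = Waveform(np.sin(2 * np.pi * np.arange(8) / 8), 1.0, "cm^3/s")
        dvdt = cvmr.mass_balance_volume_rate([q])
        assert np.array_equal(dvdt.values, q.values)

    def test_constant_production_only(self):
        """CSF-scale production of 0.36 mL/min appears as a constant dV/dt."""
        zero = Waveform(np.zeros(8), 1.0, "cm^3/s")
        dvdt = cvmr.mass_balance_volume_rate([zero], net_production=0.36 / 60.0)
        assert np.allclose(dvdt.values * 60.0, 0.36)

    def test_balanced_in_out_cancel(self):
        q = Waveform(np.sin(2 * np.pi * np.arange(8) / 8), 1.0, "cm^3/s")
        neg = Waveform(-q.values, 1.0, "cm^3/s")
        assert np.allclose(cvmr.mass_balance_volume_rate([q, neg]).values, 0.0)

    def test_mismatched_sampling_rejected(self):
        a = Waveform(np.zeros(8), 1.0, "cm^3/s")
        b = Waveform(np.zeros(9), 1.0, "cm^3/s")
        with pytest.raises(ConfigurationError):
            cvmr.mass_balance_volume_rate([a, b])


class TestMomentumInflow:
    def test_uniform_velocity(self):
        series, mask = uniform_series(v=1.0)
        f = cvmr.momentum_inflow(series, mask, WATER)
        assert np.allclose(f.values, 1.28)

    def test_zero_velocity(self):
        series, mask = uniform_series(v=0.0)
        assert np.allclose(cvmr.momentum_inflow(series, mask, WATER).values, 0.0)

    def test_poiseuille_momentum_coefficient(self):
        """Fine-grid parabolic profile: flux -> (4/3) rho vbar^2 S within 1%."""
        series, mask = fine_poiseuille_series()
        f = cvmr.momentum_inflow(series, mask, WATER)
        vbar = 0.768 / (math.pi * 0.635**2)
        expected = (4.0 / 3.0) * WATER.density * vbar**2 * math.pi * 0.635**2
        assert f.values[0] == pytest.approx(expected, rel=0.01)


class TestInertialForce:
    def test_constant_flow_gives_zero(self):
        q = Waveform(np.full(8, 3.0), 1.0, "cm^3/s")
        assert np.allclose(cvmr.inertial_force(q, WATER, GEOM).values, 0.0)

    def test_spectral_is_exact_on_single_harmonic(self):
        """17-sample sine: spectral amplitude = rho L omega Q0 to 1e-6."""
        q0, n = 0.768, 17
        q = Waveform(q0 * np.sin(2 * np.pi * np.arange(n) / n), 1.0, "cm^3/s")
        f = cvmr.inertial_force(q, WATER, GEOM, scheme="spectral")
        expected = WATER.density * GEOM.axial_length * 2 * np.pi * q0
        amp = math.hypot(*_first_harmonic(f.values))
        assert amp == pytest.approx(expected, rel=1e-6)

    def test_central_attenuation_matches_transfer_function(self):
        """Central difference underestimates by sin(omega dt)/(omega dt)."""
        q0, n = 0.768, 17
        q = Waveform(q0 * np.sin(2 * np.pi * np.arange(n) / n), 1.0, "cm^3/s")
        central = cvmr.inertial_force(q, WATER, GEOM, scheme="central")
        spectral = cvmr.inertial_force(q, WATER, GEOM, scheme="spectral")
        omega_dt = 2 * np.pi / n
        factor = math.sin(omega_dt) / omega_dt
        assert central.amplitude / spectral.amplitude == pytest.approx(
            factor, rel=1e-9
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            periodic_derivative(Waveform(np.zeros(2), 1.0, "x"))


def _first_harmonic(values):
    n = len(values)
    t = np.arange(n) / n
    a = 2.0 * np.mean(values * np.sin(2 * np.pi * t))
    b = 2.0 * np.mean(values * np.cos(2 * np.pi * t))
    return a, b


class TestViscousForce:
    def test_zero_field(self):
        series, mask = uniform_series(v=0.0)
        assert np.allclose(cvmr.viscous_force(series, mask, WATER, GEOM).values, 0.0)

    def test_drag_opposes_positive_flow(self, centered_series, centered_mask):
        k = 4  # frame near peak positive flow
        f = cvmr.viscous_force(centered_series, centered_mask, WATER, GEOM)
        assert f.values[k] < 0.0

    def test_fine_grid_poiseuille_drag(self):
        """0.0125 cm grid: |F_V| -> 8 mu L Q / R^2 within 10%."""
        series, mask = fine_poiseuille_series()
        f = cvmr.viscous_force(series, mask, WATER, GEOM)
        expected = 8.0 * WATER.dynamic_viscosity * GEOM.axial_length * 0.768 / 0.635**2
        assert abs(f.values[0]) == pytest.approx(expected, rel=0.10)
        assert f.values[0] < 0.0

    def test_thin_mask_rejected(self):
        series, _ = uniform_series()
        line = np.zeros((10, 10), dtype=bool)
        line[5, 2:8] = True  # one pixel wide: no interior neighbour across the flats
        with pytest.raises(DegenerateMaskError):
            cvmr.viscous_force(series, cvmr.RoiMask(line, 0.2), WATER, GEOM)


class TestBodyForce:
    def test_horizontal_static_phantom_is_zero(self):
        assert cvmr.body_force(WATER, GEOM.volume) == 0.0

    def test_gravity_example(self):
        assert cvmr.body_force(
            cvmr.FluidProperties(1.0, 0.01), 1.0, axial_gravity=981.0
        ) == pytest.approx(981.0)

    def test_linear_in_each_argument(self):
        f = cvmr.body_force(WATER, 2.0, 10.0, 4.0)
        assert f == pytest.approx(2.0 * cvmr.body_force(WATER, 1.0, 10.0, 4.0))
        assert cvmr.body_force(WATER, 2.0, 20.0, 8.0) == pytest.approx(2.0 * f)


class TestPressureForceCv:
    def test_simplified_is_inertial_identity(self):
        f_i = Waveform(np.sin(2 * np.pi * np.arange(8) / 8), 1.0, "dyne")
        f_p = cvmr.pressure_force_cv(f_i, mode="simplified")
        assert np.array_equal(f_p.values, f_i.values)

    def test_full_with_null_terms_equals_simplified(self):
        f_i = Waveform(np.sin(2 * np.pi * np.arange(8) / 8), 1.0, "dyne")
        zero = Waveform(np.zeros(8), 1.0, "dyne")
        f_p = cvmr.pressure_force_cv(
            f_i, mode="full", momentum_in=zero, momentum_out=zero,
            viscous=zero, body=0.0,
        )
        assert np.allclose(f_p.values, f_i.values)

    def test_full_mode_requires_both_surfaces(self):
        f_i = Waveform(np.zeros(8), 1.0, "dyne")
        with pytest.raises(ConfigurationError):
            cvmr.pressure_force_cv(f_i, mode="full")

    def test_viscous_drag_raises_required_pressure(self):
        f_i = Waveform(np.ones(8), 1.0, "dyne")
        zero = Waveform(np.zeros(8), 1.0, "dyne")
        drag = Waveform(np.full(8, -0.25), 1.0, "dyne")
        f_p = cvmr.pressure_force_cv(
            f_i, mode="full", momentum_in=zero, momentum_out=zero, viscous=drag
        )
        assert np.allclose(f_p.values, 1.25)


class TestUrchukPlewes:
    def test_zero_field(self):
        series, mask = uniform_series(v=0.0)
        up = cvmr.urchuk_plewes(series, mask, WATER, GEOM)
        assert np.allclose(up.gradient.values, 0.0)
        assert np.allclose(up.force.values, 0.0)

    def test_steady_poiseuille_gradient(self):
        """Fine-grid steady parabola: -dp/dz -> 8 mu Q / (pi R^4) within 5%."""
        series, mask = fine_poiseuille_series()
        up = cvmr.urchuk_plewes(series, mask, WATER, GEOM)
        expected = 8.0 * WATER.dynamic_viscosity * 0.768 / (math.pi * 0.635**4) * 0.1
        assert up.gradient.values[0] == pytest.approx(expected, rel=0.05)
        assert np.allclose(up.inertial_part.values, 0.0, atol=1e-12)

    def test_tracks_analytic_pressure_force(
        self, centered_series, centered_mask, analytic_pressure_force
    ):
        """The ROI-averaged -dp/dz estimate reproduces the uniform analytic
        gradient closely even at 0.2 cm resolution."""
        up = cvmr.urchuk_plewes(centered_series, centered_mask, WATER, GEOM)
        assert up.force.amplitude == pytest.approx(
            analytic_pressure_force.amplitude, rel=0.03
        )

    def test_inertial_part_vs_cv_inertial(self, centered_series, centered_mask):
        """The two inertial estimates agree to within the flat-core/bulk-mean
        distinction (~14% at alpha = 16); they measure the same physics but
        average it differently (core pixels vs pixel-summed flow)."""
        up = cvmr.urchuk_plewes(centered_series, centered_mask, WATER, GEOM)
        q = cvmr.flow_rate(centered_series, centered_mask)
        f_i = cvmr.inertial_force(q, WATER, GEOM)
        rms = np.sqrt(np.mean((up.inertial_force.values - f_i.values) ** 2))
        assert rms / f_i.amplitude < 0.16

    def test_degenerate_roi_rejected(self):
        series, _ = uniform_series()
        blob = np.zeros((10, 10), dtype=bool)
        blob[4:6, 4:6] = True  # 2x2: no pixel has 4 in-ROI neighbours
        with pytest.raises(DegenerateMaskError):
            cvmr.urchuk_plewes(series, cvmr.RoiMask(blob, 0.2), WATER, GEOM)


class TestUncertainty:
    def test_sigma_q_propagation(self, corner_mask):
        """sigma_v 0.36, N = 32, S_pix 0.04: sigma_q = 0.0815 cm^3/s."""
        report = cvmr.propagate_uncertainty(
            cvmr.PHANTOM_ACQUISITION, 25.0, corner_mask, WATER, GEOM
        )
        oracle = cvmr.velocity_noise_sigma(20.0, 25.0) * 0.04 * math.sqrt(32)
        assert report.sigma_q == pytest.approx(oracle, rel=1e-12)
        assert report.sigma_q == pytest.approx(0.0815, abs=5e-4)

    def test_noiseless_limit_vanishes(self, corner_mask):
        report = cvmr.propagate_uncertainty(
            cvmr.PHANTOM_ACQUISITION, 1e12, corner_mask, WATER, GEOM
        )
        assert report.sigma_v < 1e-10
        assert report.sigma_q < 1e-10
        assert report.sigma_inertial < 1e-8

    def test_sigma_q_scales_as_sqrt_n(self):
        """Across masks of different size, sigma_q / sqrt(N) is constant."""
        ratios = []
        for n_side in (2, 4, 6):
            mask = np.zeros((20, 20), dtype=bool)
            mask[2 : 2 + n_side, 2 : 2 + n_side] = True
            roi = cvmr.RoiMask(mask, 0.2)
            rep = cvmr.propagate_uncertainty(
                cvmr.PHANTOM_ACQUISITION, 25.0, roi, WATER, GEOM
            )
            ratios.append(rep.sigma_q / math.sqrt(roi.pixel_count))
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_central_difference_noise_gain_formula(self):
        """Central-difference noise gain is 1/(sqrt(2) dt)."""
        from cvmr.budget import derivative_noise_gain

        dt = 1.0 / 17
        assert derivative_noise_gain(17, dt, "central") == pytest.approx(
            1.0 / (math.sqrt(2) * dt), rel=1e-12
        )


class TestComputeBudget:
    def test_waveforms_share_sampling(self, centered_series, centered_mask):
        b = cvmr.compute_budget(centered_series, centered_mask, WATER, GEOM, snr=25.0)
        for w in (b.flow, b.inertial_force, b.momentum_inflow,
                  b.viscous_force, b.pressure_force_cv, b.up.force):
            assert w.n_samples == 17
            assert w.period == 1.0
        assert b.body_force == 0.0
        assert b.uncertainty is not None

    def test_simplified_pressure_equals_inertial(self, centered_series, centered_mask):
        b = cvmr.compute_budget(centered_series, centered_mask, WATER, GEOM)
        assert np.array_equal(b.pressure_force_cv.values, b.inertial_force.values)

    def test_pressure_gradient_units_bridge(self, centered_series, centered_mask):
        b = cvmr.compute_budget(centered_series, centered_mask, WATER, GEOM)
        g = b.pressure_gradient_cv
        assert g.units == "Pa/cm"
        assert g.values[4] == pytest.approx(
            b.pressure_force_cv.values[4] / GEOM.volume * 0.1, rel=1e-12
        )
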