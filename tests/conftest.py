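"""Shared fixtures: the synthetic phantom at its experimental operating point.

Water in a 1.27 cm passage, 46 mL/min sinusoidal flow at 1 Hz (Re ~ 77,
alpha ~ 15.9), imaged at 0.2 cm pixels with 17 gated phases and venc
20 cm/s -- the conditions every estimator is validated under.
"""

import math

import numpy as np
import pytest

import cvmr


@pytest.fixture(scope="session")
def phantom_flow():
    """46 mL/min sinusoidal Womersley flow in the phantom passage (alpha ~ 15.9)."""
    return cvmr.from_flow_amplitude(
        46.0 / 60.0, cvmr.PHANTOM_GEOMETRY.radius, 2.0 * math.pi, cvmr.WATER
    )


@pytest.fixture(scope="session")
def centered_series(phantom_flow):
    """Noise-free gated series, lumen centre on a pixel centre (37-pixel ROI)."""
    return cvmr.render_series(phantom_flow, cvmr.PHANTOM_ACQUISITION, cvmr.CENTERED)


@pytest.fixture(scope="session")
def corner_series(phantom_flow):
    """Noise-free gated series, lumen centre on a pixel corner (32-pixel ROI)."""
    return cvmr.render_series(phantom_flow, cvmr.PHANTOM_ACQUISITION, cvmr.CORNER)


@pytest.fixture(scope="session")
def centered_mask(centered_series):
    return cvmr.segment_series(centered_series)


@pytest.fixture(scope="session")
def corner_mask(corner_series):
    return cvmr.segment_series(corner_series)


@pytest.fixture(scope="session")
def analytic_pressure_force(phantom_flow, centered_series):
    """Exact pressure-force waveform of the phantom CV at the gated times."""
    return cvmr.Waveform(
        phantom_flow.pressure_force_waveform(
            cvmr.PHANTOM_GEOMETRY, centered_series.timestamps
        ),
        cvmr.PHANTOM_ACQUISITION.cycle_period,
        "dyne",
    )


@pytest.fixture(scope="session")
def analytic_flow_waveform(phantom_flow, centered_series):
    return cvmr.Waveform(
        phantom_flow.flow_waveform(centered_series.timestamps),
        cvmr.PHANTOM_ACQUISITION.cycle_period,
        "cm^3/s",
    )


def fine_poiseuille_series(q=0.768, radius=0.635, n_phases=4, matrix=256, fov=3.2):
    """Steady parabolic (Poiseuille) profile rendered on a fine grid.

    Returns (series, mask).  Used as a closed-form oracle for viscous drag,
    momentum flux and pressure-gradient estimators.
    """
    acq = cvmr.AcquisitionGeometry(
        field_of_view=fov,
        matrix_size=matrix,
        slice_thickness=1.0,
        n_phases=n_phases,
        cycle_period=1.0,
        venc=20.0,
    )
    d = acq.pixel_spacing
    idx = np.arange(matrix) - matrix // 2
    x, y = np.meshgrid(idx * d, idx * d)
    r = np.hypot(x, y)
    inside = r < radius
    v_mean = q / (math.pi * radius**2)
    profile = np.where(inside, 2.0 * v_mean * (1.0 - (r / radius) ** 2), 0.0)
    velocity = np.broadcast_to(profile, (n_phases, matrix, matrix)).copy()
    magnitude = np.broadcast_to(
        np.where(inside, 1.0, 0.2), velocity.shape
    ).copy()
    series = cvmr.VelocitySeries(
        velocity=velocity,
        magnitude=magnitude,
        acquisition=acq,
        timestamps=np.arange(n_phases) * acq.cycle_period / n_phases,
    )
    return series, cvmr.RoiMask(inside, d)
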