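"""Exact oscillatory laminar pipe flow (Womersley solution).

Fully developed flow of a Newtonian fluid in a rigid circular pipe driven by
a single-harmonic axial pressure gradient

    dp/dz(t) = Re[ K e^{i omega t} ],     K complex, dyne/cm^3,

has the axial velocity field

    w(r, t) = Re[ (i K / (rho omega))
                  (1 - J0(Lambda r/R) / J0(Lambda)) e^{i omega t} ],

with ``Lambda = i^{3/2} alpha``, ``alpha = R sqrt(omega/nu)`` the Womersley
number and J0, J1 Bessel functions of the first kind.  The branch of
``i^{3/2}`` is fixed to ``e^{i 3 pi / 4}`` so that Bessel-argument
conventions are reproducible.  Integrating over the cross-section gives the
complex flow amplitude

    Q_hat = (i K pi R^2 / (rho omega)) (1 - 2 J1(Lambda) / (Lambda J0(Lambda))).

This solution is the ground truth for the synthetic PC-MR generator and the
oracle every discrete estimator in :mod:`cvmr.budget` is checked against.
Limits: alpha -> 0 recovers quasi-steady Poiseuille flow; alpha -> infinity
gives a flat inertial core where the pressure force amplitude approaches
``rho L omega Q0`` and leads the flow by 90 degrees.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .core import (
    ConduitGeometry,
    ConfigurationError,
    FluidProperties,
    InvalidParameterError,
    NumericRangeError,
)

#: Branch of i^{3/2} used throughout: exp(i 3 pi / 4).
I_THREE_HALVES = cmath.exp(1j * 3.0 * math.pi / 4.0)


@dataclass(frozen=True)
class OscillatoryPipeFlow:
    """One harmonic of pressure-driven oscillatory flow in a rigid pipe.

    ``gradient_amplitude`` is the complex K above; K = 0 is the quiescent
    fluid.  All quantities CGS.
    """

    radius: float  # cm
    angular_frequency: float  # rad/s
    fluid: FluidProperties
    gradient_amplitude: complex  # K, dyne/cm^3

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if not (self.angular_frequency > 0):
            raise InvalidParameterError("angular_frequency must be > 0")

    # -- derived ------------------------------------------------------------

    @property
    def womersley_alpha(self) -> float:
        """alpha = R sqrt(omega / nu)."""
        return self.radius * math.sqrt(
            self.angular_frequency / self.fluid.kinematic_viscosity
        )

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.angular_frequency

    @property
    def _lambda(self) -> complex:
        return I_THREE_HALVES * self.womersley_alpha

    @property
    def flow_amplitude(self) -> complex:
        """Complex amplitude Q_hat with Q(t) = Re[Q_hat e^{i omega t}], cm^3/s."""
        shape = _shape_factor(self._lambda)
        rho, omega = self.fluid.density, self.angular_frequency
        return (
            1j
            * self.gradient_amplitude
            * math.pi
            * self.radius**2
            * shape
            / (rho * omega)
        )

    # -- fields -------------------------------------------------------------

    def velocity(self, r, t):
        """Axial velocity w(r, t) in cm/s; axisymmetric, no-slip at r = R.

        ``r`` may be scalar or array (cm, 0 <= r <= R); ``t`` scalar or array
        (s).  If both are arrays they broadcast against each other.
        """
        r = np.asarray(r, dtype=float)
        if np.any(np.abs(r) > self.radius * (1.0 + 1e-12)):
            raise InvalidParameterError("r must satisfy |r| <= radius")
        if self.gradient_amplitude == 0:
            return np.zeros(np.broadcast(r, np.asarray(t, dtype=float)).shape)
        lam = self._lambda
        j0_wall = jv(0, lam)
        profile = (1j * self.gradient_amplitude / (self.fluid.density * self.angular_frequency)) * (
            1.0 - jv(0, lam * np.abs(r) / self.radius) / j0_wall
        )
        if not np.all(np.isfinite(profile)):
            raise NumericRangeError(
                f"Bessel evaluation overflowed at alpha = {self.womersley_alpha:.3g}"
            )
        phasor = np.exp(1j * self.angular_frequency * np.asarray(t, dtype=float))
        return np.real(profile * phasor)

    def flow_waveform(self, times) -> np.ndarray:
        """Volume flow rate Q(t) in cm^3/s at the given times (s)."""
        phasor = np.exp(1j * self.angular_frequency * np.asarray(times, dtype=float))
        return np.real(self.flow_amplitude * phasor)

    def pressure_gradient_waveform(self, times) -> np.ndarray:
        """Axial pressure gradient dp/dz(t) in dyne/cm^3 at the given times."""
        phasor = np.exp(1j * self.angular_frequency * np.asarray(times, dtype=float))
        return np.real(self.gradient_amplitude * phasor)

    def pressure_force_waveform(self, geometry: ConduitGeometry, times) -> np.ndarray:
        """Axial pressure force on a conduit CV of cross-section S, length L.

        F_p(t) = -dp/dz(t) * S * L in dyne; positive force accelerates fluid
        in the +axial direction.  The CV cross-section must match the pipe.
        """
        if abs(geometry.radius - self.radius) > 1e-9 * self.radius:
            raise ConfigurationError(
                f"conduit radius {geometry.radius} cm does not match flow radius "
                f"{self.radius} cm"
            )
        return -self.pressure_gradient_waveform(times) * geometry.volume

    def to_dict(self) -> dict:
        """Serializable provenance record of the driving parameters."""
        return {
            "radius_cm": self.radius,
            "angular_frequency_rad_s": self.angular_frequency,
            "density_g_cm3": self.fluid.density,
            "dynamic_viscosity_poise": self.fluid.dynamic_viscosity,
            "gradient_amplitude_dyne_cm3": [
                self.gradient_amplitude.real,
                self.gradient_amplitude.imag,
            ],
            "womersley_alpha": self.womersley_alpha,
        }


def _shape_factor(lam: complex) -> complex:
    """1 - 2 J1(lam) / (lam J0(lam)); the Poiseuille limit is lam -> 0."""
    j0 = jv(0, lam)
    j1 = jv(1, lam)
    if not (np.isfinite(j0.real) and np.isfinite(j0.imag) and j0 != 0):
        raise NumericRangeError(
            f"Bessel evaluation overflowed or vanished at |lambda| = {abs(lam):.3g}"
        )
    return 1.0 - 2.0 * j1 / (lam * j0)


def from_flow_amplitude(
    q0: float,
    radius: float,
    angular_frequency: float,
    fluid: FluidProperties,
) -> OscillatoryPipeFlow:
    """Construct the solution whose flow waveform is Q(t) = q0 sin(omega t).

    The gradient phase is chosen so the flow is a pure sine starting at zero:
    Q_hat = -i q0, hence K = -i q0 rho omega / (i pi R^2 shape).

    Parameters
    ----------
    q0 : float
        Flow amplitude in cm^3/s, >= 0.
    """
    if q0 < 0:
        raise InvalidParameterError(f"q0 must be >= 0, got {q0}")
    if q0 == 0:
        return OscillatoryPipeFlow(radius, angular_frequency, fluid, 0j)
    alpha = radius * math.sqrt(angular_frequency / fluid.kinematic_viscosity)
    shape = _shape_factor(I_THREE_HALVES * alpha)
    k = (-1j * q0) * (fluid.density * angular_frequency) / (
        1j * math.pi * radius**2 * shape
    )
    return OscillatoryPipeFlow(radius, angular_frequency, fluid, k)


def poiseuille_gradient_amplitude(
    q0: float, radius: float, fluid: FluidProperties
) -> float:
    """Quasi-steady pressure-gradient magnitude 8 mu Q / (pi R^4), dyne/cm^3.

    The alpha -> 0 limit of |K|; used as an independent low-frequency oracle.
    """
    return 8.0 * fluid.dynamic_viscosity * q0 / (math.pi * radius**4)
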