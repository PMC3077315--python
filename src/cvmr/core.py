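"""Physical quantities, control-volume geometry and dimensionless numbers.

All internal computation is carried out in CGS units (cm, g, s, dyne, poise),
the natural system for the centimetre-scale, dyne-scale forces this method
resolves.  SI values are accepted at the configuration boundary and converted
once; pascal appears only in reported pressure gradients and sensor traces.

Unit bridges
------------
``DYNE_PER_CM3_TO_PA_PER_CM``   pressure gradient, dyne/cm^3 -> Pa/cm (x 0.1)
``PA_TO_DYNE_PER_CM2``          pressure, Pa -> dyne/cm^2 (x 10)
``CM3_PER_S_TO_ML_PER_MIN``     volume flow, cm^3/s -> mL/min (x 60)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------


class CvmrError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(CvmrError, ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigurationError(CvmrError, ValueError):
    """Inconsistent objects were combined (shape, sampling or geometry mismatch)."""


class SchemaError(CvmrError, ValueError):
    """A file is missing required keys or columns; the message names them."""


class EmptyRoiError(CvmrError, ValueError):
    """An operation that integrates over a region of interest received an empty one."""


class DegenerateMaskError(CvmrError, ValueError):
    """A mask is too thin to support the finite-difference stencil it was given to."""


class InsufficientDataError(CvmrError, ValueError):
    """A trace or waveform is too short for the requested operation."""


class NumericRangeError(CvmrError, ArithmeticError):
    """A special-function evaluation left the representable floating-point range."""


class ZeroRangeError(CvmrError, ZeroDivisionError):
    """Range normalization was requested against a constant reference waveform."""


# ---------------------------------------------------------------------------
# Unit bridges (bit-exact constants; applied only at reporting boundaries)
# ---------------------------------------------------------------------------

DYNE_PER_CM3_TO_PA_PER_CM = 0.1
PA_TO_DYNE_PER_CM2 = 10.0
DYNE_PER_CM2_TO_PA = 0.1
CM3_PER_S_TO_ML_PER_MIN = 60.0
ML_PER_MIN_TO_CM3_PER_S = 1.0 / 60.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants in CGS units.

    Parameters
    ----------
    density : float
        Mass density ``rho`` in g/cm^3.
    dynamic_viscosity : float
        Dynamic viscosity ``mu`` in poise (g cm^-1 s^-1).
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise InvalidParameterError(f"density must be > 0, got {self.density}")
        if not (self.dynamic_viscosity > 0):
            raise InvalidParameterError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity ``nu = mu / rho`` in cm^2/s."""
        return self.dynamic_viscosity / self.density


#: Water near room temperature, the phantom's working fluid standing in for CSF.
WATER = FluidProperties(density=1.0, dynamic_viscosity=0.01)


@dataclass(frozen=True)
class ConduitGeometry:
    """Cylindrical-passage control volume between two pressure taps.

    ``axial_sign_convention`` fixes the positive axial direction: +1 means
    flow *into* the phantom is positive.
    """

    diameter: float  # cm
    axial_length: float  # cm
    cross_section_area: float = field(default=None)  # cm^2; default pi D^2 / 4
    axial_sign_convention: int = 1

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise InvalidParameterError(f"diameter must be > 0, got {self.diameter}")
        if not (self.axial_length > 0):
            raise InvalidParameterError(
                f"axial_length must be > 0, got {self.axial_length}"
            )
        if self.cross_section_area is None:
            object.__setattr__(
                self, "cross_section_area", math.pi * self.diameter**2 / 4.0
            )
        if not (self.cross_section_area > 0):
            raise InvalidParameterError(
                f"cross_section_area must be > 0, got {self.cross_section_area}"
            )
        if self.axial_sign_convention not in (-1, 1):
            raise InvalidParameterError("axial_sign_convention must be +1 or -1")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        """Control-volume fluid volume S*L in cm^3."""
        return self.cross_section_area * self.axial_length


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Through-plane PC-MR acquisition parameters.

    A retrospectively gated sequence produces ``n_phases`` frames uniformly
    spanning one ``cycle_period``; velocities are encoded within +/- ``venc``.
    """

    field_of_view: float  # cm
    matrix_size: int
    slice_thickness: float  # cm
    n_phases: int
    cycle_period: float  # s
    venc: float  # cm/s

    def __post_init__(self) -> None:
        if not (self.field_of_view > 0):
            raise InvalidParameterError("field_of_view must be > 0")
        if self.matrix_size < 1:
            raise InvalidParameterError(
                f"matrix_size must be >= 1, got {self.matrix_size}"
            )
        if self.slice_thickness <= 0:
            raise InvalidParameterError("slice_thickness must be > 0")
        if self.n_phases < 3:
            raise InvalidParameterError(f"n_phases must be >= 3, got {self.n_phases}")
        if not (self.cycle_period > 0):
            raise InvalidParameterError("cycle_period must be > 0")
        if not (self.venc > 0):
            raise InvalidParameterError(f"venc must be > 0, got {self.venc}")

    @property
    def pixel_spacing(self) -> float:
        """Pixel edge length field_of_view / matrix_size in cm."""
        return self.field_of_view / self.matrix_size

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel in cm^2."""
        return self.pixel_spacing**2


#: The phantom acquisition: 25.6 cm FOV on a 128x128 matrix (0.2 cm pixels),
#: 1 cm slice, 17 phases over a 1 s cycle, venc 20 cm/s.
PHANTOM_ACQUISITION = AcquisitionGeometry(
    field_of_view=25.6,
    matrix_size=128,
    slice_thickness=1.0,
    n_phases=17,
    cycle_period=1.0,
    venc=20.0,
)

#: The phantom's cylindrical passage: 1.27 cm bore, 3.81 cm between taps.
PHANTOM_GEOMETRY = ConduitGeometry(diameter=1.27, axial_length=3.81)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def reynolds_from_peak_flow(
    q_max: float, geometry: ConduitGeometry, fluid: FluidProperties
) -> float:
    """Reynolds number defined from the peak volume flow rate.

    Re = (Q_max / S) * D / nu, using the flow-rate-based mean velocity
    Q_max/S at the instant of peak flow.

    Parameters
    ----------
    q_max : float
        Peak volume flow rate in cm^3/s; must be >= 0.
    """
    if q_max < 0:
        raise InvalidParameterError(f"q_max must be >= 0, got {q_max}")
    u_mean = q_max / geometry.cross_section_area
    return u_mean * geometry.diameter / fluid.kinematic_viscosity


def womersley_number(
    geometry: ConduitGeometry, frequency: float, fluid: FluidProperties
) -> float:
    """Womersley number alpha = (D/2) sqrt(omega / nu), omega = 2 pi f.

    The ratio of transient inertial to viscous forces in oscillatory flow;
    above alpha ~ 2.5 the velocity profile flattens and inertia dominates.
    """
    if not (frequency > 0):
        raise InvalidParameterError(f"frequency must be > 0, got {frequency}")
    omega = 2.0 * math.pi * frequency
    return geometry.radius * math.sqrt(omega / fluid.kinematic_viscosity)


def pixel_spacing(field_of_view: float, matrix_size: int) -> float:
    """Pixel edge length in cm for a square acquisition matrix."""
    if matrix_size < 1:
        raise InvalidParameterError(f"matrix_size must be >= 1, got {matrix_size}")
    if not (field_of_view > 0):
        raise InvalidParameterError("field_of_view must be > 0")
    return field_of_view / matrix_size


def force_to_gradient(force: float, geometry: ConduitGeometry) -> float:
    """Convert an axial force on the CV (dyne) to a pressure gradient (Pa/cm).

    dp/dz = F / (S * L), converted dyne/cm^3 -> Pa/cm.
    """
    return force / geometry.volume * DYNE_PER_CM3_TO_PA_PER_CM


def flow_amplitude_from_reynolds(
    reynolds: float, geometry: ConduitGeometry, fluid: FluidProperties
) -> float:
    """Peak volume flow rate (cm^3/s) implied by a Reynolds number.

    Inverse of :func:`reynolds_from_peak_flow`: Q_max = Re * nu * S / D.
    """
    if reynolds < 0:
        raise InvalidParameterError(f"reynolds must be >= 0, got {reynolds}")
    return (
        reynolds
        * fluid.kinematic_viscosity
        * geometry.cross_section_area
        / geometry.diameter
    )


def velocity_noise_sigma(venc: float, snr: float) -> float:
    """Velocity noise standard deviation of a two-point PC-MR measurement.

    sigma_v = sqrt(2) * venc / (pi * SNR), the standard high-SNR phase
    difference result; with venc 20 cm/s at SNR 25 this is 0.36 cm/s.
    """
    if not (venc > 0):
        raise InvalidParameterError(f"venc must be > 0, got {venc}")
    if not (snr > 0):
        raise InvalidParameterError(f"snr must be > 0, got {snr}")
    return math.sqrt(2.0) * venc / (math.pi * snr)


# ---------------------------------------------------------------------------
# Config boundary
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Read a YAML config into validated domain objects.

    The file carries CGS values under three sections::

        fluid:        {density, dynamic_viscosity}
        geometry:     {diameter, axial_length}
        acquisition:  {fov, matrix, venc, n_phases, period, slice_thickness}

    Returns a dict with keys ``fluid`` (:class:`FluidProperties`),
    ``geometry`` (:class:`ConduitGeometry`), ``acquisition``
    (:class:`AcquisitionGeometry`) and ``simulation`` (the raw optional
    section with generator settings, possibly empty).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for section, keys in (
        ("fluid", ("density", "dynamic_viscosity")),
        ("geometry", ("diameter", "axial_length")),
        ("acquisition", ("fov", "matrix", "venc", "n_phases", "period", "slice_thickness")),
    ):
        if section not in raw:
            raise SchemaError(f"config is missing required section '{section}'")
        missing = [k for k in keys if k not in raw[section]]
        if missing:
            raise SchemaError(
                f"config section '{section}' is missing keys: {', '.join(missing)}"
            )
    fluid = FluidProperties(
        density=float(raw["fluid"]["density"]),
        dynamic_viscosity=float(raw["fluid"]["dynamic_viscosity"]),
    )
    geometry = ConduitGeometry(
        diameter=float(raw["geometry"]["diameter"]),
        axial_length=float(raw["geometry"]["axial_length"]),
    )
    acq = raw["acquisition"]
    acquisition = AcquisitionGeometry(
        field_of_view=float(acq["fov"]),
        matrix_size=int(acq["matrix"]),
        slice_thickness=float(acq["slice_thickness"]),
        n_phases=int(acq["n_phases"]),
        cycle_period=float(acq["period"]),
        venc=float(acq["venc"]),
    )
    return {
        "fluid": fluid,
        "geometry": geometry,
        "acquisition": acquisition,
        "simulation": dict(raw.get("simulation") or {}),
    }
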