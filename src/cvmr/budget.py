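"""Discrete control-volume mass and momentum estimators.

The package's core method.  For a conduit control volume (CV) of
cross-section S and axial length L, with through-plane velocities v_i^k
measured on an ROI of pixel area S_pix, the axial momentum balance

    F_inertial + (momentum outflow - inflow) = F_body + F_pressure + F_viscous

is evaluated term by term from a gated velocity series:

    Q^k        = sum_ROI v_i^k S_pix                       (volume flow)
    F_I^k      = rho L (dQ/dt)^k                           (inertial force)
    F_M^k      = rho sum_ROI (v_i^k)^2 S_pix               (momentum inflow)
    F_V^k      = -mu L sum_perimeter-faces (dv/dn)^k dl    (viscous drag)
    F_B        = rho V (g_axial - a_axial)                 (body force)

and solved for the pressure force.  In the simplified mode appropriate to
short conduits at high Womersley number — momentum inflow cancels outflow,
the CV is static and horizontal, and viscous drag is small — the pressure
force equals the inertial force sample for sample.

The per-pixel Navier-Stokes pressure-gradient estimator of Urchuk & Plewes
(temporal and spatial finite differences of the same velocity data, split
into inertial and viscous parts) is provided as the established comparator.

Discrete estimators here are reconstructions from the physical definitions
of each term; see docs/methods.md for stencils and sign conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AcquisitionGeometry,
    ConduitGeometry,
    ConfigurationError,
    DYNE_PER_CM3_TO_PA_PER_CM,
    DegenerateMaskError,
    EmptyRoiError,
    FluidProperties,
    InsufficientDataError,
    InvalidParameterError,
    velocity_noise_sigma,
)
from .segmentation import RoiMask
from .synth import VelocitySeries

# ---------------------------------------------------------------------------
# Waveform container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Waveform:
    """One cycle of a uniformly sampled periodic signal.

    Sample k sits at t_k = k * period / n_samples; index arithmetic is
    modulo n_samples (the signal is treated as periodic).
    """

    values: np.ndarray
    period: float
    units: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).copy()
        )
        if self.values.ndim != 1:
            raise InvalidParameterError("waveform values must be one-dimensional")
        if not (self.period > 0):
            raise InvalidParameterError("period must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return self.period / self.n_samples

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def amplitude(self) -> float:
        """max |values| over the cycle."""
        return float(np.max(np.abs(self.values)))

    @property
    def range(self) -> float:
        """max - min over the cycle."""
        return float(np.ptp(self.values))

    def compatible_with(self, other: "Waveform") -> bool:
        return (
            self.n_samples == other.n_samples
            and abs(self.period - other.period) <= 1e-12 * self.period
        )


def _require_compatible(*waveforms: Waveform) -> None:
    first = waveforms[0]
    for w in waveforms[1:]:
        if not first.compatible_with(w):
            raise ConfigurationError(
                "waveforms must share n_samples and period: "
                f"({first.n_samples}, {first.period}) vs ({w.n_samples}, {w.period})"
            )


def periodic_derivative(
    waveform: Waveform, scheme: str = "central"
) -> Waveform:
    """d/dt of a periodic waveform.

    'central': second-order periodic central difference
    (x_{k+1} - x_{k-1}) / (2 dt); attenuates a single harmonic by
    sin(omega dt)/(omega dt).  'spectral': FFT differentiation, exact for
    band-limited signals such as the single-harmonic pump waveform.
    """
    if waveform.n_samples < 3:
        raise InsufficientDataError(
            f"derivative needs >= 3 samples, got {waveform.n_samples}"
        )
    x = waveform.values
    if scheme == "central":
        d = (np.roll(x, -1) - np.roll(x, 1)) / (2.0 * waveform.dt)
    elif scheme == "spectral":
        n = waveform.n_samples
        omega_k = 2j * math.pi * np.fft.fftfreq(n, d=waveform.dt)
        d = np.real(np.fft.ifft(omega_k * np.fft.fft(x)))
    else:
        raise InvalidParameterError(f"unknown derivative scheme '{scheme}'")
    return Waveform(d, waveform.period, waveform.units + "/s")


# ---------------------------------------------------------------------------
# Mass conservation
# ---------------------------------------------------------------------------


def flow_rate(series: VelocitySeries, mask: RoiMask) -> Waveform:
    """Volume flow rate waveform Q^k = sum_ROI v_i^k S_pix, cm^3/s.

    Sign follows the series' axial convention (flow into the phantom
    positive).  This is the discrete surface integral of the through-plane
    velocity over the flow-crossing portion of the control surface.
    """
    _check_mask_fits(series, mask)
    s_pix = series.acquisition.pixel_area
    q = series.velocity[:, mask.mask].sum(axis=1) * s_pix
    return Waveform(q, series.acquisition.cycle_period, "cm^3/s")


def mass_balance_volume_rate(
    inflows: list[Waveform], net_production: float = 0.0
) -> Waveform:
    """Rate of change of fluid volume from incompressible mass conservation.

    dV/dt = sum of inflow waveforms + net volumetric production (cm^3/s);
    the production term carries physiological CSF formation/absorption.
    """
    if not inflows:
        raise InvalidParameterError("at least one inflow waveform is required")
    _require_compatible(*inflows)
    total = np.sum([w.values for w in inflows], axis=0) + net_production
    return Waveform(total, inflows[0].period, "cm^3/s")


# ---------------------------------------------------------------------------
# Momentum conservation, term by term
# ---------------------------------------------------------------------------


def momentum_inflow(
    series: VelocitySeries, mask: RoiMask, fluid: FluidProperties
) -> Waveform:
    """Axial momentum flux through the measured control surface, dyne.

    F_M^k = rho sum_ROI (v_i^k)^2 S_pix — the single-surface inflow
    magnitude.  For a short conduit the opposing surface carries a nearly
    equal flux, so the net (in - out) contribution is far smaller than this
    waveform's variation.
    """
    _check_mask_fits(series, mask)
    s_pix = series.acquisition.pixel_area
    f = fluid.density * (series.velocity[:, mask.mask] ** 2).sum(axis=1) * s_pix
    return Waveform(f, series.acquisition.cycle_period, "dyne")


def inertial_force(
    flow: Waveform,
    fluid: FluidProperties,
    geometry: ConduitGeometry,
    scheme: str = "central",
) -> Waveform:
    """Rate of change of axial momentum in the CV, F_I = rho L dQ/dt, dyne.

    Assumes an axially uniform velocity profile over the conduit length L
    (fully developed flow), so the CV momentum is rho L Q(t).
    """
    dq = periodic_derivative(flow, scheme=scheme)
    return Waveform(
        fluid.density * geometry.axial_length * dq.values, flow.period, "dyne"
    )


def viscous_force(
    series: VelocitySeries,
    mask: RoiMask,
    fluid: FluidProperties,
    geometry: ConduitGeometry,
) -> Waveform:
    """Viscous drag on the lateral control surface, dyne.

    The wall shear is estimated at every exposed perimeter face by the
    one-sided two-point difference from the perimeter pixel toward its
    interior 4-neighbour across that face; each face contributes a wall
    strip of length = pixel spacing and axial extent L, assuming an
    axially uniform profile:

        F_V^k = -mu L sum_faces (v_interior^k - v_perimeter^k)

    (the spacing in the gradient and the face length cancel).  The sign
    opposes the bulk flow.  One-sided differences under-resolve the thin
    high-alpha boundary layer, which is why the simplified pressure
    estimate excludes this term.
    """
    _check_mask_fits(series, mask)
    m = mask.mask
    ny, nx = m.shape
    padded = np.zeros((ny + 2, nx + 2), dtype=bool)
    padded[1:-1, 1:-1] = m
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []  # (perimeter, interior)
    for drow, dcol in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        # Face exposed in direction (drow, dcol); interior neighbour opposite.
        exposed = m & ~padded[1 + drow : 1 + drow + ny, 1 + dcol : 1 + dcol + nx]
        for row, col in np.argwhere(exposed):
            irow, icol = row - drow, col - dcol
            if not (0 <= irow < ny and 0 <= icol < nx) or not m[irow, icol]:
                raise DegenerateMaskError(
                    f"perimeter pixel ({row}, {col}) has no interior 4-neighbour "
                    f"opposite its exposed face ({drow}, {dcol})"
                )
            pairs.append(((row, col), (irow, icol)))
    if not pairs:
        raise DegenerateMaskError("mask has no exposed perimeter faces")
    perim = np.array([p for p, _ in pairs])
    inner = np.array([q for _, q in pairs])
    v_perim = series.velocity[:, perim[:, 0], perim[:, 1]]
    v_inner = series.velocity[:, inner[:, 0], inner[:, 1]]
    f = -fluid.dynamic_viscosity * geometry.axial_length * (
        v_inner - v_perim
    ).sum(axis=1)
    return Waveform(f, series.acquisition.cycle_period, "dyne")


def body_force(
    fluid: FluidProperties,
    cv_volume: float,
    axial_gravity: float = 0.0,
    axial_acceleration: float = 0.0,
) -> float:
    """Axial body force rho V (g_axial - a_axial), dyne.

    Zero for a static phantom with a horizontal axis — the configuration
    of every experiment this package emulates.
    """
    return fluid.density * cv_volume * (axial_gravity - axial_acceleration)


def pressure_force_cv(
    inertial: Waveform,
    mode: str = "simplified",
    momentum_in: Waveform | None = None,
    momentum_out: Waveform | None = None,
    viscous: Waveform | None = None,
    body: float = 0.0,
) -> Waveform:
    """Axial pressure force the pressure field must exert on the CV, dyne.

    simplified (short conduit, high alpha, static horizontal CV):
        F_P = F_I.
    full:
        F_P = F_I + (momentum out - momentum in) - F_V - F_B,
    from the balance F_I + (out - in) = F_B + F_P + F_V; viscous drag F_V
    is negative for positive flow, so -F_V adds the magnitude of the drag.
    """
    if mode == "simplified":
        return Waveform(inertial.values.copy(), inertial.period, "dyne")
    if mode != "full":
        raise InvalidParameterError(f"unknown mode '{mode}'")
    if momentum_in is None or momentum_out is None:
        raise ConfigurationError(
            "full mode requires momentum waveforms for both surfaces"
        )
    _require_compatible(inertial, momentum_in, momentum_out)
    values = inertial.values + (momentum_out.values - momentum_in.values) - body
    if viscous is not None:
        _require_compatible(inertial, viscous)
        values = values - viscous.values
    return Waveform(values, inertial.period, "dyne")


# ---------------------------------------------------------------------------
# Urchuk-Plewes comparator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UrchukPlewesResult:
    """Per-pixel Navier-Stokes pressure-gradient estimate, ROI-averaged.

    ``gradient`` = inertial + viscous parts, as -dp/dz in Pa/cm;
    ``force`` = gradient x S L in dyne, directly comparable to the CV
    pressure force.
    """

    gradient: Waveform  # Pa/cm
    inertial_part: Waveform  # Pa/cm
    viscous_part: Waveform  # Pa/cm
    force: Waveform  # dyne
    inertial_force: Waveform  # dyne
    viscous_force: Waveform  # dyne
    n_stencil_pixels: int = 0


def urchuk_plewes(
    series: VelocitySeries,
    mask: RoiMask,
    fluid: FluidProperties,
    geometry: ConduitGeometry,
) -> UrchukPlewesResult:
    """Pressure-gradient waveform from per-pixel finite differences.

    At every ROI pixel whose four neighbours are all inside the ROI, the
    axial Navier-Stokes equation gives

        -dp/dz = rho dv/dt - mu laplacian(v),

    with a periodic central difference in time and the 5-point Laplacian in
    space.  The estimate is averaged over these full-stencil pixels (no
    boundary extrapolation), split into its inertial and viscous parts, and
    multiplied by the CV volume S L for comparison with CV forces.
    """
    _check_mask_fits(series, mask)
    if series.n_phases < 3:
        raise InsufficientDataError("temporal central difference needs >= 3 phases")
    m = mask.mask
    interior = (
        m
        & np.roll(m, 1, axis=0)
        & np.roll(m, -1, axis=0)
        & np.roll(m, 1, axis=1)
        & np.roll(m, -1, axis=1)
    )
    # np.roll wraps across image borders; an ROI touching the border could
    # alias, so exclude border pixels outright.
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    if not interior.any():
        raise DegenerateMaskError(
            "no ROI pixel has a full interior 5-point stencil"
        )
    v = series.velocity
    dt = series.acquisition.cycle_period / series.n_phases
    d = series.acquisition.pixel_spacing
    dv_dt = (np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)) / (2.0 * dt)
    lap = (
        np.roll(v, 1, axis=1)
        + np.roll(v, -1, axis=1)
        + np.roll(v, 1, axis=2)
        + np.roll(v, -1, axis=2)
        - 4.0 * v
    ) / d**2
    inertial_cgs = fluid.density * dv_dt[:, interior].mean(axis=1)
    viscous_cgs = -fluid.dynamic_viscosity * lap[:, interior].mean(axis=1)
    period = series.acquisition.cycle_period
    sl = geometry.volume
    to_pa = DYNE_PER_CM3_TO_PA_PER_CM
    return UrchukPlewesResult(
        gradient=Waveform((inertial_cgs + viscous_cgs) * to_pa, period, "Pa/cm"),
        inertial_part=Waveform(inertial_cgs * to_pa, period, "Pa/cm"),
        viscous_part=Waveform(viscous_cgs * to_pa, period, "Pa/cm"),
        force=Waveform((inertial_cgs + viscous_cgs) * sl, period, "dyne"),
        inertial_force=Waveform(inertial_cgs * sl, period, "dyne"),
        viscous_force=Waveform(viscous_cgs * sl, period, "dyne"),
        n_stencil_pixels=int(interior.sum()),
    )


# ---------------------------------------------------------------------------
# Noise propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertaintyReport:
    """Propagated measurement-noise uncertainties for the CV estimates.

    Independent pixel noise of standard deviation sigma_v propagates to
    sigma_Q = sigma_v S_pix sqrt(N) in the flow waveform and, through the
    temporal derivative operator, to sigma_F = rho L sigma_Q g in the
    inertial/pressure force, where g is the operator's white-noise gain
    (1/(sqrt(2) dt) for the periodic central difference).
    """

    sigma_v: float  # cm/s
    sigma_q: float  # cm^3/s
    sigma_inertial: float  # dyne
    scheme: str
    notes: str = ""


def derivative_noise_gain(n_samples: int, dt: float, scheme: str) -> float:
    """White-noise standard-deviation gain of the periodic derivative operator."""
    if scheme == "central":
        return 1.0 / (math.sqrt(2.0) * dt)
    if scheme == "spectral":
        omega_k = 2.0 * math.pi * np.fft.fftfreq(n_samples, d=dt)
        return float(np.sqrt(np.mean(omega_k**2)))
    raise InvalidParameterError(f"unknown derivative scheme '{scheme}'")


def propagate_uncertainty(
    acquisition: AcquisitionGeometry,
    snr: float,
    mask: RoiMask,
    fluid: FluidProperties,
    geometry: ConduitGeometry,
    scheme: str = "central",
) -> UncertaintyReport:
    """Propagate velocity noise to flow-rate and inertial-force uncertainty."""
    sigma_v = velocity_noise_sigma(acquisition.venc, snr)
    sigma_q = sigma_v * acquisition.pixel_area * math.sqrt(mask.pixel_count)
    dt = acquisition.cycle_period / acquisition.n_phases
    gain = derivative_noise_gain(acquisition.n_phases, dt, scheme)
    sigma_f = fluid.density * geometry.axial_length * sigma_q * gain
    return UncertaintyReport(
        sigma_v=sigma_v,
        sigma_q=sigma_q,
        sigma_inertial=sigma_f,
        scheme=scheme,
        notes=(
            "independent Gaussian pixel noise; sigma_q = sigma_v S_pix sqrt(N); "
            "sigma_F = rho L sigma_q x derivative-operator gain"
        ),
    )


# ---------------------------------------------------------------------------
# Assembled budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentumBudget:
    """Every term of the axial momentum balance for one conduit CV."""

    flow: Waveform  # cm^3/s
    inertial_force: Waveform  # dyne
    momentum_inflow: Waveform  # dyne
    viscous_force: Waveform  # dyne
    body_force: float  # dyne
    pressure_force_cv: Waveform  # dyne
    up: UrchukPlewesResult
    uncertainty: UncertaintyReport | None
    geometry: ConduitGeometry
    fluid: FluidProperties
    mode: str = "simplified"
    scheme: str = "central"
    provenance: dict = field(default_factory=dict)

    @property
    def up_gradient(self) -> Waveform:
        """Urchuk-Plewes -dp/dz waveform, Pa/cm."""
        return self.up.gradient

    @property
    def pressure_gradient_cv(self) -> Waveform:
        """CV pressure force expressed as a gradient, Pa/cm."""
        return Waveform(
            self.pressure_force_cv.values
            / self.geometry.volume
            * DYNE_PER_CM3_TO_PA_PER_CM,
            self.pressure_force_cv.period,
            "Pa/cm",
        )


def compute_budget(
    series: VelocitySeries,
    mask: RoiMask,
    fluid: FluidProperties,
    geometry: ConduitGeometry,
    mode: str = "simplified",
    scheme: str = "central",
    snr: float | None = None,
    axial_gravity: float = 0.0,
    axial_acceleration: float = 0.0,
) -> MomentumBudget:
    """Evaluate the full momentum budget of a conduit CV from one series.

    The single measured slice supplies the flow, inertial, momentum-inflow
    and viscous estimates; in 'full' mode the opposing surface is assumed
    to carry the same momentum flux (fully developed flow), so the net
    momentum term is zero and the full and simplified estimates differ only
    by the viscous and body terms.
    """
    q = flow_rate(series, mask)
    f_i = inertial_force(q, fluid, geometry, scheme=scheme)
    f_m = momentum_inflow(series, mask, fluid)
    f_v = viscous_force(series, mask, fluid, geometry)
    f_b = body_force(fluid, geometry.volume, axial_gravity, axial_acceleration)
    if mode == "simplified":
        f_p = pressure_force_cv(f_i, mode="simplified")
    else:
        f_p = pressure_force_cv(
            f_i,
            mode="full",
            momentum_in=f_m,
            momentum_out=f_m,  # fully developed: outflow profile = inflow profile
            viscous=f_v,
            body=f_b,
        )
    up = urchuk_plewes(series, mask, fluid, geometry)
    unc = (
        propagate_uncertainty(series.acquisition, snr, mask, fluid, geometry, scheme)
        if snr is not None
        else None
    )
    return MomentumBudget(
        flow=q,
        inertial_force=f_i,
        momentum_inflow=f_m,
        viscous_force=f_v,
        body_force=f_b,
        pressure_force_cv=f_p,
        up=up,
        uncertainty=unc,
        geometry=geometry,
        fluid=fluid,
        mode=mode,
        scheme=scheme,
        provenance=dict(series.provenance),
    )


def _check_mask_fits(series: VelocitySeries, mask: RoiMask) -> None:
    if mask.mask.shape != series.velocity.shape[1:]:
        raise ConfigurationError(
            f"mask shape {mask.mask.shape} does not fit series grid "
            f"{series.velocity.shape[1:]}"
        )
    if not mask.mask.any():
        raise EmptyRoiError("ROI mask contains no pixels")
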