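"""Synthetic PC-MR acquisition generator.

Renders Womersley pipe flow onto a pixel grid as a gated through-plane
velocity + magnitude series, adds calibrated velocity noise and aliasing,
and emulates the high-rate differential-pressure sensor trace.  Together
with :mod:`cvmr.womersley` this replaces the physical flow phantom: every
estimator in the package can be validated against the analytic solution
that generated its input.

Defaults reproduce the phantom acquisition: 0.2 cm pixels (25.6 cm FOV,
128x128), venc 20 cm/s, 17 phases over a 1 s cycle, SNR 25, sinusoidal
flow of 46 mL/min amplitude in a 1.27 cm passage.

Gating is emulated by sampling the analytic solution at ``n_phases``
uniform times t_k = k T / n_phases; no k-space or retrospective-binning
simulation is attempted.  Noise is zero-mean Gaussian on the velocity map
(the high-SNR limit of two-point phase-difference noise) with standard
deviation :func:`cvmr.core.velocity_noise_sigma`, and 1/SNR on magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    AcquisitionGeometry,
    ConfigurationError,
    InvalidParameterError,
    velocity_noise_sigma,
)
from .womersley import OscillatoryPipeFlow


@dataclass(frozen=True)
class GridPlacement:
    """Where the lumen centre falls relative to the pixel lattice.

    ``lumen_center_offset`` is the (x, y) offset from the centre pixel's
    centre, in fractions of a pixel, each in [0, 1).  (0, 0) puts the lumen
    centre on a pixel centre; (0.5, 0.5) on a pixel corner — the two
    alignments that yield 37 and 32 in-lumen pixels for the phantom bore on
    a 0.2 cm grid.  ``supersample`` k renders each pixel as the mean of a
    k x k sub-grid (partial volume); k = 1 is pixel-centre sampling.
    """

    lumen_center_offset: tuple[float, float] = (0.0, 0.0)
    supersample: int = 1

    def __post_init__(self) -> None:
        ox, oy = self.lumen_center_offset
        if not (0.0 <= ox < 1.0 and 0.0 <= oy < 1.0):
            raise InvalidParameterError(
                f"lumen_center_offset components must be in [0, 1), got {self.lumen_center_offset}"
            )
        if self.supersample < 1:
            raise InvalidParameterError("supersample must be >= 1")


#: Lumen centred on a pixel centre (37 in-lumen pixels for the phantom bore).
CENTERED = GridPlacement((0.0, 0.0))
#: Lumen centred on a pixel corner (32 in-lumen pixels for the phantom bore).
CORNER = GridPlacement((0.5, 0.5))


@dataclass(frozen=True)
class VelocitySeries:
    """Gated stack of through-plane velocity and magnitude images.

    ``velocity``: (n_phases, ny, nx) in cm/s; ``magnitude``: same shape,
    in [0, 1] before noise; ``timestamps``: one per phase, uniform over a
    single cycle.
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    acquisition: AcquisitionGeometry
    timestamps: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.velocity.shape != self.magnitude.shape:
            raise ConfigurationError(
                f"velocity shape {self.velocity.shape} != magnitude shape "
                f"{self.magnitude.shape}"
            )
        if self.velocity.shape[0] != len(self.timestamps):
            raise ConfigurationError("one timestamp per phase is required")
        dt = np.diff(self.timestamps)
        if len(dt) and not np.all(dt > 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if len(self.timestamps) and (
            self.timestamps[-1] - self.timestamps[0]
        ) >= self.acquisition.cycle_period:
            raise ConfigurationError("timestamps must span less than one cycle")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]


def lumen_mask(
    radius: float, acquisition: AcquisitionGeometry, placement: GridPlacement
) -> np.ndarray:
    """Boolean image of pixels whose centres lie strictly inside the lumen."""
    x, y = _pixel_center_coords(acquisition, placement)
    return np.hypot(x, y) < radius


def _pixel_center_coords(
    acquisition: AcquisitionGeometry, placement: GridPlacement
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre (x, y) coordinates relative to the lumen centre, cm."""
    n = acquisition.matrix_size
    d = acquisition.pixel_spacing
    ox, oy = placement.lumen_center_offset
    # Lumen centre sits at the centre pixel's centre plus the fractional offset.
    idx = np.arange(n) - n // 2
    x = (idx[None, :] - ox) * d
    y = (idx[:, None] - oy) * d
    return np.broadcast_to(x, (n, n)), np.broadcast_to(y, (n, n))


def render_series(
    flow: OscillatoryPipeFlow,
    acquisition: AcquisitionGeometry,
    placement: GridPlacement = CENTERED,
    background_magnitude: float = 0.2,
) -> VelocitySeries:
    """Render an analytic flow as a noise-free gated velocity/magnitude series.

    Pixel-centre sampling (default): a pixel inside the lumen carries the
    analytic velocity at its centre and magnitude 1.0; outside pixels carry
    velocity exactly 0 and ``background_magnitude``.  With ``supersample``
    k > 1 each pixel value is the mean over a k x k sub-grid, which models
    partial-volume averaging at the wall.
    """
    n = acquisition.matrix_size
    d = acquisition.pixel_spacing
    if flow.radius * 2.0 > acquisition.field_of_view:
        raise ConfigurationError(
            f"lumen diameter {2 * flow.radius} cm exceeds field of view "
            f"{acquisition.field_of_view} cm"
        )
    times = (
        np.arange(acquisition.n_phases)
        * acquisition.cycle_period
        / acquisition.n_phases
    )
    k = placement.supersample
    if k == 1:
        x, y = _pixel_center_coords(acquisition, placement)
        sub_x, sub_y = x[None], y[None]
        weights = 1.0
    else:
        x, y = _pixel_center_coords(acquisition, placement)
        # Sub-grid offsets covering the pixel uniformly, centred on zero.
        off = (np.arange(k) + 0.5) / k - 0.5
        sub_x = np.broadcast_to(
            x[None, None] + (off * d)[None, :, None, None], (k, k, n, n)
        ).reshape(k * k, n, n)
        sub_y = np.broadcast_to(
            y[None, None] + (off * d)[:, None, None, None], (k, k, n, n)
        ).reshape(k * k, n, n)
        weights = 1.0 / (k * k)
    r = np.hypot(sub_x, sub_y)
    inside = r < flow.radius
    vel = np.zeros((acquisition.n_phases, n, n))
    if flow.gradient_amplitude != 0 and inside.any():
        rin = r[inside]
        for j, t in enumerate(times):
            v_sub = np.zeros_like(r)
            v_sub[inside] = flow.velocity(rin, t)
            vel[j] = (v_sub * weights).sum(axis=0) if k > 1 else v_sub[0]
    mag_single = np.where(inside, 1.0, background_magnitude)
    mag = (mag_single * weights).sum(axis=0) if k > 1 else mag_single[0]
    magnitude = np.broadcast_to(mag, vel.shape).copy()
    return VelocitySeries(
        velocity=vel,
        magnitude=magnitude,
        acquisition=acquisition,
        timestamps=times,
        provenance={
            "generator": "cvmr.synth.render_series",
            "flow": flow.to_dict(),
            "placement": {
                "lumen_center_offset": list(placement.lumen_center_offset),
                "supersample": placement.supersample,
            },
            "background_magnitude": background_magnitude,
        },
    )


def add_noise(series: VelocitySeries, snr: float, seed: int) -> VelocitySeries:
    """Add calibrated measurement noise to a rendered series.

    Velocity pixels receive i.i.d. zero-mean Gaussian noise of standard
    deviation ``velocity_noise_sigma(venc, snr)``; magnitude pixels receive
    Gaussian noise of standard deviation 1/SNR.  Identical seeds give
    bit-identical output.
    """
    if not (snr > 0):
        raise InvalidParameterError(f"snr must be > 0, got {snr}")
    rng = np.random.default_rng(seed)
    sigma_v = velocity_noise_sigma(series.acquisition.venc, snr)
    vel = series.velocity + rng.normal(0.0, sigma_v, series.velocity.shape)
    mag = series.magnitude + rng.normal(0.0, 1.0 / snr, series.magnitude.shape)
    prov = dict(series.provenance)
    prov.update({"snr": snr, "noise_seed": int(seed), "sigma_v_cm_s": sigma_v})
    return replace(series, velocity=vel, magnitude=mag, provenance=prov)


def wrap_velocity(series: VelocitySeries) -> VelocitySeries:
    """Apply phase wrapping: velocities alias into (-venc, venc].

    Each velocity v is shifted by the multiple of 2 venc that lands it in
    (-venc, venc] -- the aliasing a two-point phase-contrast measurement
    imposes (+/- venc are the same encoded phase).  Values already in range
    are returned bit-identically.
    """
    venc = series.acquisition.venc
    shift = np.ceil((series.velocity - venc) / (2.0 * venc))
    wrapped = series.velocity - 2.0 * venc * shift
    return replace(series, velocity=wrapped)


def simulate_sensor_trace(
    pressure_values: np.ndarray,
    period: float,
    sampling_rate: float,
    n_cycles: int,
    noise_sigma: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Emulate the high-rate differential-pressure sensor recording.

    Tiles one periodic pressure waveform (``pressure_values`` uniformly
    sampled over ``period`` seconds, in Pa) over ``n_cycles`` cycles at
    ``sampling_rate`` Hz, interpolating linearly between waveform samples,
    then adds Gaussian noise of ``noise_sigma`` Pa.  Returns (time_s, dp_pa).
    """
    if sampling_rate * period < 2:
        raise InvalidParameterError(
            "sampling_rate must give at least 2 samples per cycle"
        )
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    values = np.asarray(pressure_values, dtype=float)
    n = len(values)
    n_samples = round(sampling_rate * n_cycles * period)
    t = np.arange(n_samples) / sampling_rate
    # Periodic linear interpolation: close the cycle with the first sample.
    knots_t = np.arange(n + 1) * period / n
    knots_v = np.concatenate([values, values[:1]])
    dp = np.interp(np.mod(t, period), knots_t, knots_v)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dp = dp + rng.normal(0.0, noise_sigma, n_samples)
    return t, dp
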