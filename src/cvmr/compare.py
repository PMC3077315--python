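"""Waveform statistics: phase/ensemble averaging, sinusoid fits, rms deviation.

These are the operations used to reduce a long high-rate sensor trace to a
single representative cycle (phase averaging over gated cycles, ensemble
averaging over repeated experiments) and to compare waveforms from
different routes (normalized rms deviation, sinusoidal fits at the known
pump frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    ConfigurationError,
    InsufficientDataError,
    InvalidParameterError,
    ZeroRangeError,
)
from .budget import Waveform, _require_compatible


@dataclass(frozen=True)
class SensorTrace:
    """Uniformly sampled differential-pressure record (time in s, value in Pa)."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ConfigurationError("time and value must be equal-length 1-D arrays")
        if len(t) < 2:
            raise InsufficientDataError("a sensor trace needs at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ConfigurationError("sensor trace must be uniformly sampled")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0] + (self.time[1] - self.time[0])


def phase_average(trace: SensorTrace, period: float, n_bins: int) -> Waveform:
    """Collapse a multi-cycle trace to one cycle by phase binning.

    Samples are assigned to n_bins uniform phase bins modulo the period and
    averaged within each bin; the incomplete trailing cycle is discarded.
    Bins are centred on the gated-frame times t_k = k * period / n_bins
    (bin k spans phases [k - 1/2, k + 1/2) * period / n_bins), so the
    result aligns sample-for-sample with a gated velocity series.
    """
    if not (period > 0):
        raise InvalidParameterError("period must be > 0")
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    t0 = trace.time - trace.time[0]
    n_complete = int(np.floor(trace.duration / period + 1e-9))
    if n_complete < 2:
        raise InsufficientDataError(
            f"phase averaging needs >= 2 full periods, trace spans {trace.duration:.3g} s"
        )
    keep = t0 < n_complete * period - 1e-12
    phase_bin = np.rint(np.mod(t0[keep], period) / period * n_bins).astype(int)
    phase_bin = np.mod(phase_bin, n_bins)
    sums = np.bincount(phase_bin, weights=trace.value[keep], minlength=n_bins)
    counts = np.bincount(phase_bin, minlength=n_bins)
    if np.any(counts == 0):
        raise InsufficientDataError(
            "sampling rate too low: some phase bins received no samples"
        )
    return Waveform(sums / counts, period, "Pa")


def ensemble_average(waveforms: list[Waveform]) -> tuple[Waveform, Waveform]:
    """Pointwise mean and sample standard deviation over repeated experiments.

    Returns (mean, pointwise_std); std uses the n-1 normalisation and is
    zero for a single member.
    """
    if not waveforms:
        raise InvalidParameterError("at least one waveform is required")
    _require_compatible(*waveforms)
    stack = np.stack([w.values for w in waveforms])
    mean = stack.mean(axis=0)
    std = (
        stack.std(axis=0, ddof=1) if len(waveforms) > 1 else np.zeros_like(mean)
    )
    w0 = waveforms[0]
    return Waveform(mean, w0.period, w0.units), Waveform(std, w0.period, w0.units)


def fit_sinusoid(waveform: Waveform, frequency: float) -> dict:
    """Least-squares fit value ~ A sin(2 pi f t + phi) + c at a known frequency.

    Linear least squares on the {sin, cos, 1} basis; returns
    {'amplitude', 'phase', 'offset', 'rms_residual'}.
    """
    if waveform.n_samples < 3:
        raise InsufficientDataError("sinusoid fit needs >= 3 samples")
    if not (frequency > 0):
        raise InvalidParameterError("frequency must be > 0")
    t = waveform.times
    omega = 2.0 * math.pi * frequency
    basis = np.column_stack([np.sin(omega * t), np.cos(omega * t), np.ones_like(t)])
    if np.linalg.matrix_rank(basis) < 3:
        raise InvalidParameterError(
            "degenerate sampling: sinusoid basis is rank-deficient at this frequency"
        )
    coef, *_ = np.linalg.lstsq(basis, waveform.values, rcond=None)
    a, b, c = coef
    residual = waveform.values - basis @ coef
    return {
        "amplitude": float(math.hypot(a, b)),
        "phase": float(math.atan2(b, a)),
        "offset": float(c),
        "rms_residual": float(np.sqrt(np.mean(residual**2))),
    }


def normalized_rms_deviation(
    test: Waveform, reference: Waveform, normalization: str = "range"
) -> dict:
    """rms deviation of test from reference, absolute and as a percentage.

    'range' (default): percent = rms / (max - min of reference) x 100 —
    the convention for flow-versus-fit comparisons.  'amplitude':
    percent = rms / max|reference| x 100.  Both conventions are named in
    reports; they differ by a factor of ~2 for zero-mean waveforms.
    """
    _require_compatible(test, reference)
    rms = float(np.sqrt(np.mean((test.values - reference.values) ** 2)))
    if normalization == "range":
        denom = reference.range
    elif normalization == "amplitude":
        denom = reference.amplitude
    else:
        raise InvalidParameterError(f"unknown normalization '{normalization}'")
    if denom == 0:
        raise ZeroRangeError(
            f"reference waveform has zero {normalization}; cannot normalise"
        )
    return {
        "absolute": rms,
        "percent": 100.0 * rms / denom,
        "normalization": normalization,
    }


def mean_relative_deviation(
    test: Waveform, reference: Waveform, zero_tolerance: float = 1e-12
) -> float:
    """Mean over the cycle of |test - reference| / |reference|, as a percent.

    Samples where the reference is (numerically) zero are excluded — for a
    pure sine sampled from t = 0 that is the zero-crossing frame, where a
    relative error is undefined.  This is the metric used to quantify the
    spatial-discretization error of the pixel-summed flow waveform against
    the analytic solution.
    """
    _require_compatible(test, reference)
    ref = reference.values
    scale = np.max(np.abs(ref))
    if scale == 0:
        raise ZeroRangeError("reference waveform is identically zero")
    keep = np.abs(ref) > zero_tolerance * scale
    if not keep.any():
        raise ZeroRangeError("no reference sample is distinguishable from zero")
    return float(
        100.0 * np.mean(np.abs(test.values[keep] - ref[keep]) / np.abs(ref[keep]))
    )
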