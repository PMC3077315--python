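"""File I/O: NIfTI image series with JSON sidecars, CSV waveforms, budget reports.

Interchange formats
-------------------
* velocity/magnitude series: 4-D NIfTI (x, y, z=1, t), two files
  ``<stem>.nii`` and ``<stem>_mag.nii``, plus ``<stem>.json`` sidecar with
  acquisition metadata and generator provenance;
* ROI mask: 3-D NIfTI of 0/1 plus a JSON summary {N, area_cm2, threshold};
* waveforms: CSV with header ``time_s,value,units``;
* sensor traces: CSV with header ``time_s,dp_pa``;
* momentum budgets: a single JSON report carrying every waveform at full
  float precision, geometry, fluid, uncertainties and scheme choices.

All JSON reports carry a ``schema_version`` field.  Round trips are
lossless: arrays are written as float64 and JSON floats use repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .budget import MomentumBudget, UncertaintyReport, Waveform
from .core import (
    AcquisitionGeometry,
    ConduitGeometry,
    FluidProperties,
    InsufficientDataError,
    SchemaError,
)
from .compare import SensorTrace
from .segmentation import RoiMask
from .synth import VelocitySeries

SCHEMA_VERSION = "1"

_SIDECAR_REQUIRED = (
    "venc_cm_s",
    "pixel_spacing_cm",
    "period_s",
    "n_phases",
    "fov_cm",
    "matrix",
    "slice_thickness_cm",
)


def _affine(pixel_spacing: float, slice_thickness: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


# ---------------------------------------------------------------------------
# Velocity series
# ---------------------------------------------------------------------------


def write_series(series: VelocitySeries, stem) -> dict:
    """Write a series as <stem>.nii + <stem>_mag.nii + <stem>.json.

    Returns the sidecar dict.  Arrays are stored (x, y, z=1, t) per NIfTI
    convention; in memory they are (t, y, x).
    """
    stem = Path(stem)
    acq = series.acquisition
    affine = _affine(acq.pixel_spacing, acq.slice_thickness)
    for data, path in (
        (series.velocity, stem.with_suffix(".nii")),
        (series.magnitude, Path(str(stem) + "_mag.nii")),
    ):
        img = nib.Nifti1Image(
            data.transpose(2, 1, 0)[:, :, None, :].astype(np.float64), affine
        )
        nib.save(img, path)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "cvmr_version": __version__,
        "venc_cm_s": acq.venc,
        "pixel_spacing_cm": acq.pixel_spacing,
        "period_s": acq.cycle_period,
        "n_phases": acq.n_phases,
        "fov_cm": acq.field_of_view,
        "matrix": acq.matrix_size,
        "slice_thickness_cm": acq.slice_thickness,
        "timestamps_s": series.timestamps.tolist(),
        "provenance": series.provenance,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return sidecar


def read_series(stem) -> VelocitySeries:
    """Read a series written by :func:`write_series`."""
    stem = Path(stem)
    sidecar_path = stem.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"sidecar {sidecar_path} not found")
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in sidecar]
    if missing:
        raise SchemaError(f"sidecar is missing keys: {', '.join(missing)}")
    acq = AcquisitionGeometry(
        field_of_view=sidecar["fov_cm"],
        matrix_size=sidecar["matrix"],
        slice_thickness=sidecar["slice_thickness_cm"],
        n_phases=sidecar["n_phases"],
        cycle_period=sidecar["period_s"],
        venc=sidecar["venc_cm_s"],
    )
    vel = np.asarray(nib.load(stem.with_suffix(".nii")).get_fdata())
    mag = np.asarray(nib.load(Path(str(stem) + "_mag.nii")).get_fdata())
    vel = vel[:, :, 0, :].transpose(2, 1, 0)
    mag = mag[:, :, 0, :].transpose(2, 1, 0)
    return VelocitySeries(
        velocity=vel,
        magnitude=mag,
        acquisition=acq,
        timestamps=np.asarray(sidecar["timestamps_s"], dtype=float),
        provenance=sidecar.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def write_mask(mask: RoiMask, path, summary_path=None) -> dict:
    """Write a 0/1 NIfTI mask and a JSON summary {N, area_cm2, threshold}."""
    path = Path(path)
    affine = _affine(mask.pixel_spacing, 1.0)
    img = nib.Nifti1Image(
        mask.mask.T[:, :, None].astype(np.uint8), affine
    )
    nib.save(img, path)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "N": mask.pixel_count,
        "area_cm2": mask.area,
        "threshold": None if np.isnan(mask.threshold_used) else mask.threshold_used,
        "pixel_spacing_cm": mask.pixel_spacing,
    }
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=1))
    return summary


def read_mask(path, pixel_spacing: float, threshold_used: float = float("nan")) -> RoiMask:
    data = np.asarray(nib.load(path).get_fdata())
    return RoiMask(data[:, :, 0].T > 0.5, pixel_spacing, threshold_used)


# ---------------------------------------------------------------------------
# Waveform / sensor CSV
# ---------------------------------------------------------------------------


def write_waveform_csv(waveform: Waveform, path) -> None:
    pd.DataFrame(
        {
            "time_s": waveform.times,
            "value": waveform.values,
            "units": waveform.units,
        }
    ).to_csv(path, index=False)


def read_waveform_csv(path, period: float | None = None) -> Waveform:
    """Read a waveform CSV; the period defaults to n * median time step."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "value", "units") if c not in df.columns]
    if missing:
        raise SchemaError(f"waveform CSV is missing columns: {', '.join(missing)}")
    if len(df) == 0:
        raise InsufficientDataError(f"waveform CSV {path} has no samples")
    if period is None:
        dt = float(np.median(np.diff(df["time_s"].to_numpy()))) if len(df) > 1 else 1.0
        period = dt * len(df)
    return Waveform(df["value"].to_numpy(), period, str(df["units"].iloc[0]))


def write_sensor_csv(trace: SensorTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "dp_pa": trace.value}).to_csv(
        path, index=False
    )


def read_sensor_csv(path) -> SensorTrace:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "dp_pa") if c not in df.columns]
    if missing:
        raise SchemaError(f"sensor CSV is missing columns: {', '.join(missing)}")
    if len(df) < 2:
        raise InsufficientDataError(
            f"sensor CSV {path} has {len(df)} samples; at least 2 are required"
        )
    return SensorTrace(df["time_s"].to_numpy(), df["dp_pa"].to_numpy())


# ---------------------------------------------------------------------------
# Budget JSON
# ---------------------------------------------------------------------------


def _waveform_to_dict(w: Waveform) -> dict:
    return {"values": w.values.tolist(), "period_s": w.period, "units": w.units}


def _waveform_from_dict(d: dict) -> Waveform:
    return Waveform(np.asarray(d["values"]), d["period_s"], d["units"])


def write_budget_json(budget: MomentumBudget, path) -> dict:
    """Serialize a momentum budget (all waveforms at full float precision)."""
    report = {
        "schema_version": SCHEMA_VERSION,
        "cvmr_version": __version__,
        "mode": budget.mode,
        "scheme": budget.scheme,
        "geometry": {
            "diameter_cm": budget.geometry.diameter,
            "axial_length_cm": budget.geometry.axial_length,
            "cross_section_area_cm2": budget.geometry.cross_section_area,
        },
        "fluid": {
            "density_g_cm3": budget.fluid.density,
            "dynamic_viscosity_poise": budget.fluid.dynamic_viscosity,
        },
        "body_force_dyne": budget.body_force,
        "waveforms": {
            "flow": _waveform_to_dict(budget.flow),
            "inertial_force": _waveform_to_dict(budget.inertial_force),
            "momentum_inflow": _waveform_to_dict(budget.momentum_inflow),
            "viscous_force": _waveform_to_dict(budget.viscous_force),
            "pressure_force_cv": _waveform_to_dict(budget.pressure_force_cv),
            "up_gradient": _waveform_to_dict(budget.up.gradient),
            "up_inertial_part": _waveform_to_dict(budget.up.inertial_part),
            "up_viscous_part": _waveform_to_dict(budget.up.viscous_part),
            "up_force": _waveform_to_dict(budget.up.force),
        },
        "uncertainty": (
            None
            if budget.uncertainty is None
            else {
                "sigma_v_cm_s": budget.uncertainty.sigma_v,
                "sigma_q_cm3_s": budget.uncertainty.sigma_q,
                "sigma_inertial_dyne": budget.uncertainty.sigma_inertial,
                "scheme": budget.uncertainty.scheme,
                "notes": budget.uncertainty.notes,
            }
        ),
        "provenance": budget.provenance,
    }
    Path(path).write_text(json.dumps(report, indent=1))
    return report


def read_budget_json(path) -> dict:
    """Read a budget report back; waveforms are restored as Waveform objects."""
    raw = json.loads(Path(path).read_text())
    if "waveforms" not in raw:
        raise SchemaError("budget JSON is missing key: waveforms")
    raw["waveforms"] = {
        name: _waveform_from_dict(d) for name, d in raw["waveforms"].items()
    }
    return raw
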