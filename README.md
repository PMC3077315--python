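# cvmr

Non-invasive estimation of pressure-differential waveforms from
phase-contrast MR (PC-MR) velocity images by control-volume (CV) momentum
analysis — with a Womersley-flow synthetic phantom so the whole pipeline is
testable without a scanner.

## The problem

Pressure differentials drive cerebrospinal fluid flow, but the differences
between freely communicating intracranial spaces (tens of Pa or less) are
below the resolution of implantable sensors, and the sites are invasive to
reach. Gated through-plane PC-MR, by contrast, routinely measures the
velocity field crossing a slice. For a conduit control volume of
cross-section S and length L between two "taps", the integral momentum
balance

    F_I + (Ṁ_out − Ṁ_in) = F_B + F_P + F_V

links the measurable velocity data to the pressure force F_P on the CV. For
pulsatile flow at high Womersley number α = (D/2)√(ω/ν) in a short conduit,
the momentum-flux terms cancel, the body force vanishes for a static
horizontal CV, and viscous drag is small, so the balance collapses to

    F_P ≈ F_I = ρ L dQ/dt,

the inertial force computed from the volume-flow waveform Q^k = Σ v_i^k S_pix
over a segmented ROI. The package implements every term of the balance
discretely (flow, inertial, momentum flux, viscous drag, body force),
the per-pixel Navier–Stokes comparator of Urchuk & Plewes
(−dp/dz = ρ∂v/∂t − μ∇²v), measurement-noise propagation, magnitude-image
ROI segmentation, waveform statistics (phase/ensemble averaging, sinusoid
fits, normalized rms deviation), and a synthetic PC-MR generator driven by
the exact Womersley solution. See `docs/methods.md` for the estimators,
conventions and limitations.

## Worked example

The defaults reproduce the bench phantom: water in a 1.27 cm passage with
taps 3.81 cm apart, 46 mL/min sinusoidal flow at 1 Hz (Re ≈ 77, α ≈ 15.9),
imaged at 0.2 cm pixels, 17 gated phases, V_enc 20 cm/s, SNR 25.

```python
import math
import cvmr

flow = cvmr.from_flow_amplitude(46/60, cvmr.PHANTOM_GEOMETRY.radius,
                                2*math.pi, cvmr.WATER)
series = cvmr.wrap_velocity(cvmr.add_noise(
    cvmr.render_series(flow, cvmr.PHANTOM_ACQUISITION), snr=25.0, seed=1))
mask = cvmr.segment_series(series, threshold=0.60)
budget = cvmr.compute_budget(series, mask, cvmr.WATER,
                             cvmr.PHANTOM_GEOMETRY, snr=25.0)

fit = cvmr.fit_sinusoid(budget.flow, 1.0)
analytic = cvmr.Waveform(
    flow.pressure_force_waveform(cvmr.PHANTOM_GEOMETRY, series.timestamps),
    1.0, "dyne")
dev = cvmr.normalized_rms_deviation(budget.pressure_force_cv, analytic, "range")

print(f"ROI: N = {mask.pixel_count} pixels, area = {mask.area:.2f} cm^2")
print(f"flow amplitude (sinusoid fit): {fit['amplitude']*60:.1f} mL/min")
print(f"pressure force amplitude: {budget.pressure_force_cv.amplitude:.1f} dyne "
      f"(gradient {cvmr.force_to_gradient(budget.pressure_force_cv.amplitude, cvmr.PHANTOM_GEOMETRY):.2f} Pa/cm)")
print(f"sigma_Q = {budget.uncertainty.sigma_q*60:.1f} mL/min, "
      f"sigma_F = {budget.uncertainty.sigma_inertial:.1f} dyne")
print(f"deviation from analytic pressure force: {dev['percent']:.1f}% of range")
```

prints:

```text
ROI: N = 37 pixels, area = 1.48 cm^2
flow amplitude (sinusoid fit): 43.6 mL/min
pressure force amplitude: 17.9 dyne (gradient 0.37 Pa/cm)
sigma_Q = 5.3 mL/min, sigma_F = 4.0 dyne
deviation from analytic pressure force: 8.8% of range
```

Reading the numbers: segmentation at threshold 0.60 recovers the 37-pixel
(1.48 cm²) lumen ROI; the pixel-summed flow underestimates the true
46 mL/min amplitude by a few percent (spatial resolution plus noise); the
derived pressure force of ~18 dyne corresponds to a ~0.37 Pa/cm gradient
amplitude across the CV; σ_Q and σ_F are the noise uncertainties propagated
from σ_v = √2·V_enc/(π·SNR) = 0.36 cm/s; and the derived waveform deviates
from the exact analytic pressure force by ~9% of its range — noise,
resolution, and the viscous contribution the inertia-only estimate omits.

The same chain is available from the shell:

```sh
cvmr simulate --config config.yaml --seed 1 --out series
cvmr segment  --series series --out mask.nii
cvmr analyze  --series series --mask mask.nii --config config.yaml --snr 25 --out out/
cvmr report   --config config.yaml --seed 1 --out report/   # whole pipeline
```

where `config.yaml` carries `fluid {density, dynamic_viscosity}`,
`geometry {diameter, axial_length}` and `acquisition {fov, matrix, venc,
n_phases, period, slice_thickness}` in CGS units (see
`tests/test_compare_io.py` for a complete example).

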