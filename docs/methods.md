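# Methods

`cvmr` estimates the pressure-differential waveform across a conduit control
volume (CV) from gated through-plane phase-contrast MR (PC-MR) velocity
images, and ships a synthetic phantom — analytic oscillatory pipe flow
rendered as velocity/magnitude image series — so every estimator can be
validated against exact ground truth.

## Model and assumptions

For a fixed cylindrical CV of cross-section S = πD²/4 and axial length L,
filled with an incompressible Newtonian fluid, the integral axial momentum
balance reads

    F_I + (Ṁ_out − Ṁ_in) = F_B + F_P + F_V

with F_I the rate of change of fluid momentum in the CV, Ṁ the momentum
fluxes across the two flow-crossing surfaces, F_B the body force, F_P the
pressure force and F_V the viscous drag on the lateral surface. The package
assumes:

- fully developed axial flow (velocity profile independent of z over L), so
  the CV momentum is ρLQ(t) and F_I = ρL dQ/dt;
- a short conduit, so the inflow and outflow velocity profiles match and the
  net momentum-flux term is ~zero (the single-surface flux ρΣv²S_pix is
  still reported, as a check of that assumption);
- a static CV with horizontal axis: F_B = 0;
- rigid walls (no moving-boundary displacement term).

At high Womersley number α = (D/2)√(ω/ν) the viscous drag is small relative
to F_I and the balance collapses to **F_P ≈ F_I = ρL dQ/dt**: the pressure
force is read off the measured volume-flow waveform. This is the
"simplified" mode and the package default; "full" mode adds the momentum,
viscous and body corrections with documented signs.

## Discrete estimators

From a gated series v_i^k (pixel i, frame k, S_pix the pixel area) and a
static ROI of N pixels:

- **Flow**: Q^k = Σ_ROI v_i^k S_pix (flow into the phantom positive).
- **Inertial force**: F_I = ρL dQ/dt with a *periodic* temporal derivative —
  central difference by default, spectral (FFT) as an option. The central
  difference attenuates a single harmonic by sin(ωΔt)/(ωΔt) (2.3% at 17
  frames/cycle); spectral is exact for the single-harmonic driving used
  here but has a higher white-noise gain.
- **Momentum flux**: Ṁ^k = ρ Σ_ROI (v_i^k)² S_pix on the measured surface.
- **Viscous drag**: one-sided two-point normal differences at every exposed
  perimeter face, F_V^k = −μL Σ_faces (v_interior − v_perimeter) (the face
  length and the gradient spacing, both one pixel, cancel). Coarse grids
  under-resolve the O(R/α) oscillatory boundary layer, which is why F_V is
  *reported* but excluded from the simplified pressure estimate.
- **Comparator** (Urchuk–Plewes): per-pixel −dp/dz = ρ∂v/∂t − μ∇²v with a
  periodic central time difference and the 5-point Laplacian, averaged over
  ROI pixels whose full spatial stencil lies inside the ROI (no boundary
  extrapolation), then scaled by SL for comparison with CV forces.
- **Noise propagation**: σ_v = √2·V_enc/(π·SNR) (two-point PC-MR, high-SNR
  limit); σ_Q = σ_v S_pix √N for independent pixel noise; σ_F = ρLσ_Q g with
  g the derivative operator's white-noise gain (1/(√2Δt) central).

All internal computation is CGS; pascal appears only at reporting
boundaries (dyne/cm³ → Pa/cm is ×0.1, exact).

## Ground truth: oscillatory pipe flow

The simulator and the oracles use the exact solution for sinusoidally
driven laminar flow in a rigid circular pipe. With dp/dz = Re[K e^{iωt}],

    w(r,t) = Re[(iK/ρω)(1 − J₀(Λr/R)/J₀(Λ)) e^{iωt}],   Λ = i^{3/2} α,
    Q̂     = (iKπR²/ρω)(1 − 2J₁(Λ)/(ΛJ₀(Λ))),

with the i^{3/2} branch fixed to e^{i3π/4}. Flows are constructed from a
requested amplitude with the phase convention Q(t) = Q₀ sin(ωt). Two limits
serve as independent oracles: α→0 recovers quasi-steady Poiseuille flow
(|K| → 8μQ₀/πR⁴, centreline/mean → 2, drag → 8μLQ/R²), and α→∞ the
inertial regime (pressure amplitude → ρLωQ₀, leading the flow by 90°).

A point worth stating explicitly because it shapes the validation bounds:
the inertial limit converges slowly. The exact pressure amplitude is
ρLωQ₀/|F(α)| with F = 1 − 2J₁(Λ)/(ΛJ₀(Λ)), and |F| ≈ 1 − √2/α, so at the
phantom operating point (α ≈ 15.9) the true pressure force is ~8.8% *above*
ρLωQ₀. The simplified CV estimate, being inertia-only, inherits this
deficit by construction; the Urchuk–Plewes estimate does not (its viscous
part survives in the flat core, where ρ∂w/∂t equals the full gradient).
Likewise the two "inertial" estimates differ systematically at high α: the
CV one follows the bulk flow, the comparator's follows the core velocity;
they agree only in the limit where profile shape stops mattering.

## Synthetic phantom

The generator's defaults are the phantom experiment's conditions: water
(ρ = 1 g/cm³, μ = 0.01 poise) in a D = 1.27 cm passage with taps L = 3.81 cm
apart; sinusoidal flow of 46 mL/min amplitude at 1 Hz (Re ≈ 77, α ≈ 15.9);
25.6 cm field of view on a 128×128 matrix (0.2 cm pixels), 17 gated phases,
V_enc 20 cm/s, SNR 25. Frames sample the analytic solution at
t_k = kT/n_phases (no k-space simulation); pixels take the analytic
velocity at their centre (membership: centre strictly inside the lumen),
optionally a k×k sub-pixel average for partial-volume studies. Pixel-centre
sampling is the default because it reproduces the two characteristic ROI
sizes of the phantom bore on a 0.2 cm grid — 37 pixels (1.48 cm²) with the
lumen centre on a pixel centre, 32 pixels (1.28 cm²) on a pixel corner —
and the spatial-resolution error of the flow estimator. Noise is zero-mean
Gaussian on velocity (σ_v) and magnitude (1/SNR), the high-SNR limit of the
phase-difference statistics, not Rician channel noise. Velocities alias
into (−V_enc, V_enc]. The sensor emulator tiles a periodic pressure
waveform at a high sampling rate (5 kHz scale) with additive Gaussian
noise; phase averaging uses bins centred on the gated-frame times so traces
and image series align sample-for-sample.

What the phantom does *not* emulate: eddy-current/Maxwell phase errors,
gradient nonlinearity, slice misalignment, retrospective-binning artefacts,
wall motion. Tests passing on it therefore demonstrate correctness of the
estimators under ideal acquisition physics, not robustness to scanner
systematics.

## Numerical and design choices

- ROI segmentation is static: min–max-normalised magnitude (temporal mean
  by default; any single frame gives the identical result on noise-free
  fixtures), threshold 0.60, 4-connected component containing a seed pixel,
  perimeter = true pixels with a false 4-neighbour. No sub-pixel boundary
  refinement, consistent with pixel-centre flow summation.
- The spatial-resolution error of the flow estimator is quantified as the
  mean over gated frames of |Q_pix − Q_analytic|/|Q_analytic|, excluding
  frames where the analytic flow is exactly zero (the t = 0 frame of a
  sine, where a relative error is undefined). At the default conditions
  this is 4.7%; the related amplitude deficit is 5.0%.
- Waveform comparisons report rms deviation under two normalisations, by
  the reference's range (default) and by its peak amplitude; both are named
  in reports since they differ by ~2× for zero-mean cycles.
- Degenerate inputs fail loudly: empty or multi-component ROIs, masks too
  thin for a stencil, traces shorter than two cycles, Bessel overflow at
  extreme α (beyond α ≈ 1000), zero-range references.
- Problem sizes in the test-suite oracles: fine-grid closed-form checks use
  0.0125–0.02 cm grids (160–256 px matrices) and 3–64 phases; noise
  calibration pools residuals over ~10⁵–10⁶ pixels or 120 seeded
  realizations, sized so sampling error sits well below the asserted
  tolerances.

## Known limitations

- Single-harmonic driving only; multi-harmonic waveforms would need the
  solution summed over harmonics.
- One measured slice: "full" mode assumes the opposing surface carries the
  same momentum flux rather than measuring it.
- The viscous-drag estimator is first-order and biased low on coarse grids
  at high α; it is diagnostic, not corrective, at scanner resolution.
- The simplified pressure estimate carries the irreducible ~√2/α viscous
  deficit described above (~9% at α = 16) in addition to resolution error;
  at scanner resolution its amplitude sits ~12–14% below the exact pressure
  force while the Urchuk–Plewes route sits within ~1–3%.
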