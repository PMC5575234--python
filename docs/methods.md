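# Methods

This note records the models, parameter choices and numerical decisions
behind `cryoptycho`, and what the desk-scale studies do and do not show.

## Geometry and conventions

All arrays are row-major with index (0, 0) top-left; scan positions are
integer pixel offsets of the probe patch's top-left corner (sub-pixel
positions are out of scope). Every Fourier transform is unitary
(`norm="ortho"`), so Σ|ψ|² is an electron count in both domains and the
far-field intensity of an exit wave integrates to the exposure's
electrons. The electron wavelength is the relativistic de Broglie value,
λ = hc/√(E(E+2m₀c²)) — 1.969 pm at 300 keV — and the image sampling is
r_d = λΔz/(N_pix·d_pix).

The reference configuration is 300 keV with a 128² detector binned so
r_d = 1.7 Å. The detector side length is an inference, not a measured
value: it is chosen so that ~8500 electrons per pattern at 20 e⁻/Å²
correspond to ~0.52 e⁻ per detector pixel. Note an internal tension in
the published optics: at r_d = 1.7 Å and 300 keV the detector's angular
Nyquist limit is 5.79 mrad, so a 9.2 mrad probe-forming aperture cannot
be represented on that grid. Probe constructors therefore raise when the
aperture exceeds Nyquist; the default simulation aperture is 4.5 mrad
(the angular scale of the published probe gallery), and a 9.2 mrad probe
requires a finer pixel size (≤ ~1.07 Å). Relatedly, a "roughly 3 nm"
scan step at 20 e⁻/Å² implies ~6200 e⁻/pattern, not 8500; the package
reports the budgets of its actual configuration instead of forcing
agreement.

## Probes

All probes are built in the aperture plane and focused by the lens
transform (unitary inverse FFT), so a probe's far field is exactly its
aperture field and the aperture invariant (zero Fourier amplitude beyond
the half-angle) holds by construction.

* **Defocused**: aperture disc times the quadratic phase χ(q) = πλΔf q²;
  default Δf = 400 nm. Its real-space support diameter tracks the
  geometric estimate 2·Δf·α within 20%.
* **Fresnel zone plate**: a binary (0/π) plate equals a perfect lens
  times a sawtooth residual phase in [0, π); the aperture carries that
  residual (8 zones across the aperture by default, a free parameter)
  plus the defocus chirp for the stated distance from focus. The
  first-order focal efficiency (2/π)² ≈ 40% emerges from the residual's
  mean phasor rather than being imposed.
* **Randomized**: a uniform-random phase screen on the aperture grid,
  Gaussian-smoothed with a configurable correlation length (default 4
  pixels; the published gallery constrains but does not determine these
  statistics) and rescaled to a standard deviation of π. For correlation
  lengths well below the aperture diameter the focused intensity is
  fully developed speckle (contrast ≈ 1).

Probe support is the pixel set above 1% of peak intensity; the scan step
solves the circle–circle lens-area equation for the requested fractional
*area* overlap of the circular-equivalent support (75% default), rounded
to whole pixels.

## Specimen models

The phantom is a compact cluster of Gaussian pseudo-atoms (projected
phase peak 0.3 rad by default — a free display-range choice) on a weakly
fluctuating ice background, with amplitude exp(−t/2Λ) from the inelastic
mean free path (ice 320 nm, protein 270 nm at 300 keV, thickness 50 nm),
giving the minimal amplitude contrast typical of frozen-hydrated
specimens. Pseudo-atoms replace physically parameterized scattering
factors deliberately: the package's claims are algorithmic (recovery,
metrics), not biophysical. External volumes load from mode-2 MRC files
(slices along z; in-plane voxel size must match r_d).

Thick specimens are simulated by multislice: per slice, transmission
exp(iσV_re·dz − V_im·dz) with the energy-dependent interaction constant
σ, band-limited to 2/3 Nyquist (the standard anti-aliasing convention;
the transmission, not the propagator, is band-limited so that free-space
propagation stays exactly unitary), then Fresnel propagation over the
slice thickness. The *reconstruction* forward model is always the
thin-object product — specimen thickness is negligible at the
resolutions reached here — and the imaginary potential is a per-slice
amplitude attenuation in 1/Å.

## Detector

Detection per pattern: multiply the intensity's Fourier transform by
√DQE (negative ringing clipped at zero), draw Poisson counts, filter by
NTF. Radial DQE/NTF tables over fractional Nyquist are bundled as
editable CSVs shaped like a counting direct detector; published curves
for any specific camera can be dropped in. The reconstruction path uses
the identity response: with heavy binning DQE is near-constant and NTF
near unity. Each pattern draws from an independent `(seed, index)`
stream, so detection is reproducible pattern-by-pattern. Dose
calibration assigns dose × (step·r_d)² electrons to the mean pattern —
the dose share of one scan cell — and the study recipes also rescale the
probe to that budget so that model intensities for |T| ≈ 1 live on the
counts' scale; without this the iterate must absorb a large global
amplitude and the likelihood geometry degrades.

## Reconstruction

The Poisson negative log-likelihood Σ[I_i − y_i log I_i] is minimized
with Polak–Ribière nonlinear CG on the Wirtinger gradient
2P†[(1 − y/I)(PT)], assembled via the operator adjoint (adjointness is
tested to 1e-8; gradients match finite differences to 1e-5). Model
intensities are floored at 1e-12 of their nonzero mean inside logs and
divisions. The Armijo backtracking line search only accepts
non-increasing steps, restarting along steepest descent when a conjugate
direction fails, so the objective trace is non-increasing between
denoiser refreshes. Stopping: relative objective change below `rel_tol`
or `max_iters`.

**Priors.** The Tikhonov penalty (μ₀/κ)‖∇T‖² uses forward differences
with replicate boundaries and the true adjoint-difference gradient
(the compact printed form of the gradient omits the adjoint operators
and is not the derivative of the penalty). Its scale κ = 8N_pix²/(N_m‖I‖₁)
is implemented as published, but note that at desk-scale problem sizes
μ₀ = 1e-2 then weights the penalty far above the likelihood and flattens
the iterate — μ₀ must be treated as a free parameter per configuration.
The sparse prior μ₁‖T − T_sparse‖² (gradient 2μ₁(T − T_sparse); the
factor 2 keeps gradient/objective consistency) pulls toward a denoised
reference refreshed every 10 iterations (configurable): the complex
field is domain-colored (phase→hue centred at 0.5, amplitude→value,
saturation 1), each channel denoised, and mapped back. The bundled
denoiser is BayesShrink wavelet soft-thresholding with a biorthogonal
spline wavelet (`bior2.2`); heavier collaborative-filtering denoisers
such as BM3D plug in through `register_denoiser`.

**Truncation.** Measurement i is retained iff
|y_i − I_i| ≤ (α_h/KM)‖y−I‖₁·|p_i T|/‖T‖₂ (α_h = 5 default). The rule is
implemented exactly and verified against brute force, but an empirical
caveat is documented: electron diffraction patterns are strongly peaked,
and the |p_i T|-proportional bound permanently discards dark-field
pixels — at these problem sizes 30–50% of measurements are dropped even
at the ground truth, and CG stalls from a random start. The study
recipes therefore run with truncation disabled (α_h = ∞); the rule
remains available for configurations closer to its Gaussian-measurement
origins.

**Initialization.** Random: |T| = 1, phase ~ Normal(0.1, variance 0.1).
Spectral: power iteration on the object-space operator
(Q†Q)⁻¹Q†F†·M·FQ, where M keeps the intensities above the 80th
percentile (exactly ⌈0.2·KM⌉ entries) and (Q†Q)⁻¹ is the pointwise
inverse of the summed probe intensity, floored at 1e-6 of its maximum.
Without the mask this operator is exactly the orthogonal projection onto
range(FQ), so all phase information enters through the mask — which is
why the method needs high counts (it is only reliable around
100 e⁻/Å² and above; the package defaults to random initialization).
The returned object is unit-amplitude with the eigenvector's phase.

Because several gauge-equivalent solutions exist (global phase always;
global complex scale when the probe normalization is unknown), no gauge
is fixed during iteration and every comparison aligns a global scalar
first: full complex scale for SNR/NRMSE, phase-only for dataset
averaging (the least-squares scale estimator is biased toward zero on
noisy fields and would cap ensemble gains).

## Study recipes and their scale

`workflows.py` runs the studies at sizes chosen for a single CPU: a 32²
detector patch at r_d = 1.7 Å, 64² objects (96² for the dose series,
where finer low-frequency ring sampling is needed to order 5 vs 20
e⁻/Å²), 200 CG iterations, three random starts with the lowest final
objective kept (the objective is non-convex; occasional poor stationary
points are real). Evaluation uses the central half of the field — the
border of a ptychographic field of view is weakly constrained — and the
FRC/SNR ground truth is the phantom's *phase* image, since complex-field
correlations are dominated by the flat transmission background. The
specimen phantom is a fixed study condition; seeds vary probe, noise and
initialization.

Scan grids are randomized per dataset (random origin plus ±step/3
jitter): a strictly periodic raster imprints an artifact at the scan
frequency that is *shared* between independent datasets and survives
averaging, capping the split-half FRC. The probe-design comparison is
the exception and uses the periodic raster: the defocused probe's
low-frequency SNR deficit comes from low data diversity between
neighbouring positions, which jittering would partly mask.

What passing these studies shows: correct likelihood/gradient/operator
machinery, dose-calibrated Poisson statistics, and the expected
qualitative orderings (resolution improves with dose; speckled and
zone-plate probes beat a plain defocused probe at low spatial
frequencies; pooling independent datasets improves split-half
resolution). What they do not show: performance on real micrographs —
the phantom has no solvent amorphousness, no beam-induced motion, no
energy-filter distortions, no probe miscalibration (the probe is assumed
known throughout), and pseudo-atom contrast rather than tabulated
scattering potentials.

## Known limitations

* The truncation rule and the printed Tikhonov scaling both behave
  poorly at desk scale (see above); they are faithful implementations
  with documented caveats, not the study defaults.
* FRC first-crossing resolution is bistable when the curve hovers near
  threshold at low rings; medians over ≥5 independent datasets are
  reported for that reason.
* Sub-pixel scan positions, probe retrieval, partial coherence,
  position refinement and 3D reconstruction are out of scope.
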