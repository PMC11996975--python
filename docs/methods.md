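# Methods

`ctiq` measures the frequency-resolved image quality of CT systems from
phantom acquisitions — the task transfer function (TTF), the noise power
spectrum (NPS), the slice sensitivity profile (SSP) — and combines them
into an ideal-observer detectability index d′ and a system performance
function SPF(f) = TTF²(f)/NPS(f). A synthetic phantom generator with
fully parametric ground truth makes every estimator testable by
parameter recovery. This note records the models, the estimator choices,
and the known limits of both.

## The phantom and its synthetic emulation

The physical setup emulated is a 300-mm water bath (an adult-abdomen
absorber) imaged on a 512×512 grid with a 300-mm display field of view
(pixel pitch Δ = 0.586 mm) and 1.0-mm nominal slices. Three sections are
used: a uniform water section (NPS), a two-rod section with 30-mm
iodine-equivalent rods at ±50 mm from the center (TTF and task
contrast), and a 70-mm central rod whose top surface is tilted ≈5°
against the image plane (SSP). Voxel centers sit at (i+0.5)·Δ with the
origin at the volume corner; all positions are in mm, all CT numbers in
HU.

### Ground-truth models

* **MTF** — Gaussian, parameterized by its 50% frequency f50:
  MTF(f) = exp(−f²/2σ_f²), σ_f = f50/√(2 ln 2). The equivalent spatial
  PSF is Gaussian with σ_s = 1/(2π σ_f).
* **NPS** — flat (white, level N0 in HU²·mm²) or "ramp × low-pass":
  NPS(f) = peak · (f/f_p) · exp[(1 − (f/f_p)²)/2], which rises linearly
  from zero, peaks at f_p and rolls off beyond — the generic shape of a
  filtered-backprojection noise spectrum. Default peak frequency
  ≈ 0.2 mm⁻¹, typical of a body kernel on this grid.
* **SSP** — Gaussian or rectangular, parameterized by FWHM (mm).

### Synthesis

Blurred axial sections are synthesized in closed form: each disk's
analytic Fourier transform (πR²·2J₁(2πRf)/(2πRf), phase-shifted to its
center) is multiplied by the MTF and inverse-transformed at the voxel
centers. Voxels are therefore exact point samples of the blurred object
band-limited to the grid, and the stack's end-to-end in-plane transfer
equals the configured MTF — there is no pixel-aperture term and no
rasterization error. Against a continuous-domain oracle (the
disk⊗Gaussian Rice integral) individual edge voxels agree to ≈0.6 HU
(the out-of-band tail a sampled grid cannot carry, MTF(f_Nyq) ≈ 0.05)
and radially binned edge profiles to <0.2 HU. Two alternatives were
evaluated and rejected: carrying the pixel-aperture sinc (it shifts a
truth f50 of 0.41 to ≈0.385, so the generator's truth would not be what
its own estimator measures), and supersampled boolean rasterization with
an aperture-compensated filter (its ±1/32 area-quantization leaves
orientation-dependent edge errors up to 13 HU). With no blur configured
(MTF ≡ 1) the geometry is instead rasterized at 4× and block-averaged,
so edge voxels carry exact area-coverage fractions.

Noise is stationary, Gaussian and independent across slices: a white
field is shaped by √(NPS/(ΔxΔy)) in the frequency domain, which makes
the ensemble 2D periodogram converge to the model exactly and gives
variance = N0/(ΔxΔy) for a flat spectrum. Real CT noise is neither
stationary across the FOV nor uncorrelated along z; both
simplifications are deliberate, and consequences are noted under
Limitations.

The tilted-rod volume evaluates the SSP's edge response analytically
along z (each slice sees ΔHU · C(z_edge(y) − z), C the SSP's integral),
with the edge plane advancing by tan(tilt) per mm of lateral offset,
then applies the in-plane blur per slice and adds noise.

### Default study conditions

The two simulated arms emulate a photon-counting system ("PCD", the
slice-thickness reference) and a dual-source dual-energy system
("DECT") at 70 and 40 keV virtual monoenergetic levels and doses of 15,
7.5 and 3 mGy. Where the source study prints measured values they are
used as truth set-points: the 40-keV f50 sequence (PCD 0.41/0.39/0.31,
DECT 0.34/0.29/0.25 mm⁻¹ by dose) and all twelve SSP FWHMs (e.g. PCD
1.26 mm vs DECT 1.43 mm at 40 keV, 15 mGy). Values the study does not
print are package choices, made once:

* Rod contrasts: 600/100 HU at 40 keV and 216/36 HU at 70 keV for the
  12 and 2 mgI/mL rods — iodine enhances by roughly 50 HU per mgI/mL at
  40 keV and 18 HU per mgI/mL at 70 keV. (Contrasts several-fold lower
  would make the low-contrast edge unmeasurable under the CNR ≥ 20
  repeat-averaging protocol the TTF method requires.)
* Noise levels: NPS peak 600 (PCD) / 1000 (DECT) HU²·mm² at 40 keV and
  140/150 at 70 keV at the 15-mGy reference, i.e. single-scan noise of
  roughly 18–23 HU at 40 keV; noise power scales as 1/dose.
* 70-keV f50s: plausible near-kernel values (0.38–0.42 mm⁻¹), slightly
  favoring the PCD arm.
* Repeat-scan counts follow the study design: 5/8/12 (PCD) and 6/11/14
  (DECT) for 15/7.5/3 mGy.

## Estimators

### TTF (circular edge)

The rod center is refined to subpixel accuracy (intensity-weighted
centroid of the half-contrast mask). Every pixel in a ±5-mm annulus
around the nominal edge radius contributes a (distance, HU) pair; pairs
are averaged in bins of 0.1 pixel, giving an edge spread function
oversampled ≈6× relative to the pixel pitch (≈170 populated bins). The
LSF is the central finite difference; a Hann window centered on the LSF
peak suppresses noise in the tails before the DFT; TTF = |DFT(LSF)|
normalized at zero frequency, reported to the in-plane Nyquist
(0.853 mm⁻¹). f50 is the first downward 0.5 crossing, linearly
interpolated.

The window width is 16× the LSF's FWHM (≈17 mm for these blurs,
effectively a gentle taper over the whole annulus). A tighter 8× window
was measured to clip genuine LSF wings, biasing a 0.41 mm⁻¹ truth f50
to 0.428; at 16× the noiseless bias is +0.005 and noisy recoveries
(8-scan averages, CNR ≈ 34) scatter 0.416 ± 0.005. Windowing and the
window width are config-exposed; with `window="none"` the noiseless
estimator matches the truth MTF binwise to 0.005.

Magnitude spectra are noise-floor biased: |S + N| ≥ |S| in expectation.
At edge CNR below ≈10 the floor can exceed half the zero-frequency
value and f50 becomes undefined (the estimator raises). This is why the
procedure prescribes CNR ≥ 20 via repeat averaging; the estimator warns
(`LowCNRWarning`) below 20.

### NPS (ROI ensemble)

Four 128-px ROIs on a 50-mm circle per slice, 50 consecutive slices
(200 ROIs). Each ROI is detrended (2nd-order 2D polynomial by default;
mean subtraction available) and its scaled periodogram
(ΔxΔy/N²)|DFT₂|² accumulated; the ensemble 2D NPS is radially rebinned.
Parseval's identity (ΣNPS·Δf² = detrended variance) holds to machine
precision per ROI.

Radial rebinning choices, each made for estimator accuracy and
config-exposed:

* **Bin width 2Δf ≈ 0.027 mm⁻¹** (Δf = 1/(128Δ)). At Δf the lowest bin
  pools only ~4 independent Fourier cells — ~3.5% relative sd even at
  200 ROIs; at 2Δf it pools ≥12.
* **Bins are reported at the mean frequency of their contributing
  cells**, which removes the assignment bias of nominal bin centers.
* **The fx = 0 and fy = 0 axis lines are excluded** (standard CT-NPS
  practice): detrending residue and window leakage concentrate there.

Two periodogram configurations exist. The plain (rectangular-window)
periodogram is the default and matches established practice, but its
Fejér sidelobes leak ≈0.3% of the spectral peak across the whole band:
bins where the true spectrum is below a few percent of peak (the lowest
bin of a ramp spectrum, or a deep high-frequency roll-off) are biased
high by 10% and more. `taper="hann"` (power-normalized) suppresses the
leakage to negligible levels at the cost of ≈2× coarser spectral
resolution and is the configuration used for parameter-recovery
validation. Even then, the first radial bin of a ramp spectrum carries
a few-percent positive bias — the window's frequency smoothing at the
conical |f| vertex (E|f + jitter| > |f| near the origin) — and its
variance is inflated because the four 75-mm ROI windows of one slice
overlap spectrally at wavelengths of 40–75 mm, so the effective low-f
ensemble is ~50, not 200. Recovery validation therefore averages
estimates over 5 independent acquisitions: seed-averaged recovery is
0.9% (flat) and 4.5% (shaped) max binwise below 0.8·Nyquist.

### SSP (slant edge)

A ≈30-mm sagittal slab is averaged around the rod center; the tilt is
fitted from the half-maximum z locus regressed on lateral position
(agrees with the configured angle to <0.05° noiseless) unless supplied.
Each lateral column's profile is shifted by −tan(tilt)·(y−y₀) and
pooled into bins of Δz/4, yielding a z-ESF sampled at 0.05 mm for the
0.2-mm slice spacing; sparse extreme bins (fed by single columns) are
dropped. The SSP is the derivative, boxcar-smoothed over one native
slice spacing, peak-normalized; the FWHM comes from the outermost
half-maximum crossings (linear interpolation). The boxcar preserves a
rectangular profile's FWHM exactly and widens a Gaussian's by <1%;
without it the max-over-noisy-bins normalization biased FWHM low by
≈0.02 mm and crossings jittered ±0.04 mm even after 8-scan averaging.
Crossings clustered within 30% of the width on one flank are treated as
noise jitter; a wider spread raises a multi-modality error. Recovery at
the 1.26-mm set-point (5° rod, Δz = 0.2 mm, 8 scans averaged at the
15-mGy noise level): 1.26 ± 0.02 mm; noiseless, 1.274 (the +0.014 being
the smoothing and binning widening).

### Slice-thickness NPS correction, d′ and SPF

Image noise variance scales inversely with slice thickness, so before
comparing systems the NPS of the thicker-slice system is scaled up by
factor = FWHM_other/FWHM_reference (>1; the reference arm has factor
1.0, and the factor is frequency-independent under the variance ∝
1/thickness model). The detectability index is

    d′² = 2π ∫ f · TTF²(f)/NPS_c(f) · W²(f) df

with the disk task function W(f) = (π/2)|ΔHU| d² J₁(πdf)/(πdf)
(W(0) = π|ΔHU|d²/4 by the small-argument limit), d = 5.0 mm tasks at
the two iodine contrasts, and ΔHU measured from 25×25-px ROIs averaged
over 10 consecutive images. Both curves are linearly interpolated onto
a uniform 512-point grid from 0 to f_max (default: the common extent of
the measured curves, ≈ Nyquist); the integrand vanishes at f = 0 so the
NPS DC bin never enters; trapezoidal quadrature. Against the flat-NPS
closed form d′ = |ΔHU|(d/2)√(π/N0) the default grid is accurate to
≈0.4% over the measurement band; wide-band integrals (f_max ≫ Nyquist)
need a proportionally denser grid to resolve the jinc oscillations.
SPF(f) = TTF²/NPS_c and SPF² are attached on the same grid (DC
omitted). Exact scaling laws hold by construction: d′ linear in |ΔHU|,
d′ → d′/√k when NPS → k·NPS, SPF → SPF/k.

Outside the curves' support the end values are held constant (relevant
only below the first NPS bin, 0.015 mm⁻¹, where the integrand weight
f·W² is already small).

## Pipeline and report

`run_comparison` executes the whole design per arm × energy × dose:
simulate repeat rod scans → average → TTF per rod and ΔHU; simulate the
water section → NPS; simulate (or take from config) the tilted rod →
SSP FWHM; then correction factors against the reference arm, d′ and
SPF² per task, and the comparison tables — FWHM ratios rounded
half-up to two decimals and d′ percentage increases to one decimal, as
the source tables print them. Every random stream derives from
(seed, arm, energy, dose, stage, repeat), so reports are bit-identical
under a fixed seed, and every derived cell is recomputable from the
primary cells it sits next to. Increases are always recomputed from
full-precision d′, not from rounded table entries (recomputing from
rounded entries changes some cells by 0.1–0.3 points).

Problem sizes are configurable; the validation suite runs the NPS
protocol at full size (4×128 px × 50 slices), TTF recovery with 8-scan
averaging × 10 seeds, SSP with 8 averaged scans, and the 40-replicate
two-arm dominance study with 5 NPS slices and 4 pooled TTF slices per
replicate.

## Known limitations

* Stationary Gaussian noise: no FOV-dependent noise texture, no
  streaks, no z-correlation. Recovery results bound estimator error
  under ideal stationarity only.
* The generator's MTF is isotropic and contrast-independent; measured
  per-rod TTFs differ only through noise, whereas real low-contrast
  TTFs can differ systematically (dose- and contrast-dependence of
  nonlinear reconstruction is out of scope, as are scanner kernels and
  spectral physics).
* Band-limited synthesis cannot carry out-of-band content; per-voxel
  agreement with a continuous-domain oracle saturates at ≈0.6 HU for
  the default blur.
* The plain-periodogram NPS is biased where the spectrum is below a few
  percent of its peak (leakage floor); use the tapered configuration
  when that region matters.
* The FWHM-ratio NPS correction assumes noise variance ∝ 1/thickness
  exactly and frequency-independence; both are approximations for
  helical reconstruction.
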