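# Methods

This note records the models, estimator choices, defaults and known
limitations of `ctiq`, in the spirit of a physics-methods appendix.

## Synthetic phantom

A slice is a uniform background (default −100 HU, polyethylene-like) with a
circular insert (default +350 HU, iodine-solution-like; 25 mm radius) on a
512×512 grid at 0.390625 mm/pixel (200 mm field of view), i.e. a Nyquist
frequency of 1.28 mm⁻¹.  The insert must fit inside the image with a margin
of 10% of the image width.

**Blur.** Either an isotropic Gaussian PSF of standard deviation σ (mm) or a
tabulated radial MTF.  For the Gaussian case the blurred circular edge is
written in closed form as a radial complementary-error-function profile,
exact up to the disk-curvature term of order σ²/(2R); at the default scales
(σ ≤ 0.8 mm, R = 25 mm) that term is ≤ 1% of the contrast, and the test
suite cross-validates the closed-form path against the frequency-domain
(tabulated-MTF) rendering path at exactly this tolerance.  Pixels sample the
continuous profile at their centers; area averaging is omitted because its
effect is second-order at these blur scales.

**Noise.** Stationary Gaussian noise, colored in the frequency domain: the
DFT of unit white noise is multiplied by the square root of the target power
spectrum and inverse transformed, giving the exact target spectrum in
expectation on the periodic grid.  Spectral shapes: `white` (flat),
`ramp_bandpass` (f·e^{−f/f₀}, a single-peaked spectrum with its mode at the
configurable peak frequency f₀, mimicking filtered-back-projection noise
texture), and `tabulated_nps`.  The field is scaled so the pixel variance
equals the configured value exactly in expectation.  Slices get independent
sub-seeds spawned from the model seed; identical parameters and seed give
bit-identical stacks.

**Patient size.** Emulated purely as a noise-variance multiplier
(small/medium/large = 1×/2×/4× by default); noise texture is left unchanged,
matching the empirical observation that attenuation scales noise magnitude
with little texture change.  The demo configuration overrides the
multiplier with explicit per-size variances for its test system (see below).

What the simulator does **not** emulate: projection/reconstruction physics
(no sinograms, no reconstruction-kernel correlations beyond the imposed
spectrum), beam hardening, scatter, non-stationarity across the field of
view, spectral (multi-energy) channels, or z-direction correlations.
Passing recovery tests therefore demonstrates estimator correctness on
stationary, isotropic data — not robustness to every artifact of real
scanner images.

## NPS estimation

Square background ROIs (default: four 100×100 ROIs per slice at the
cardinal positions midway between insert edge and image edge) are plane
detrended (least-squares first-order 2D polynomial — removes slow background
inhomogeneity without biasing mid frequencies), DFT'd, modulus-squared,
scaled by (pixel area / pixel count) and ensemble averaged.  No apodization
window is applied; after detrending this is standard CT-NPS practice and a
window would bias the magnitude integral.  The radial average uses annular
bins of width equal to the 2D frequency sample spacing 1/(roi·Δx), centered
at integer multiples of it, so the DC sample has its own bin; empty bins
are dropped.

The peak frequency is the bin-center of maximum amplitude after a 3-bin
moving average, excluding the DC bin (near-zero content reflects large-scale
inhomogeneity, not noise texture); ties break toward the lower frequency.
Note the ramp_bandpass spectrum is intentionally flat around its mode
(±1 bin changes the density by < 1%), so the recovered peak is reproducible
to about one radial bin at a few hundred ROIs — parameter-recovery checks
are therefore stated relative to the nearest representable bin center.
The noise magnitude is the trapezoidal integral of the 1D radial curve
(exactly as defined for the comparison statistic — not the 2πf-weighted
variance integral; the variance consistency check uses the 2D integral
separately, where Parseval holds to within the three detrend degrees of
freedom).

## TTF estimation

Circular-edge method.  The insert center is the centroid of the
half-amplitude level set of the normalized (slice-averaged) image, refined
with soft weights — accurate to well under 0.1 pixel on synthetic data.
The insert radius defaults to the stack's ground-truth metadata or, absent
that, to the area-equivalent radius of the half-amplitude region; a radius
bias only shifts the ESF origin (a pure phase), which the Fourier modulus
discards.

Pixels inside a 68 mm crop and within ±6 mm of the edge are assigned to
overlapping angular sectors (default 15° aperture stepped by 10° → 36
sectors) and pooled over slices; radial distances are binned at 0.1 pixel
(0.039 mm) with bin-mean aggregation.  Sectors averaging fewer than 10
samples per bin raise an error — in practice this sets a minimum slice
count (≈ 6 slices at the default geometry).  The ESF is resampled to a
uniform grid, differentiated by central differences, windowed with a Hann
window of 5 mm half-width centered on the LSF peak (wide relative to all
blur scales used), zero-padded and Fourier transformed; the modulus is
normalized at zero frequency and truncated at the image Nyquist frequency.
No sinc correction is applied for binning/differentiation: at a 0.039 mm
bin the correction is < 1% below 1.3 mm⁻¹, a documented small bias (the
end-to-end Gaussian recovery bias is ≈ +1.5% on f50/f10).  Sector TTFs are
averaged in the frequency domain and renormalized; TTF50/TTF10 use the
*first* downward level crossing with linear interpolation, which makes
noisy non-monotone tails harmless.  With heavy noise and few slices the
rectified LSF tail can keep the TTF above 0.1 everywhere; the f10 read-off
then raises an out-of-range error rather than returning a fabricated value
— pooling more slices is the remedy.

## NPWE observer

The detectability index is the radial-integral form stated in the README,
evaluated by the trapezoid rule on 2048 uniform frequencies in [0, fNy]
(doubling the grid changes d′ by < 0.1%); TTF and NPS are interpolated
linearly with constant extrapolation, and negative interpolated NPS values
are clipped to zero with a warning.  The disk spectrum uses the analytic
limit πr² at f = 0.  Task sizes are interpreted as diameters (r = size/2);
the default battery holds six high-contrast (450 HU, configurable to
400 HU) and six 30 HU tasks at diameters 0.5–3 mm.  A half-disc lesion
geometry is not modelled; the disk transform is used for all tasks.

**Eye filter.** V(u) = u^a e^{−cu²} with u in cycles/degree, defaults
a = 1.3 and c = a/(2·4²) so the response peaks at 4 cyc/deg, normalized to
unit maximum; viewing geometry: cycles/degree = f_image / zoom ×
(D·π/180) with D = 500 mm viewing distance and zoom = 1.5.  These are the
conventional parameters of the CT-detectability literature, pinned for
reproducibility and fully configurable; `enabled=False` gives the plain
NPW observer used for closed-form checks.

**Normalization convention.** The radial-integral index carries a prefactor
2π with no 2π inside the denominator root.  Radializing the 2D-integral SNR
of the exact linear template observer gives (2π·I_num)/√(2π·I_den), so the
index exceeds the simulated observer's decision-variable SNR by the
constant √(2π) ≈ 2.507 for *every* task.  The package keeps the
radial-integral form as its quoted d′ (all comparative statistics — ratios,
shifts, orderings — are invariant to the constant) and the Monte-Carlo
oracle reports both its empirical AUC and its empirical SNR, which the test
suite ties to the analytic index through exactly this constant.  Absolute
AUC values derived from the quoted d′ via Φ(d′/√2) inherit the convention
and overstate the simulated observer's AUC; comparisons between systems do
not.

**Monte-Carlo oracle.** Signal-present images are the disk blurred through
the TTF plus noise shaped to the NPS on a 128² grid (256² available);
signal-absent images are independent noise; the template (expected signal
filtered by VTF²) is applied as a cross-correlator at the known location.
AUC is the rank-based Mann–Whitney statistic with a Hanley–McNeil standard
error.  Everything is linear-Gaussian, so the oracle validates the entire
simulation + estimation chain; residual grid-discretization bias at 128² is
below half a percent of d′.

## Pipeline and demo configuration

A study grid is systems × sizes; each condition is simulated (or loaded),
measured (NPS, TTF), and scored (12-task d′ battery using the *measured*
curves), deterministically: per-condition seeds are derived from the base
seed and the condition labels, and CSV outputs are byte-stable.  Every CSV
carries a header with a hash of the canonicalized configuration.

The shipped demo uses 48 slices per condition — enough for stable NPS and
TTF curves at the demo's contrast-to-noise ratios while keeping a full
6-condition run in the tens of seconds.  The "EID-like" system has Gaussian
blur σ = 0.60 mm and ramp noise peaked at 0.285 mm⁻¹ with per-size
variances 100/200/400 HU²; the "PCD-like" system has σ = 0.60/1.35 mm
(f50 exactly 35% higher), peak 0.44 mm⁻¹, and variances 91/134/248 HU²
(−9/−33/−38% relative).  These settings are *illustrative*: absolute
image-domain noise levels of real systems are not publicly fixed, so the
demo is designed to reproduce the qualitative sign/ordering structure of a
photon-counting vs energy-integrating comparison (positive NPS-peak and TTF
shifts, negative magnitude reduction, uniformly higher d′, d′ falling with
patient size), not any particular scanner's absolute numbers.

## Degenerate inputs and numerical guards

Zero noise variance: all-zero fields; the NPS peak is then undefined (NaN in
pipeline summaries) and the detectability stage raises a division error
(d′ diverges; the guard triggers when d′ would exceed 10¹², i.e. the NPS
carries only round-off).  ROIs are rejected if they leave the image or
touch the insert.  Sector ESFs with sparse bins, all-constant images at
center detection, levels outside (0, 1), and empty task batteries or curve
sets all raise typed errors rather than returning silent defaults.

## Problem sizes used in the checks

Recovery and identity checks run at: 400 ROIs (Parseval, white-noise
level), 428 ROIs = 107 slices × 4 (noise-peak recovery), 8 noiseless slices
× 36 sectors (blur recovery), 5000 trials at 128² (Monte-Carlo), and the
full 48-slice × 6-condition demo.  These sizes give estimator noise well
inside the stated tolerances (e.g. NPS curve recovery ≈ 1% mean absolute
relative deviation over [0.1, 0.9·fNy]).
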