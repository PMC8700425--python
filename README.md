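# ctiq — task-based CT image quality

`ctiq` measures the image-quality triad used to compare CT systems on
detection tasks: the **noise power spectrum** (NPS), the **target transfer
function** (TTF, the contrast-dependent MTF measured on a circular insert
edge), and the **non-pre-whitening model observer with eye filter** (NPWE),
which combines the two into a detectability index d′ and an ROC area for
disk-detection tasks such as simulated coronary plaques.  It is aimed at
medical-physics users who characterize scanners (e.g. photon-counting vs
energy-integrating detectors) from uniform-phantom slice stacks.

Because real scanner acquisitions are rarely shareable, the package ships a
synthetic phantom simulator with fully known ground truth — a 5 cm iodine
insert (+350 HU) in a polyethylene-like background (−100 HU) on a 512×512,
200 mm field of view, blurred by a configurable PSF and overlaid with
stationary noise of prescribed power spectrum — so every estimator is
verifiable by parameter recovery and closed-form limits.

## The model

For background ROIs the 2D NPS is estimated ICRU-style (plane detrend, DFT,
modulus squared, scaled by pixel area over pixel count, ensemble averaged)
and radially averaged to NPS(f).  Its peak frequency characterizes noise
texture; its integral the noise magnitude.  The TTF comes from the classic
circular-edge method: subpixel center location, angular-sector edge-spread
functions oversampled at 0.1 pixel, differentiation to a line-spread
function, Hann windowing, Fourier modulus, normalization to 1 at f = 0, and
TTF50/TTF10 read-off.  The detectability index for a disk of contrast
|ΔHU| and radius r is

    d′ = 2π |ΔHU| ∫₀^fNy S²(f) TTF²(f) VTF²(f) f df
         / sqrt( ∫₀^fNy S²(f) TTF²(f) NPS(f) VTF⁴(f) f df )

with S(f) = (r/f)·J₁(2πrf) the disk transform, VTF the eye filter
(u^a·e^{−cu²} in cycles/degree, peaking at 4 cyc/deg), fNy the Nyquist
frequency, and AUC = Φ(d′/√2).  Two systems are compared through relative
shift statistics: NPS peak-frequency shift, noise-magnitude reduction,
TTF50/TTF10 shifts (all 100·(a−b)/b, in %), and per-task d′ ratios.  A
Monte-Carlo template-observer oracle simulates the actual detection
experiment in the image domain; see `docs/methods.md` for the exact
relation between the radial-integral index above and the simulated
observer's decision-variable SNR.

## Worked example

The shipped demo pits a "PCD-like" system (sharper TTF, higher-frequency
noise peak, lower variance) against an "EID-like" reference at three
simulated patient sizes (noise levels):

```bash
ctiq demo --seed 1 --out demo_out
```

prints the headline comparison table (PCD-like relative to EID-like):

```
size_label  peak_frequency_shift_pct  noise_magnitude_reduction_pct  ttf50_shift_pct  ttf10_shift_pct
     small                 23.076923                     -24.172890        32.754782        33.239229
    medium                 50.000000                     -44.024950        32.634079        34.016011
     large                 41.666667                     -47.930723        32.960281        33.391917
```

Positive peak-frequency shifts mean the PCD-like system's noise texture is
finer; negative magnitude reductions mean it is less noisy; positive TTF
shifts mean it resolves finer detail (the demo's blur models are set 35%
apart, and the estimated shifts land near +33%).  `demo_out/` also contains
per-condition NPS/TTF curves, d′/AUC tables for twelve disk tasks
(six high-contrast "plaque" and six 30 HU "lipid" tasks, 0.5–3 mm), and
per-size d′ ratio tables, e.g. for the small size the 0.5 mm plaque task
gives d′ 23.7 (PCD-like) vs 12.7 (EID-like), a +87% ratio — the sharper,
quieter system wins every task at every size.  Individual stages are
available as `ctiq simulate / nps / ttf / dprime / compare / report`.

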