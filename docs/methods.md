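# Methods

## Model and rationale

The package measures orientation order in band-like texture. Its target is
dermal collagen in cross-polar picrosirius images: bright birefringent
fibre bundles on a dark background, healthy skin showing two bundle
families crossing at ~90° (the basketweave). The central assumption is
that orientation order is a *spectral* property: a family of parallel
bundles concentrates amplitude-spectrum energy in a narrow wedge
perpendicular to the bundle direction, and loss of order spreads that
wedge. The pipeline therefore never segments fibres; it scores the shape
of frequency-domain energy.

Stages, per image:

1. **Grayscale + median.** RGB inputs are reduced with Rec. 601 luminance
   weights (0.299, 0.587, 0.114) — configurable, since the acquisition
   could equally justify a single channel — then passed through a 3×3
   median filter (reflect padding) to suppress photon-noise impulses
   without blurring bundle edges.
2. **Directional Gabor bank.** The mean-subtracted image is convolved
   (reflect padding, FFT-backed, real cosine kernel) with Gabor filters at
   θ ∈ {0°, 45°, 90°, 135°}. The even cosine kernel makes θ and θ+180°
   identical, so four channels realise eight directions. Mean subtraction
   removes the non-zero DC gain of the cosine kernel, making channel
   energy reflect oriented structure rather than brightness.
3. **Windowed amplitude spectrum.** Each channel is tapered with a
   separable 2-D Hann window — suppressing the axis-aligned leakage cross
   that image-edge discontinuities would imprint on the spectrum — and
   transformed to the centred DFT modulus under the 1/(MN) normalisation.
   The taper reintroduces a small weighted mean, so the windowed array is
   re-centred immediately before the FFT; the DC bin is then exactly zero
   and cannot masquerade as blob content.
4. **Binarisation.** A single threshold per image — the 0.995 quantile of
   the log-compressed amplitudes pooled over the four channels — converts
   each channel spectrum to a binary scatter pattern. Pooling is
   essential: a per-channel quantile would self-normalise each channel and
   erase precisely the cross-channel energy disproportion the index
   measures. The quantile form keeps the threshold invariant to overall
   image gain. Comparison is strictly above threshold, so a quantile that
   lands on the spectrum's zero floor never floods the mask.
5. **Equivalent ellipse and index.** Each channel's whole supra-threshold
   pattern is summarised by the ellipse with the same second central
   moments (axis = 4·√eigenvalue of the bin-coordinate covariance; axes
   floored at 1 bin, the extent of a single bin). The per-direction score
   is the elongation `N_ωn = 1 − short/long`, and the image index is
   `N = max(N_ωn)/min(N_ωn)`. Measuring the whole pattern, rather than one
   connected component, keeps the estimate stable: thresholded spectra of
   narrowband channels fragment into centro-symmetric lobe pairs, and the
   shape of any single fragment is noise-dominated, while the pooled
   pattern's moments are governed by the deterministic channel envelope.
   (The standalone `binarize_spectrum` operation retains the
   central/largest-component rule for isolating a single blob when that is
   wanted.)

The FFT-only baseline applies stages 1, 3–5 to the unfiltered image; with
a single spectrum there is no max/min ratio, so its index is the lone
elongation score in [0, 1). On white noise the supra-threshold pattern
fills the frequency plane uniformly and the score is near 0; on oriented
texture the pattern is a wedge and the score grows. It detects only gross
anisotropy: on two-family basketweave phantoms it stays low and nearly
flat across degradation levels, which is the motivation for the Gabor
stage.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `gabor.sigma_x`, `sigma_y` | 4 | px | Gaussian spread of the kernel; sets orientation/frequency bandwidth (≈1/(2πσ) ≈ 0.04 cycles/px) |
| `gabor.freq` | 0.08 | cycles/px | carrier frequency; tuned to the ~12 px bundle spacing at the target magnification |
| `gabor.support_radius` | 15 | px | kernel half-size; ≥ 3σ so truncation is negligible |
| `gabor.response` | real | — | cosine kernel as defined; quadrature magnitude available as an option |
| `spectrum.quantile` | 0.995 | — | binarisation quantile on pooled log-amplitudes |
| `spectrum.window` | hann | — | taper; `none` only for diagnostic use |
| `epsilon_floor` | 1e-3 | — | smallest admissible per-channel elongation; below it the image is reported as degenerate-isotropic rather than silently clamped |
| `min_side` | 64 | px | smallest image side for a usable spectrum |

Index values are comparable only within one configuration; every result
carries a hash of the canonical parameter serialisation.

The filter defaults suit ~90× magnification where bundle spacing is
~10–15 px; for other scales `freq` should track 1/spacing and σ a few
pixels below the spacing. The method is tuned to the *absolute* channel
orientations, so specimens should be mounted in a consistent plane
(see rotation sensitivity below); a per-image pre-rotation column in the
ROI file allows manual alignment, and no automatic orientation
normalisation is attempted.

## The phantom generator

`generate_basketweave` renders two families of finite straight fibre
segments (default orientations 45°/135°), each segment's orientation drawn
from N(family angle, `angular_jitter_sd`); the jitter SD is the
degradation knob. Defaults, fixed from realism arguments at design time:
segment length uniform on 60–100 px and width 4 px (collagen bundles are
finite, and finite length gives the intact spectrum its
diffraction-limited angular width — infinitely long lines would produce
measure-zero spectral ridges and a spectrally degenerate "intact" field);
mean spacing 12 px with uniform (Poisson-like) segment placement at
matching density; per-fibre relative intensity jitter 0.25 (uneven
birefringence); additive intensity for overlaps, clipped to [0, 1]
(bright fibres on a dark cross-polar background); Gaussian pixel noise
SD 0.02 over a 0.05 background. `generate_isotropic` provides the fully
disordered control (white noise, mean 0.5, SD 0.15, clipped).

Ground truth is method-independent: wedge-integrated spectral energy
recovers the family angles to within ~1° at zero jitter, and wedge
concentration decreases strictly with the jitter SD. What the phantoms do
*not* model: fibre curvature, width variation along a bundle, the
papillary/reticular layering, polarisation optics, staining variability,
or correlated illumination gradients. Passing phantom tests therefore
demonstrates sensitivity to orientation dispersion under controlled
conditions, not end-to-end validity on histology; on real material the
index additionally inherits sectioning and mounting variability, which the
per-animal averaging (≥ 3 fields) is meant to damp.

## Numerical choices

- Reflect (symmetric) padding throughout (median, convolution), avoiding
  dark-border spectral artifacts.
- Even-sized spectra place DC at index (M/2, N/2) after centring.
- Single-bin (and collinear) masks are floored to 1-bin axes, giving
  elongation 0 and surfacing as degenerate isotropy if they decide the
  index.
- Component-selection ties (equal-size largest components) resolve to the
  lowest label in scan order — deterministic.
- The pipeline is fully deterministic: identical input and configuration
  give bitwise-identical results; phantom generation is reproducible from
  its seed.
- Interpolated bilinear rotation is restricted to |angle| ≤ 45° and
  followed by a central crop to the largest padding-free rectangle;
  multiples of 90° are exact array quarter-turns, under which the four
  channels permute exactly and the index is invariant.

## Behaviour at the study scale

The test suite and experiment recipes use 256×256 phantoms (512×512 for
noise controls), a jitter grid of {0, 10, 20, 30, 40}° with 10 replicates
per level, chosen to resolve the behaviours of interest while keeping a
full run in seconds on one CPU. At these sizes: isotropic controls give
N ≈ 1.01–1.06 (analytic floor 1); the mean index declines strictly with
jitter (≈3.7 at 0° to ≈1.14 at 40°) with r² ≈ 0.84 for the linear
index–jitter correlation — the decay is convex, saturating as the texture
approaches isotropy, so the linear r² understates the ordering; adjacent
degradation levels are separated with Cohen's d ≈ 0.7–3.0, uniformly
larger in magnitude than the FFT-only baseline's. A 5° whole-image
rotation preserves the intact-vs-degraded contrast; 25° pulls the intact
index down to near the degraded level, because the basketweave then falls
between the fixed filter orientations.

## Known limitations

- The index depends on the four fixed channel orientations; textures
  misaligned by ~20–30° are scored as less ordered. Consistent specimen
  orientation is a protocol requirement, not a software guarantee.
- The binarisation quantile trades robustness against sensitivity: far
  higher quantiles fragment the pattern, far lower ones dilute it with
  floor bins. The default was chosen with the filter bandwidth and is not
  re-optimised per image.
- `N` is a ratio statistic: when all channels are near-isotropic its
  denominator is small and the index becomes noisy; the epsilon floor
  turns the pathological limit into an explicit error rather than a
  silently unstable number.
- Group-level inference (ANOVA, t-tests) is deliberately out of scope; the
  CSV outputs are shaped for downstream statistics tools.
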