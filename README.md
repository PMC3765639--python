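# gaborient

Quantifying collagen basketweave integrity in skin histology from
Gabor-filtered Fourier spectra.

## The problem

Healthy dermal collagen is organised as a *basketweave*: two families of
fibre bundles crossing at roughly 90°, which appear as bright bands on a
dark background in cross-polar photomicrographs of picrosirius-stained
sections. Ageing and disease (e.g. type 2 diabetes) relax this orthogonal
order long before gross pathology such as fibrosis is visible, and the
change is hard to score by eye or with bulk measures. `gaborient` turns a
single such photomicrograph into one scalar — a **collagen orientation
index** — sensitive to that progressive loss of order. It is intended for
histology image analysts and skin-biology groups screening ageing or
therapeutic interventions at scale.

## The method

For an image `f(x, y)` (grayscale, 3×3 median-filtered):

1. A bank of real Gabor filters — Gaussian-windowed cosines

   `g(x, y) = 1/(2π σx σy) · exp(−½ (x²/σx² + y²/σy²)) · cos(2π ω x)`

   rotated to θ ∈ {0°, 45°, 90°, 135°} — decomposes the texture by
   orientation. Because the cosine kernel is even, each channel covers the
   opposite-angle pair {θ, θ+180°}, so the four channels realise an
   8-direction analysis.
2. Each filtered channel is Hann-windowed and transformed to its centred
   DFT amplitude spectrum `|F(u, v)|` (normalisation `1/(MN)`).
3. A single binarisation threshold — a quantile (default 0.995) of the
   log-compressed amplitudes pooled over the four channels — converts each
   spectrum into a binary scatter pattern, and the pattern is summarised by
   the ellipse with the same second central moments.
4. Each direction is scored by its ellipse elongation

   `N_ωn = 1 − short axis / long axis ∈ [0, 1)`

   and the per-image index is the spread of the four scores:

   `N = max(N_ωn) / min(N_ωn) ≥ 1`.

An intact basketweave at 45°/135° loads the diagonal channels
disproportionately, giving unequal elongations and a large `N`; as order
degrades the four spectra approach equality and `N` falls toward 1. An
FFT-only baseline (the elongation of the single unfiltered spectrum) is
included for comparison; it is markedly less sensitive to incipient
degradation.

Because no reference micrographs ship with the package, a synthetic module
generates basketweave *phantoms* — two families of finite straight fibre
segments with a tunable per-fibre angular-jitter SD standing in for
biological degradation — plus isotropic white-noise controls, giving an
analytic ground truth (spectral wedge energy) against which the index is
validated.

## Worked example

```python
from gaborient import (PhantomSpec, generate_basketweave,
                       analyze_image_gabor, analyze_image_fft_only)

for jit in (0.0, 30.0):
    ph = generate_basketweave(PhantomSpec(angular_jitter_sd=jit, seed=1))
    res = analyze_image_gabor(ph)
    base = analyze_image_fft_only(ph)
    print(f"jitter {jit:4.0f}:  N_w = "
          + ", ".join(f"{k}: {v:.3f}" for k, v in res.n_omega.items())
          + f"  ->  N = {res.index_N:.2f}   (fft-only: {base.index_N:.3f})")
```

prints

```
jitter    0:  N_w = 0/180: 0.247, 45/225: 0.843, 90/270: 0.198, 135/315: 0.850  ->  N = 4.29   (fft-only: 0.006)
jitter   30:  N_w = 0/180: 0.631, 45/225: 0.715, 90/270: 0.716, 135/315: 0.732  ->  N = 1.16   (fft-only: 0.110)
```

For the intact phantom the diagonal channels (45°/225° and 135°/315°)
carry elongations near 0.85 against ~0.2 for the off-axis channels, so the
index is large (4.29); after 30° of per-fibre jitter the four channels are
nearly equal and the index collapses toward its floor of 1. The FFT-only
baseline barely separates the two conditions.

## Command line

```
gaborient phantoms --output ph/ --jitter-grid 0,10,20,30,40 --n-seeds 10
gaborient analyze --input 'ph/*.png' --output results/ --method both
gaborient experiment-monotonicity --output mono/
gaborient experiment-rotation --output rot/
```

`analyze` writes one tidy CSV row per image × ROI × method (per-image
failures are recorded as rows, never abort the batch) and stores the exact
configuration (`config.json`) beside the results. ROI files
(`image, compartment_label, row0, col0, height, width`) support
compartment-level analysis, e.g. papillary vs reticular dermis. Per-animal
averaging over ≥ 3 fields and Pearson correlation reports (r², 95% CI, p)
are available via `gaborient.aggregate` and `gaborient.pearson`.

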