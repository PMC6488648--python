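# Methods

`coralwatch` extracts two behavioural time series from hourly fixed-camera
imagery of a cold-water coral (*Lophelia pertusa*) colony — tissue colour
`xi_t` and polyp activity `gamma_t` — and analyses them together with
environmental sensor records using correlation and Morlet wavelet methods.
This note documents the models and procedures, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical choices that matter.

## 1. Coral colour series `xi_t`

Per frame: translation-only registration against a fixed reference frame →
fixed white balance → CIELab conversion → texture-based live-coral
segmentation → masked mean colour. `xi_t` is the a-channel (green–red axis)
of the masked mean; `L` and `b` are stored alongside so the assumption that
they carry no signal of interest can be re-checked at any time.

**Registration.** The camera is fixed, so only integer-pixel jitter is
expected; phase correlation estimates the translation and the frame is rolled
back, with rolled-in border pixels flagged invalid. Failure detection uses
the Pearson correlation of the registered overlap (default threshold 0.2)
because the phase-correlation peak statistic under phase normalisation is
near 1 for structured *and* pure-noise pairs. Failed frames become gaps.
An affine upgrade was considered and deliberately left out: nothing in a
fixed-observatory deployment produces rotation or scale between hours.

**White balance.** One gain triple for the whole sequence, either supplied or
estimated once from a configured neutral patch in the reference frame
(`estimate_white_balance`). Because the gains are constant, relative
frame-to-frame colour differences — the thing `xi_t` measures — are
preserved exactly up to quantisation.

**Colour convention.** sRGB primaries, D65 white point, standard CIELab
transform (scikit-image `rgb2lab`). Consumer cameras default to sRGB; any
fixed convention works since `xi_t` is analysed for variation, not absolute
colorimetry.

**Segmentation.** Texture features are Gabor filter-bank magnitudes: 4
frequencies (0.04–0.32 cycles/px, octave-spaced) × 6 orientations, pooled
over orientation (rotation-robust, 4 features/pixel) and smoothed with a
4 px Gaussian for spatial coherence. Filtering runs in the Fourier domain
because low-frequency Gabor kernels are large. The pixel labeller is a flat
8×8 self-organising map trained on labelled seed pixels: batch training with
a shrinking Gaussian neighbourhood, majority-vote class per node,
nearest-prototype prediction. A hierarchical hyperbolic SOM variant exists in
the literature this stage descends from; the flat SOM keeps the class
decision (which is what drives the mask) while remaining a plain,
reproducible vector quantizer. The predicted mask is cleaned by morphological
opening + closing with a 2 px disc to suppress salt-and-pepper labels.

## 2. Polyp activity series `gamma_t`

Experts annotate polyp positions as *active* (extended, feeding) or
*inactive* (retracted) on a subset of frames. The polyp mask `M` is the
union of discs (default radius 23 px — half the patch size, tying the mask
to the classifier footprint) around every annotated point of every
annotator. 46×46 patches are extracted at annotated positions (border
centres skipped and logged), a background class is sampled at 100 random
out-of-mask positions, and each patch is augmented 48-fold:
{identity, horizontal flip} × {12 rotations at 30°, reflective resampling} ×
{clean, Gaussian noise at 2% of dynamic range}.

Splits (70/20/10 train/val/test) are assigned at the **source-annotation
level per class**, before augmentation inheritance, so no augmented
descendant of a held-out patch can reach the training set; the provenance
table makes this auditable.

**Classifier.** A LeNet-5-layout CNN adapted to 46×46×3 input: conv 6@5×5 →
maxpool 2 → conv 16@5×5 → maxpool 2 → fc 120 → fc 84 → softmax, implemented
in numpy (im2col convolutions, minibatch Adam, deterministic under seed).
The head is 3-way (active / inactive / background) because the background
class participates in training; for `gamma` the background prediction simply
isn't "active", i.e. it collapses into the inactive side. The output used
downstream is the continuous likelihood P(active), thresholded at 0.5
(configurable) — the natural softmax contract behind a nominally binary
decision.

**Eq for `gamma`.** Every pixel of `M` is classified from the patch centred
on it (the ROI is reflect-padded so border pixels have full patches) and

    gamma_t = #{masked pixels classified active} / #{masked pixels}.

Dense per-pixel classification is expensive, so a stride evaluates a subgrid
and nearest-fills the rest. The function default is stride 2; the pipeline
config uses stride 4–5 for full sequences, which changes `gamma` by well
under the noise level (the stride-1 brute-force oracle is kept in the test
suite and the stride-2 vs stride-4 difference is asserted ≤ 0.05). Note that
`gamma` is a pixel fraction, not a polyp count: pixels near an active polyp
classify as active across the whole disc, so `gamma` is a monotone but
compressed proxy of the true active fraction — which is why recovery is
scored by rank correlation.

**Accuracy protocol.** Inter-observer agreement uses greedy nearest-first
point matching within 23 px; agreement = (matched pairs with equal class) /
(matched pairs + unmatched points), so missed detections and label conflicts
both count against agreement. The published agreement statistic for this
kind of data is not standardised; this definition is declared rather than
tuned. A count-based manual activity (fraction of annotated points marked
active) is rank-correlated against `gamma_t` over the annotated frames.

## 3. Series alignment

All interpolation is bracketed-linear: the value at target `t` is
interpolated between the latest measurement ≤ t and the earliest ≥ t, with
exact pass-through at measurement times and no extrapolation. `to_hourly`
maps any series onto an hourly grid; a **max-gap guard** (default 24 h)
marks grid points whose bracket spans a longer outage as missing, because
bridging a week-long sensor failure with a straight line fabricates
low-frequency structure. Setting the guard to `None` recovers the literal
interpolation equations. The wavelet stage runs on guard-free interpolation
(it needs a gapless grid); the guard protects the correlation tables.

Daily averages are per-UTC-calendar-day means of raw measurements — never of
interpolated values — and days without data are absent, not zero-filled.
Correlations (Pearson/Spearman) drop incomplete pairs and report `n`.

## 4. Wavelet analysis

Morlet CWT with nondimensional frequency `omega0 = 6` (the geophysical
convention balancing time and scale resolution), dyadic scales at 12
voices/octave from 2·dt up to half the record length (configurable), FFT
evaluation with zero-padding to the next power of two, cone of influence at
the e-folding distance sqrt(2)·s. Equivalent Fourier period = 1.033 × scale.

**Bias-corrected power** is `|W|²/s`: without the 1/s correction,
equal-amplitude oscillations at longer periods show inflated peaks (the test
suite demonstrates both the corrected equality and the uncorrected bias).
The global spectrum is the time-average of corrected power per scale; by
default over all times, with an inside-COI variant behind a flag.

**Power significance** is the pointwise chi-square test: under an AR(1)
background with lag-1 autocorrelation `a` and variance `s²`, power at each
scale is compared against `s² · P(f) · chi2_{0.95}(2)/2` where `P(f)` is the
normalised AR(1) spectrum at the scale's equivalent frequency. AR(1)
parameters are fitted by lag-1 autocorrelation. Calibration is verified
empirically: ~5% of inside-COI points flagged on pure AR(1) input.

**Coherence.** Squared coherence = `|S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s))`
with `S` a Gaussian-in-time smoother (width = the scale, matching the Morlet
envelope) followed by a boxcar over 0.6 octave in scale. The smoothing
windows follow the established coherence construction for geophysical
records and are configurable; coherence is clipped to [0, 1] against
rounding. Phase is the argument of the smoothed cross-spectrum: 0 in phase,
±pi counter-phase, +pi/2 when the second series lags the first by a quarter
period. Significance is Monte Carlo: AR(1) surrogate pairs matched to both
series' lag-1 autocorrelation and variance, per-scale 95% quantile of
surrogate coherence pooled over inside-COI times (default 300 surrogates).

## 5. The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes, not
reef optics:

- a live-coral region (smooth random blob, ~1/3 of the frame) carrying an
  oriented band-pass texture (carrier 0.12 cycles/px) and a controllable
  CIELab a* tissue colour, on a smoother bluish background — so the Gabor/SOM
  stage has a real texture contrast to find;
- polyps at fixed positions across the sequence (a colony does not move),
  drawn per frame as Bernoulli(activity) active states: active polyps are
  6–10 thin radial arms reaching ~20 px (the 46 px patch scale), inactive
  ones smooth discs — so the patch classes are learnable but not trivial;
- hourly timestamps, integer-pixel Gaussian camera jitter (the first frame
  is jitter-free and anchors the coordinate system), and a fraction of
  frames dropped outright, the way camera malfunctions leave holes;
- sensor series = piecewise-linear trend + sinusoids (tidal 12.4 h, diel
  24 h, lunar ~707 h) + AR(1) noise of specified stationary sd, minus outage
  gaps;
- point annotations per synthetic expert with Gaussian position error and
  Bernoulli label flips.

Rendering happens in CIELab and is converted to sRGB once, so the injected
a* survives the round trip to within quantisation (verified ±1). Everything
is deterministic under the seed.

**What it does not emulate** — and therefore what passing tests do not show
about real data: water-column optics and lighting drift (the fixed white
balance is exact here, approximate in the sea), biological texture variety
(one carrier frequency vs real coral rugosity), polyp morphology (the
radial-arm/disc dichotomy is a stand-in; real expansion states form a
continuum), fish/shrimp occlusions, and focus changes. Classifier accuracies
near 1.0 on synthetic patches say the pipeline is correct, not that real
patches are this separable.

**Benchmark scales.** The synthetic study conditions mirror the deployment:
hourly frames over a record of ~5100 h for spectral checks (seven months),
13 annotated frames, 3 annotators, 100 background patches, 70/20/10 splits,
48× augmentation. The annotated frames are spread evenly over the record,
as annotation campaigns sample it in practice; this matters, not
cosmetically: training patches must cover the record-long colour drift or
the classifier is applied under covariate shift and its activity estimates
degrade on late frames (we observed exactly this failure with
first-13-frames annotation before adopting the spread). The image-pipeline recovery benchmark runs 100 frames at
512×512 with 30 polyps — enough for stable ramp-recovery statistics while
keeping the CPU-only CNN training and dense classification to minutes; frame
count and resolution are configurable upward without code changes.

## 6. Numerical choices and degenerate inputs

- Interpolation at a measurement time returns the measurement bit-exactly.
- `mean_color` with an empty mask, correlation of constant input, AR(1) fit
  of a constant series, classification over an empty mask: all raise typed
  errors; series stages catch them and record gaps instead of inventing
  values.
- SOM nodes that win no training pixel inherit the label of the nearest
  labelled node; codebook initialisation is a seeded sample of the data.
- Max-pool gradient splits ties evenly (relevant only for saturated uint8
  patches).
- Coherence values are clipped to [0, 1] after division; thresholds at
  scales with no inside-COI points are NaN and flag nothing.
- The scale ladder stops at half the record length; peaks near that edge sit
  mostly outside the COI and are attenuated by the zero-padding — a ~5100 h
  record is needed before the ~707 h lunar peak lands on its scale.

## 7. Known limitations

- Translation-only registration; a slumping camera platform would need the
  (deliberately omitted) affine mode.
- `gamma` compresses the true active fraction (pixel-disc effect above);
  absolute levels are not comparable across colonies with different polyp
  densities, trends and ranks are.
- The AR(1) null is the standard red-noise model; strongly tidal series
  violate it and their "significant" tidal power is exactly what the test is
  supposed to find, but broadband violations (e.g. storms) inflate false
  positives.
- The numpy CNN is single-threaded BLAS-bound; at much larger patch counts a
  GPU backend would be the right substitution, behind the same `Classifier`
  surface.
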