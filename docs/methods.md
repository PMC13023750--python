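# Methods

This note documents the models, numerical choices and limitations behind
`respgate`, in the spirit of a methods appendix.

## Spoiled-GRE signal model and the mid-field CNR penalty

The steady-state transverse magnetization of an RF-spoiled gradient-echo
sequence is modelled in closed form,

    S = M0 · B0 · (1 − E1) sin α / (1 − cos α · E1) · exp(−TE/T2*),
    E1 = exp(−TR/T1),

with the equilibrium magnetization taken linear in B0. Noise is modelled as
field-independent additive Gaussian with a user-set SD, so CNR ratios
between field strengths carry the full linear B0 scaling; no Bloch
simulation, RF-spoiling phase cycling or B0/B1 inhomogeneity is attempted.
Angles are degrees at all interfaces and radians internally.

Tissue relaxation values are **not hard-coded**: they are read from a CSV
table (`name, field_T, T1_ms, T2star_ms, M0_rel`). The bundled default
table holds literature values transcribed for 0.6 T and 1.5 T (myocardium
T1 701/1030 ms, liver 339/586 ms, fat 183/260 ms; typical T2* 40/30, 30/24,
50/40 ms; lung 800/1100 ms with very short T2*) together with standard
relative proton densities (0.8/0.7/1.0/0.2). These are literature defaults,
not measurements by this package, and they can be replaced wholesale.

With this table and the protocol sequence (TR 5.9 ms, TE 3.5 ms, flip 15°),
the CNR ratio between 1.5 T and 0.6 T for the two fat-contrast interfaces
(liver–fat, myocardium–fat) evaluates to ≈ 2.1–2.4 around the protocol flip
angle — the expected mid-field CNR penalty for a projection navigator,
below the raw 2.5× B0 ratio because T1 shortening at lower field partially
compensates. Two caveats are deliberate design statements rather than
oversights:

- the **myocardium–liver** pair is reported but not held to that band: with
  proton-density weighting its signal difference changes sign near 5° at
  both field strengths, so its CNR passes through zero inside the sweep and
  the ratio is singular there and systematically lower (~1.35) at 15°;
- the band itself is only as good as the transcribed relaxation values;
  with a different literature table the sweep should be recomputed
  (`respgate cnr-sweep`), which is why the table is user-editable.

## Synthetic study conditions

The generators emulate a free-breathing thoracic acquisition with known
ground truth. Defaults were chosen once, as the package's standing study
conditions:

- **Breathing** — plateaued cosine-power (Lujan-type) waveform,
  `z(t) = z0 − A_k cos^{2n}(π(t−t_k)/T_k)` per cycle, with baseline
  z0 = 180 mm, amplitude 12 mm (typical SI excursion of the heart–liver
  interface), period 4 s (0.25 Hz, inside the physiological 0.1–0.7 Hz
  band), plateau exponent n = 2, per-cycle jitter of 0.25 s / 1 mm, and a
  0.5 mm/min linear drift. The plateau sits at z0, so end-expiration is the
  most occupied amplitude state — the property the polarity heuristic and
  the tercile binning rely on. The waveform model has a small step at cycle
  boundaries of the order of the amplitude jitter; this is accepted as part
  of the cycle-to-cycle variability. Duration defaults to 240 s, a
  desk-scale stand-in for a multi-minute scan, sampled at the 45 ms profile
  interval (22.2 Hz).
- **Projection phantom** — 360 mm SI field of view at 2.5 mm resolution
  (144 samples), tissue stack lung/myocardium/liver/fat with intensities
  from the signal model at 0.6 T. The myocardium–liver boundary follows the
  waveform and the lung–myocardium boundary follows it with unit coupling,
  i.e. the heart translates rigidly — SI translation of the heart and
  diaphragm is precisely the motion that projection self-gating detects.
  Sub-pixel motion is rendered by linear partial-volume weighting, so edge
  positions are recoverable to below one pixel.
- **Coils** — 32 Gaussian receive profiles (60 mm width) spread over the
  FOV, matching a 32-channel thoracic array. Coil count matters: the
  sum-of-squares combination averages noise across channels, and the
  surrogate-recovery guarantees below are stated for this array.
- **Noise** — complex white Gaussian noise in k-space with
  SD = |S(k0)|/SNR, where |S(k0)| is the mean over coils of the noiseless
  k-space-center magnitude of the static phantom. The definition is the
  package's own (no standard exists at this interface); note it is strict,
  since the k-space center is the brightest sample of the readout. Default
  SNR 20.
- **Camera** — `y(t) = gain·w(t−delay) + offset + noise` resampled to
  30 Hz; defaults delay 500 ms (the latency scale of camera-based
  surrogates), gain −0.8 (opposite sign convention, exercising polarity
  handling), noise SD 0.45 mm ≈ 10% of the waveform SD. The synthetic chest
  video modulates one rectangular patch affinely with the waveform over a
  static texture plus frame noise.
- **Velocity phantom** — 32×32×16 grid at 2.5 mm, axis-aligned cylindrical
  vessel of radius 15 mm (ascending-aorta calibre), parabolic cross-section
  with centerline peak 100 cm/s, venc 150 cm/s, separable raised-sine
  systolic waveform h(t) over a 1 s cycle at 24 phases. Parabolic×temporal
  separability (rather than Womersley flow) is deliberate: it gives the
  analytic ground truth Q(t) = πR²·v_peak·h(t)/2, stroke volume ∫Q dt and
  peak velocity v_peak·max h used by the acceptance tests. The second
  "reconstruction" is the first plus an independent Gaussian perturbation
  (SD 2.25 cm/s per component) inside the mask, so the expected vector RMSE
  is 2.25·√3 ≈ 3.9 cm/s — the magnitude of inter-reconstruction
  disagreement reported for in-vivo gating comparisons, which the phantom
  is meant to emulate.

All generators are seeded (`numpy.random.default_rng`) and bit-reproducible.

### What the phantoms do *not* emulate

The k-space simulation is a 1D profile stream, not a full 4D pseudo-spiral
trajectory; there is no eddy-current modulation between velocity-encoding
packages, no cardiac motion in the projection, no through-plane motion of
the camera target, no B1 shading, and the velocity phantom has no wall
motion, partial-volume rim or background phase. Passing tests therefore
demonstrate correctness of the *analysis chain* under controlled
conditions, not in-vivo performance; in-vivo agreement numbers will be
lower than the synthetic cohort's.

## Self-gating chain

Profiles are inverse-Fourier transformed per coil (centered, orthonormal
FFT, so Parseval holds to machine precision), magnitudes are combined by
sum of squares, and PCA is applied with **time points as observations and
spatial positions as variables**; the surrogate is the temporal score
series. The respiratory component is the one (of the first ten) with the
largest fraction of Welch spectral power (Hann window, segments of
min(n_t, 512) samples, 50% overlap) inside the 0.1–0.7 Hz band. Scores are
normalized to unit variance before the spectral comparison, making the
selection statistic scale-invariant — raw in-band power would trivially
favor the first component. A winning band fraction below 0.2 attaches a
"may not be respiratory" warning. The diagnostics record the per-component
explained variance and band fractions, plus the band fractions of the
transposed PCA interpretation (observations = positions), so the
orientation choice is auditable.

PCA leaves the sign of each component arbitrary; the sign is resolved only
by `orient_polarity`, which places the more-occupied half of the amplitude
range (the end-expiratory plateau) at the high end. A balanced histogram
(e.g. a pure sinusoid) keeps its sign and is flagged ambiguous. The
heuristic needs ≥ 30 s of signal and is idempotent.

## Alignment and binning

Both surrogates are linearly resampled to the coarser of the two rates over
their overlapping support and mean-centered; the delay is the lag
maximizing the normalized cross-correlation on that discrete grid
(optional parabolic sub-sample refinement is off by default because binning
operates at sample resolution). The peak is located by **largest absolute
correlation**: an inverted surrogate aligns at its anticorrelation peak and
is flagged for polarity review, rather than being mis-aligned to a spurious
positive lobe. Positive delay means the camera signal lags self-gating; a
peak on the search boundary (default ±5 s) warns.

"Three equally populated bins" is implemented as rank terciles with ties
broken by earlier time index and any remainder spread from the
end-expiratory bin downward, so populations differ by at most one (the
guarantee tested is ≤ 2). Bins are computed independently per surrogate
from each signal's own amplitude distribution, mirroring how each gating
method would be used on its own. For the confusion metrics the self-gating
arm is the reference and the camera arm the prediction; end-expiration is
the positive class. The consistency matrix is row-normalized to percent; an
empty reference bin yields a NaN row with a warning. The maximum
cross-correlation is computed after alignment, with the zero-lag value
reported alongside.

## Flow and velocity-field metrics

Plane extraction is axis-aligned nearest-slice (the phantom vessel is
axis-aligned; oblique reslicing would add unspecified interpolation).
Flow integrates the through-plane component over the masked lumen
(cm/s × cm² = mL/s); stroke volume uses the rectangular rule over the
uniformly sampled cycle (trapezoidal optional). Relative Bland–Altman
differences use the mean-of-pair denominator; limits of agreement are
bias ± 1.96·SD (n−1). The correlation statistic is the coefficient of
determination R² of an OLS fit. The paired Wilcoxon test drops zero
differences, uses the exact null for n ≤ 25 without ties and the
tie-corrected normal approximation otherwise.

The masked vector error is implemented as a true RMS — per phase, the mean
over masked voxels of the squared vector difference, square-rooted, then
averaged over phases — which is the quantity the name "root-mean-square
error" describes; the raw (un-normalized) sum of squares is exposed
separately for audit. The mean directional error `1 − cos∠(u,v)` is
averaged over systolic frames, with voxels excluded when either norm is
below 1% of venc (direction is undefined for near-zero vectors). Systolic
frames are those whose mask-mean velocity magnitude reaches half the cycle
maximum; "peak systole" is the frame maximizing that mean. Peak velocity
takes the masked maximum-intensity projection across the slice axis, then
scans all 4×4 kernel placements lying fully inside the 2D mask, picks the
one with the highest mean (ties → smallest row-major origin, for
determinism) and returns its maximum pixel.

## Pipeline

`run_comparison` executes simulate → self-gate → camera → align → bin →
agree → flow/velocity metrics from a validated nested config (unknown keys
rejected); every output carries a provenance block (config hash, seed,
versions) and a fixed seed reproduces a run bit-identically. `run_cohort`
repeats over independent seeds and `write_report` emits per-seed rows plus
a mean ± SD summary (sample SD, n−1). Stage failures are re-raised with the
stage name; completed stages' outputs are retained.

## Numerical and degenerate-input conventions

- F1 with no positives in either arm is defined as 1 (vacuous agreement);
  with positives present but no true positive it is 0.
- A constant projection raises "no respiratory component"; an all-zero
  profile stream yields an all-zero projection with a warning.
- A constant OLS response returns slope 0 and R² = 0 rather than an error.
- Velocity values beyond 2×venc are flagged, not rejected.
- Waveform parameters implying a breathing frequency at or above Nyquist
  are rejected at construction.

## Known limitations

- The delay between camera and self-gating surrogates is modelled (and
  estimated) as constant over the scan.
- The polarity heuristic assumes a dominant end-expiratory plateau; pathological
  breathing patterns without one are flagged ambiguous rather than resolved.
- The CNR band statement depends on transcribed literature relaxation
  values (see above) and excludes the sign-crossing myocardium–liver pair.
- The synthetic cohort's agreement metrics (accuracy ≈ 0.91, F1 ≈ 0.86,
  cross-correlation ≈ 0.98 at default noise) characterize the pipeline
  under the stated conditions only; they are upper bounds relative to
  in-vivo behaviour, where the two surrogates track different anatomy.
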