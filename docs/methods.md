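# Methods

This note documents the models implemented in `placentadce`, the choices
made where the underlying methodology leaves the design open, and what the
digital phantom does and does not emulate.

## Acquisition model and conventions

The dynamic series is a 4-D array (x, y, slice, frame) of T1-weighted
spoiled gradient-echo magnitudes, nominally 50 frames at 18 s per frame
(sampling rate 55.6 mHz, Nyquist 27.8 mHz), TE = 1.872 ms, TR = 101.493 ms,
flip angle 75°, voxels 0.156 × 0.156 × 0.85 mm.  Variable-flip-angle stacks
use TR = 114.88 ms at flip angles 75/55/30/20/10°.  Frames are indexed from
0; `injection_frame` is the first post-injection frame (default 4, i.e. the
bolus arrives between the 4th and 5th acquired frames counting from one).
All R1 values are in Hz, T1 internally in ms, perfusion in mL/min/100 mL
(÷6000 for s⁻¹).

## Pre-processing

Per voxel along time: a median filter (window 3 frames) followed by
grayscale morphological closing (structuring element 3 frames), both with
replicate padding; then a 3×3×3 spatial median per frame.  The window sizes
are the smallest non-trivial odd sizes, preserving the ~18 s dynamics while
suppressing single-frame respiration spikes and short dropouts.  The
temporal operators are 1-D by design: the artifacts they target (respiration,
inter-frame translation) are temporal.  The mean-removed maximum-intensity
projection (max over frames of signal minus the uptake-phase mean) is
provided as the segmentation reference image.

The arterial input function is extracted from the temporally denoised series
*before* the spatial median: the renal-hilum ROI is only a few voxels wide,
and a 3×3×3 median bleeds non-enhancing neighbors into it, roughly halving
the measured peak (and correspondingly inflating every perfusion value).
The steepest-slope map itself is computed on the fully filtered series.

## Perfusion

The steepest-slope model assumes no venous washout during wash-in, a
well-mixed arterial input, and a linear signal–concentration relationship
over the enhancement range.  Signal enhancement is used directly as the
concentration surrogate; the derivative estimator is the forward first
difference (a Savitzky–Golay alternative is deliberately not the default, to
keep the estimator faithful to "steepest slope of the signal").  Negative
slopes are clamped to zero in the map — washout is outside the model's
validity — but negative ΔR1 values in relaxometry are retained, since
clamping would bias chamber means.  Perfusion is normalized by the AIF's
peak *enhancement* (not a converted concentration), consistent with
signal-domain slopes; the global signal scale then cancels exactly.

## Chambers

The threshold is the per-placenta 55th (E14.5) or 45th (E17.5) percentile of
perfusion, with linear interpolation of the empirical CDF; voxels strictly
below go to the low chamber, ties to the high chamber, so a constant
placenta is all-high (with a warning).  On tie-free values the low-chamber
fraction is exact by construction whenever the count is attainable
(n divisible by 20).  Thresholding per placenta (rather than pooled per
litter) is the literal reading of the procedure; litter pooling can be
emulated by passing pooled values to `physiological_threshold`.

## Distribution biomarkers

The mixture is fitted on log10 perfusion (zeros excluded and counted).  EM
is implemented explicitly: responsibilities from the two weighted normal
densities, then weighted-moment updates.  Initialization splits the sample
at its median and moment-matches each half — deterministic, hence
reproducible; seeded random restarts are available (`n_init`).  Convergence:
relative log-likelihood change < 1e-8 (default), max 500 iterations; a
variance floor of 1e-6 (σ ≥ 1e-3) prevents point collapse, with re-spreading
and a non-convergence flag after repeated collapse.  Component labels
(low/high) are assigned by mean.  Peaks and AUCs describe the *weighted*
component densities, so the two AUCs sum to one; AUC is trapezoidal over a
grid spanning both means ±6σ.

Apparent blood volume uses the extensive form ABV = v·ΣF/100 (mL/min, with v
the voxel volume in mL), which is monotone in both placental size and
perfusion.  The literal density-integral form ((1/N)∫h dn) is emitted
alongside for comparison; it is dimensionally inconsistent as a volume and
nearly constant by normalization, which is why the extensive form is the
primary output.

## Motion and spectra

Horn–Schunck flow uses the original 2×2×2 gradient stencils, 8-neighbor flow
averaging, smoothness weight α = 100, 100 iterations or mean update < 1e-4,
computed per slice in 2-D on the temporally denoised series.  Because the
data/smoothness balance depends on the intensity scale, series are mapped to
a 0–255 range before flow — the conventional α = 10² is calibrated against
integer-image gradients.

Welch periodograms use a Hamming window, segment length ⌊n/4⌋ rounded down
to even (so the one-sided axis ends exactly at Nyquist), 50% overlap,
constant detrend.  The spectrogram uses a 15-sample Bartlett window, 50%
overlap, FFT length 10× the trace length.

The 8–12 mHz relative-power map divides each voxel's band power by its total
power after removing the slow contrast-uptake trend with a 9-frame
(162 s, ≈6 mHz cutoff) moving-average high-pass.  Plain mean removal is
available as an option but is not the default: the uptake ramp carries far
more variance than any physiological oscillation, and with it in the
denominator the relative band power of genuinely moving voxels falls to
~0.05, making the statistic unusable for classification.  With the
high-pass, moving voxels approach 1 and static noisy voxels stay near the
band's share of white-noise power (~0.14).  A placenta is classified phasic
when its best chamber's mean relative power exceeds 0.2 (configurable).

## The phantom

The phantom generates: K ellipsoidal placentas (default 8; 6–12 typical of
a litter) on a ring, long axes radial, each split by a plane perpendicular
to the long axis into low/high chambers at the stereological volume
fractions (55/45% at E14.5, flipped at E17.5); a central spherical AIF
region standing in for the renal hilum; a gamma-variate AIF
C_A(t) = A·((t−t₀)/ab)^a·e^{a−(t−t₀)/b} with delay 63 s, shape 2, decay
60 s, peak 0.15 concentration units at 183 s (washout under way well before
350 s); wash-in tissue curves C_T = (F/V_T)∫C_A with programmed perfusion
(30/55 at E14.5, 45.6/79.97 mL/min/100 mL at E17.5, i.e. developmental
increases of 15.6 and 24.97); spoiled-GRE signal through the Ernst relation
with R1(t) = 0.6 Hz + 3.3·C(t); smooth ~12% M0 texture inside placentas
(biological heterogeneity, and what gives optical flow and the band-power
map interior gradients to work with); sinusoidal in-plane translation of the
high chamber (components at 10, 15, 25 mHz with amplitudes 0.5/0.25/0.25
voxels) applied to round(prevalence·K) placentas — prevalence 0.111 at
E14.5, 0.821 at E17.5; additive Gaussian noise at 2% of the baseline
placental signal (Rician optional), added after motion.  VFA stacks are
synthesized pre-contrast (baseline R1) and post-contrast (baseline +
relaxivity × end-of-study concentration).

Geometry scale: on the default 64×64×8 grid the semi-axes are
(8.0, 5.5, 4.5) voxels at E14.5 and (9.0, 6.5, 5.0) at E17.5, scaled
proportionally on other grids.  Placentas are deliberately large relative to
the 3×3×3 median kernel and are cut by the slab in z — in the real
acquisition (256×160 matrix, 0.156 mm in-plane, 0.85 mm slices) placentas
span tens of voxels in-plane and only a few thick slices.  Were the
placentas much smaller, the spatial median would erode their rims into the
background and bias chamber means low by more than the model errors
themselves.

Concentration units are arbitrary-but-consistent (the method only uses
ratios); the peak amplitude 0.15 puts the AIF enhancement at ~50% over
baseline and keeps the signal–concentration relation near-linear, so the
forward-model bias of the recovered perfusion stays within a few percent.

What the phantom does **not** emulate: k-space/reconstruction effects,
self-gating, coil sensitivity profiles, B1 inhomogeneity, maternal organs
other than the AIF region, partial-volume fetal structures, bulk maternal
motion, and real anatomical chamber geometry (planar divide vs. the true
curved labyrinth/decidua interface).  Passing tests therefore demonstrate
the correctness and calibration of the *analysis*, not robustness to every
artifact of in vivo data.

## Numerical notes and limitations

- VFA fitting: the linearized S/sinα-vs-S/tanα regression is the initializer
  (exact on noiseless data); 30 vectorized Gauss–Newton iterations refine
  it, with E1 clipped to (1e-6, 1−1e-6).  Voxels that are all-zero or whose
  E1 leaves (0,1) are flagged invalid, never silently zeroed.
- Apparent Gd uptake multiplies the chamber-mean ΔR1 by the voxel count
  (extensive, "cumulative gadolinium" reading); the chamber-mean ΔR1 itself
  is reported alongside as the volume-normalized companion.
- The steepest-slope maximum over noisy differences is upward-biased; at 2%
  noise this bias is the dominant error in chamber means (~+10–15% for the
  low chamber) and is partly offset by the spatial median's boundary
  erosion.  Heavier temporal smoothing would reduce it at the cost of
  flattening the wash-in peak.
- Group statistics (Welch t, one-way ANOVA, Tukey–Kramer) are routine and
  delegated to scipy (`ttest_ind`, `f_oneway`, `tukey_hsd`).
- Pipeline problem sizes: the default study grid is 64×64×8×50 per session;
  a two-session study (analysis including flow) completes in well under a
  minute on one CPU.
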