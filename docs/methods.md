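# Methods

This note documents the models, conventions, and numerical choices behind
`lifespanfc`, and what its validation experiments do and do not show.

## Synthetic cohort model

Each subject is a set of parcel time series sampled at `fs` Hz, organized as
`n_epochs` independent epochs of `epoch_len` seconds:

- **Background**: Gaussian noise spectrally shaped to power ∝ 1/f^χ
  (default χ = 1), unit RMS. This emulates the aperiodic component of
  neural spectra; it contributes in-band noise at every analysis frequency.
- **Oscillations**: band-limited components built by frequency-domain
  masking of white noise with a Gaussian profile (σ_f = bandwidth/2)
  centered on the component frequency. Masking only positive frequencies
  yields the analytic representation z(t) directly; the waveform is Re z,
  normalized to unit RMS.
- **Planted coupling**: for a coupled pair (i, j) with strength κ ∈ [0, 1],
  parcel i receives a shared narrowband component s = Re z and parcel j
  receives `sqrt(1 − κ²)·u + κ·Re(z·e^{−iφ})` with u an independent
  narrowband draw — κ is the amplitude fraction of the shared (lagged)
  component relative to the parcel's independent narrowband power, so κ = 0
  gives independence and κ = 1 a pure lagged copy. The default lag φ = π/2
  is the point of maximal WPLI sensitivity (WPLI is blind to 0/π lags).
- **Age profiles**: κ(age) is constant, linear (κ₀ + slope·(age − ref)), or
  quadratic (κ₀ − curvature·(age − ref)², an inverted-U peaking at the
  reference age), plus optional per-subject Gaussian noise, clipped to
  [0, 1]. Ages are uniform on [18, 87] by default.
- **Behavior**: overcompensation = w_age·z(age) + w_conn·z(κ_target) +
  noise, with κ_target the mean realized κ of the coupling specs touching
  the designated target parcels in the designated band. A negative w_conn
  emulates a sensorimotor-attenuation measure that falls with connectivity.
- **Source patches**: n sources around one true parcel signal; a fraction
  is "flipped" (orientation > 90° from the dominant axis, signal negated),
  the regime that sign-flip averaging is designed to undo.

Reproducibility: per-subject seeds derive from the master seed by a
counter-based `SeedSequence(master, spawn_key=(k,))` scheme; identical
(config, seed) reproduce cohorts bit for bit.

**What the generator does not emulate**: volume conduction / source leakage
(signals are generated at the parcel level, so the leakage-insensitivity of
WPLI is exercised only through the zero-lag boundary cases), realistic
spatial covariance between parcels, line noise and artifacts, peak-frequency
drift with age, and power–age confounds. Passing recovery tests therefore
demonstrates correctness of the estimation and inference chain under the
stated generative model, not robustness to every property of real MEG.

## Filterbank conventions

Complex Morlet wavelets with fixed cycle count ω = 5: σ_t = ω/(2πf), a
Gaussian frequency response with σ_f = f/ω. The default grid is 32
geometrically spaced center frequencies from 1 to 100 Hz. Choices the
estimator needed that are conventions of this package:

- **Normalization**: unit gain at the center frequency — the analytic
  amplitude of a unit sinusoid at f_c is 1, so power is in signal units².
- **Truncation and edges**: kernels truncated at ±5σ_t; FFT convolution per
  epoch with zero padding; samples within half the truncated support of an
  epoch edge are masked invalid and excluded from all averages (power,
  cross-spectra, N_t). Epochs are filtered independently.
- Epochs must be longer than the f_min kernel (2·⌈5σ_t·fs⌉ + 1 samples);
  shorter inputs raise an error naming the required minimum.

## Connectivity conventions

- **WPLI**: time samples are pooled across all kept epochs into a single
  estimate per pair and frequency (one N_t), matching the single-sum
  definition; 0/0 (e.g. exact zero-lag) is defined as 0. Diagonals are
  stored as NaN and excluded everywhere; networks are never thresholded.
- **Band membership**: a bin belongs to a band iff low ≤ f_center < high,
  so a 13-Hz bin is beta and a 4-Hz bin theta; bins in the 30–40-Hz gap
  belong to no band.
- **Orthogonalized AEC**: per-sample orthogonalization
  y⊥ = Im(y·conj(x)/|x|), Pearson correlation of |x| with |y⊥| over valid
  samples, symmetrized by averaging both directions; raw envelopes (no log
  transform). Zero-amplitude reference samples are dropped; a residual
  whose RMS is ≤ 1e−10 of the signal RMS is treated as collinear (AEC 0).
- **Aggregation**: coarse weight (A, B) is the mean of all fine weights
  (i ∈ A, j ∈ B); decade averages use 10-year half-open bins anchored at
  the cohort minimum age.
- **Sign-flip averaging**: dominant direction = principal axis of the
  orientation second-moment matrix (robust when many sources are flipped),
  sign-aligned with the orientation sum; a source is flipped iff its dot
  product with the dominant direction is strictly negative (exact 90° is a
  no-op).

## Statistics conventions

- **Effects**: linear = Pearson r; quadratic = sign(β_x²)·(R²₂ − R²₁), the
  hierarchical increment, reading "after removing the linear trend" as
  incremental variance explained. (The full level-2 R² is the other
  defensible reading; the incremental form is the one this package uses,
  and it makes a pure linear trend score exactly 0.) Note the increment is
  a ratio to the total sum of squares, so it is invariant to affine
  rescaling of x but not to adding a linear-in-x component to y — only its
  numerator (the incremental explained sum of squares) is.
- **Permutation test**: two-tailed on |statistic|, shuffling the outcome
  with predictors fixed; add-one estimator p = (#{|s_perm| ≥ |s_obs|} + 1)
  / (n_perm + 1), so p is never 0. Within one mass-univariate call the same
  shuffled index sets are reused across units (per seed) for efficiency.
- **FDR pooling**: Benjamini–Hochberg within the pool the analysis level
  defines — connections or regions of one frequency band, or the frequency
  bins of a whole-network spectrum — separately per effect kind. Subjects
  with missing outcomes are dropped with a warning and n is recorded.
- **Detection floor**: with m units in a pool, the smallest attainable
  adjusted p for a lone true unit is m/(n_perm + 1) at BH rank 1. For a
  66-edge pool at 1000 permutations that floor is 0.066 > 0.05, so
  detection experiments either plant several true edges (raising the BH
  rank, as mass-univariate analyses at full scale do naturally) and/or use
  n_perm = 5000.
- **Multiple regression**: OLS on z-scored variables via statsmodels;
  parametric two-tailed coefficient t-tests; refuses to fit when
  |corr(age, overcompensation)| ≥ 0.7; FDR pools both predictors' p values
  across regions.
- **Outliers**: default rule excludes values more than 3 SDs from the mean
  (configurable); the analysis is re-run on the masked subset.

## Validation experiment design (problem sizes)

The desk-scale reference conditions (`lifespanfc.studies`) are 120 subjects,
12 parcels, 250 Hz, 2 × 10-s epochs. Recovery experiments use a 4-bin
analytic bank spanning only the analyzed band rather than the full 32-bin
grid — unanalyzed bins are simply not computed; membership and pooling are
unchanged. The same profile is planted on six disjoint edges so that the
66-edge FDR pool contains several true units (see the detection floor
above); the designated edge (0, 1) is the one scored.

Planted parameters are fixed once, for detectability at this scale:

- **Linear condition**: κ(age) = 0.35 + 0.00281·(age − 52.5) + N(0, 0.128²)
  in the alpha band, giving a population corr(age, κ) ≈ 0.40. The κ → WPLI
  mapping (nonlinearity plus finite-sample estimation noise at ~20 s of
  data) attenuates the recovered age–WPLI correlation by roughly 10%
  relative to corr(age, κ).
- **Inverted-U condition**: κ(age) = 0.62 − 2.5e−4·(age − 52.5)² + N(0,
  0.06²) in the beta band: a strongly negative signed quadratic statistic
  with a near-null linear effect (the profile is symmetric about mid-age).
- **Behavioral condition**: constant-profile beta couplings on parcels 0–3
  drive overcompensation (w_conn = −0.85, w_age = 0.25, noise 0.3); linear
  age-profile couplings sit on disjoint parcels 6–9.

Calibration experiments: type-I error from 500 null repetitions × 200
permutations at n = 120; FDR control from 50 repetitions of 200 units with
10% true effects at 500 permutations. The acceptance script runs 20 cohorts
per recovery condition (the test suite runs 50).

## Known limitations

- AEC estimation is loop-based (pairwise per sample vector); adequate for
  the desk scale it is exercised at, not tuned for 448-parcel inputs.
- The quadratic-effect reading (incremental vs. full-model R²) is a
  documented convention, as is pooling WPLI samples across epochs rather
  than averaging per-epoch estimates.
- Decade bins anchored at the cohort minimum age are a convention; calendar
  decades are obtainable via `bin_start`.
- The generator's omissions listed above bound what recovery results imply
  about real recordings.
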