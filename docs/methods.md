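# Methods

## Flash model and kinetic parameters

A photon-counting record is a vector of counts per bin (default bin width
10 ms, record length 40 s) with two multiplicative photon-calibration
factors: `calibration` (photons emitted per detected count, from a
calibrated reference source) and `qe_correction` (photomultiplier quantum
efficiency at the calibration-source emission wavelength relative to the
sample's ~475-nm bioluminescence). Both default to 1.0 and must be supplied
by the user; scaling either by *k* scales maximum intensity and integrated
emission by exactly *k* and leaves all time parameters unchanged.

Six parameters are computed per flash. With background *B*, peak bin count
*P*, and amplitude *A = P − B*:

* maximum intensity = *A* / bin_width × calibration × qe_correction;
* E-fold time and 90% decay time are the first downward crossings of
  *B + A/e* and *B + 0.1A* after the peak;
* rise time runs from the initiation crossing to the peak-bin center;
* duration = rise time + 90% decay time;
* integrated emission sums (count − *B*) from initiation to the end of 90%
  decay, times the calibration factors.

All sub-bin crossing times are linearly interpolated between adjacent bin
centers, so 10-ms binning does not quantize millisecond-scale parameters.
Decay thresholds are relative to the background-subtracted amplitude, which
is required for records with non-zero dark counts.

### Design choices where the procedure is genuinely open

* **Initiation** is the last upward crossing of the detection threshold
  before the peak — standard photon-counting practice; the threshold is a
  configuration parameter (`threshold_sigma`, default 3), so the choice is
  recoverable.
* **Peak ties** go to the earliest maximal bin (deterministic and
  order-stable).
* **Truncated flashes** (record edge reached, or overlap with the next
  flash before 10% decay) are flagged and counted in the per-record flash
  count but excluded from geometric-mean aggregation, since their decay
  parameters are lower bounds.
* **Overlap** is handled by merging above-threshold runs separated by fewer
  than `min_gap_bins` sub-threshold bins (default 5 bins = 50 ms) and
  otherwise splitting at the count minimum between peaks.
* **Integration bounds** for integrated emission run from initiation to the
  end of 90% decay, the same window that defines duration.

### Background and detection

The background is estimated robustly: starting from the median of all bins,
bins above median + 5σ are excluded iteratively, where σ is the MAD-derived
scale floored at √max(median, 1) — the shot-noise floor keeps low-rate
Poisson backgrounds (median 0–1, MAD 0) from being clipped to their zero
bins. The detection threshold is background + `threshold_sigma` ×
max(background SD, √background), the square root again being the Poisson
floor.

Two practical notes for realistic records. First, at the default 3σ a
4000-bin Poisson(2) background produces on the order of ten single-bin
false alarms per record (the Poisson tail is heavier than a Gaussian 3σ
suggests); 5–6σ gives a negligible per-record false-alarm rate. Second,
flashes with a slow luminescent tail dwell near the threshold for a long
time on the way down, so Poisson fluctuations split the tail into several
above-threshold runs; a larger `min_gap_bins` (e.g. 100 bins = 1 s, well
below typical inter-flash intervals) merges these into one flash.

## Synthetic flash records

The generator's waveform is a smooth rise times a one- or two-component
exponential decay,

    rate(t) = A′ (1 − e^(−t/τ_r)) [(1 − f) e^(−t/τ_d) + f e^(−t/τ_t)],

normalized so the maximum equals the requested peak photon rate. The
optional slow tail exists because measured *P. kofoidii* dark-phase flashes
show a 90%-decay/E-fold ratio of ~2.55, above the single-exponential value
ln 10 ≈ 2.30, so no single-exponential decay can reproduce the measured
regime. Expected counts per bin are the rate at the bin midpoint times the
bin width plus a constant dark-count background; counts are Poisson draws
(the standard photon-counting noise model), or the exact unrounded
expectation when noise is disabled (integers appear only when records are
written to disk — rounding noise-free tails would inject spurious
quantization into crossing times at low amplitudes).

The default model freezes parameters fitted once against the measured
dark-phase first-flash regime (rise 49 ms, E-fold 107.7 ms, 90% decay
275 ms, duration 326.7 ms, peak 3.87 × 10⁸ photons·s⁻¹): τ_r = 150 ms,
τ_d = 54 ms, f = 0.014, τ_t = 1200 ms, giving dense-grid truth values of
47.3, 111.0, 280.6 and 327.9 ms. A global search shows this waveform family
cannot land on all three measured times simultaneously; ~4% per parameter
is the attainable optimum, which is adequate for a generator whose role is
to produce realistic, fully known inputs rather than to replay the
instrument. The default dark background is 2 counts/bin (dark rates of a
cooled bialkali photon-counting module are of order 10²/s).

`ground_truth_kinetics` is the oracle: it evaluates the noise-free waveform
on a 0.1-ms grid and applies the parameter definitions directly (initiation
at 0.1% of peak — a noise-free, pipeline-independent convention), sharing
no code with the binned analysis.

### What the generator does and does not emulate

It reproduces the count statistics (Poisson), waveform scale, multi-flash
records, and dark background of stimulated single-cell measurements. It
does not model the stirring stimulus, cell-to-cell parameter variability
within a record, circadian modulation, flash-to-flash fatigue, or detector
artifacts (afterpulsing, dead time). Passing tests therefore demonstrate
correctness of the measurement pipeline on data that obey the stated model,
not fidelity of that model to any particular instrument.

## Validation results and problem sizes

* **Oracle equivalence.** A 26-model battery (τ_r 10–80 ms × τ_d
  50–300 ms × peak 10²–10⁴ counts/bin, plus the default two-component shape
  at 10³ and 10⁵) is generated noise-free on 2-ms bins over 40-s records;
  the binned pipeline matches the dense-grid oracle within one bin on every
  time parameter and within 1% on photon quantities (measured worst case:
  0.90 bins, 0.33%). The validation grid uses 2-ms bins because midpoint
  sampling of a sharp maximum on 10-ms bins contributes up to ~2.6% of pure
  discretization for the fastest waveforms, which would mask pipeline
  error; 40-s records keep the flash tail from contaminating the background
  estimate.
* **Recovery under noise.** 100 Poisson replicates per condition on 10-ms
  bins, 8-s records, background 2 counts/bin. At the measured dark-phase
  peak amplitude (3.87 × 10⁶ counts/bin) every parameter's median absolute
  relative error is below 5%. At a dim 500 counts/bin the rise time cannot
  be recovered to 10%: the earliest-maximal-bin peak estimate and the
  last-threshold-crossing initiation each jitter by one to two bins at peak
  SNR √500 ≈ 22, an intrinsic noise floor of these (deliberately simple,
  deterministic) estimators rather than an implementation defect. The
  boundary is at roughly 10³ counts/bin for the regimes probed.
* **Statistical calibration.** Type-I error of the pooled t, paired t and
  one-way ANOVA at α = 0.05 over 5000 null replicates each lies within
  [0.04, 0.06]; coverage of the back-transformed geometric-mean CI over
  2000 lognormal samples (n = 30) lies within [93%, 97%].

## Spectra

Processing order is background subtraction → Savitzky–Golay smoothing →
summary. When no measured background spectrum accompanies the data, a
constant baseline equal to the median of the lowest decile of intensities
is subtracted; note this estimator sits at roughly the 5th percentile of
the dim-channel noise, so it under-subtracts by ~1.6 noise SDs — negligible
for bright baselines, and overridden whenever a background vector is
supplied (the synthetic generator attaches its known baseline as such a
vector). Negative corrected intensities are retained so residual noise
statistics stay unbiased.

Smoothing fits a second-degree polynomial over a 25-channel window (both
configurable; the window must be odd and larger than the degree). Edge
points are fitted on the truncated one-sided window rather than on padded
data, so no values are invented outside the measured range. Polynomials of
degree ≤ 2 pass through unchanged to machine precision; the filter is
linear; repeated passes are contractive on white noise. One pass of the
(25, 2) filter broadens a 30-nm-FWHM Gaussian by ~0.4 nm — the familiar
smoothing/bias trade-off, kept because a single pass is the conventional
treatment for these spectra.

The peak wavelength is reported at the maximal grid sample (ties broken
toward the blue end), matching 1-nm reporting precision rather than a
sub-nm fitted vertex. FWHM uses the outermost half-maximum crossings
bracketing the global peak, each linearly interpolated, which is robust to
noise ripples near the half level; a missing crossing raises an error
naming the side. SNR divides the maximum smoothed intensity by the RMS of
the raw − smoothed residual over the analysis range — the only noise
estimate available from a single scan; identical inputs yield an infinite
SNR as a flagged value, not an exception.

## Statistics

Flash parameters are approximately lognormal, so values are natural-log
transformed (the geometric mean and back-transformed CI are invariant to
the base); the CI uses the t quantile with n − 1 degrees of freedom, not
the normal. The two-sample t-test defaults to the pooled (Student) form
with df = n₁ + n₂ − 2 — the convention under which the printed
flashes-per-cell comparison gives df = 69 for n = 34 and 37 — with Welch's
form available by flag. All tests are two-sided. Degenerate inputs
(zero variance where the statistic is undefined) return a flagged
`undefined` result rather than ±∞. The summary-statistics variants
(t-test and ANOVA from mean, SD, n) are algebraically identical to the
raw-data computations and are tested to agree exactly.

## Numerical and I/O choices

Crossing interpolation clamps negative interpolated times to zero and flags
them; equal neighbouring counts at a crossing place the crossing at the
later bin center. The pipeline writes CSV with a `%.10g` float format and a
sorted-key JSON manifest (configuration echo, package version, SHA-256
input checksums) so that identical inputs, configuration and seed produce
byte-identical outputs. All randomness flows from a single seed. Input
validation reports the offending row for negative or non-integer counts,
non-uniform bin widths, and non-increasing wavelength grids; a failing file
in a batch is reported in the manifest and the batch continues.

## Known limitations

* Detection is single-scale thresholding; overlapping flashes closer than
  the 10%-decay window are split at the inter-peak minimum and flagged
  truncated rather than deconvolved.
* Rise times of dim flashes (≲10³ counts/bin at the peak) are biased and
  noisy, as quantified above.
* The SNR definition conflates residual signal structure with noise if the
  smoothing window is far too wide for the peak.
* The spectrum baseline estimator assumes ≥10% of channels are
  signal-free.
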