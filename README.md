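# bioflash

Quantification of dinoflagellate bioluminescence from photon-counting and
spectrometer measurements.

Mechanically stimulated dinoflagellates such as *Polykrikos kofoidii* emit
discrete light flashes that are recorded as photon counts in 10-ms bins over
a 40-s stimulation period. `bioflash` detects the flashes in such records
and extracts the six standard kinetic parameters per flash:

* **rise time** (ms) — flash initiation to maximum intensity,
* **maximum intensity** (photons·s⁻¹) — background-subtracted peak rate,
* **E-fold time** (ms) — maximum to 1/e of maximum (initial decay rate),
* **90% decay time** (ms) — maximum to 10% of maximum,
* **duration** (ms) — initiation to the end of 90% decay,
* **integrated emission** (photons·flash⁻¹),

plus the number of flashes per cell per record. Counts are converted to
photons by a calibration factor (photons per detected count) and a
photomultiplier quantum-efficiency correction between the calibration-source
and sample emission wavelengths.

The package also processes emission spectra (background subtraction,
Savitzky–Golay smoothing with a second-degree polynomial over a 25-channel
window, peak wavelength, FWHM from interpolated half-maximum crossings, and
SNR = maximum smoothed intensity / RMS of the raw−smoothed residual), and
implements the statistics used to report such measurements: geometric means
with back-transformed t-based 95% confidence limits of log-transformed
values, pooled and Welch two-sample t-tests (from raw data or printed
mean ± SD, *n* summaries), paired t-tests, and one-way ANOVA.

Because raw instrument records are rarely deposited, a synthetic-data module
generates flash records (smooth exponential rise × one- or two-component
exponential decay, Poisson counting noise over a dark-count background) and
single-peak spectra with known ground truth, together with a dense-grid
oracle (`ground_truth_kinetics`) that is independent of the binned analysis
path.

## Worked example

Simulate one 40-s record containing a flash in the measured dark-phase
regime of *P. kofoidii* (peak 3.87 × 10⁸ photons·s⁻¹ on a 2 counts/bin dark
background), then analyze it:

```sh
bioflash simulate flashes --seed 1 --out sim
printf 'threshold_sigma: 6.0\nmin_gap_bins: 100\n' > config.yaml
bioflash flashes sim/record_000.csv --config config.yaml --out out
cat out/flashes.csv
```

```
record_id,flash_index,rise_time_ms,max_intensity_photons_per_s,efold_time_ms,decay90_time_ms,duration_ms,integrated_photons,truncated
record_000,0,49.99992053,386516867.5,113.631047,283.6053562,333.6052767,55512507.96,False
```

The detected flash rises for 50 ms, peaks at 3.87 × 10⁸ photons·s⁻¹, falls
to 1/e of maximum in 114 ms and to 10% in 284 ms, and emits 5.55 × 10⁷
photons in total — within about one 10-ms bin of the noise-free dense-grid
values for the same model (47.3, 111.1 and 280.6 ms; 5.50 × 10⁷ photons).
The config raises the detection threshold to 6σ (a 3σ threshold triggers on
roughly a dozen single-bin Poisson background fluctuations over a 4000-bin
record) and merges above-threshold runs separated by less than 1 s, since
the slow luminescent tail of a flash re-crosses the threshold repeatedly.

The same statistics the tables of such studies print can be reproduced from
summaries alone, e.g. flashes per cell in dark (3.8 ± 2.6, *n* = 34) versus
light (3.6 ± 2.7, *n* = 37) phase:

```sh
printf 'label,mean,sd,n\ndark,3.8,2.6,34\nlight,3.6,2.7,37\n' > groups.csv
bioflash stats ttest-summary groups.csv
```

```
test_name,statistic,df,p_value
t_unpaired_pooled,0.3173598887,69,0.7518783938
```

i.e. *t* = 0.32, df = 69, *p* = 0.75 — no significant difference.

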