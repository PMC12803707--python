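# storysync

Analysis pipeline for naturalistic story-listening fMRI under varying
speech clarity: envelope and condition GLMs, leave-one-out intersubject
correlation (ISC), condition-trend inference over brain parcels, and
event-boundary epoch analysis — exercised end-to-end on synthetic
parcellated BOLD data with planted, recoverable effects.

## Who this is for

Researchers studying how speech masking (a story in twelve-talker babble at
clear, +14, +9, +4 and −1 dB SNR) changes cortical tracking, across-listener
synchrony, and the neural segmentation of a narrative into events. Human
story-listening data of this kind usually cannot be shared, so the package
ships a first-class simulator that reproduces the study's design —
pseudorandom 30–33 s clarity segments without immediate repeats, three
randomization versions, region-averaged time series at TR = 1 s over a
seven-network parcellation — with every analyzed effect planted at a known
magnitude, making the whole pipeline testable.

## The methods in brief

* **GLMs.** The speech amplitude envelope (mean |waveform| in 1 s bins) or
  per-condition boxcars are convolved with the canonical double-gamma HRF
  (gamma(6,1) − gamma(16,1)/6, peak at 5 s), fitted per region by OLS with
  one intercept per story, and reduced by a contrast: envelope regressors
  weighted 1, or condition regressors weighted by the clarity codes
  −2, −1, 0, +1, +2 (clear … −1 dB SNR).
* **ISC.** Time courses are shifted 5 s for the hemodynamic delay.
  Temporal ISC: segment-wise mean-centering, concatenation per condition,
  then each subject's course is Spearman-correlated with the average of
  all other subjects (leave-one-out). Spatial ISC: per-voxel time averages
  per condition, mean-centered across a region's voxels, correlated across
  subjects the same way. A quadratic fit of ISC on the clarity codes gives
  per-subject linear and quadratic trend coefficients.
* **Inference.** One-sample (or paired) t per region, converted to a signed
  z = Φ⁻¹(F_t(t)), thresholded two-sidedly at the Bonferroni cutoff
  Φ⁻¹(1 − α/m) — 3.89 for α = 0.05 over 1,000 regions. Epoch time-course
  tests use Benjamini–Hochberg FDR across the 21 offsets.
* **Event boundaries.** 21-sample epochs (−10..+10 s) around narrative
  event boundaries and event centers (midpoints between boundaries),
  summarized by the post-minus-pre contrast (mean over +1..+7 s minus
  −7..−1 s), compared by paired tests, split into high (clear, +14 dB) and
  low (+4, −1 dB) clarity for the interaction measure and a 2×2
  within-subject rmANOVA (Speech Clarity × Event Type).

## Worked example

```python
import storysync as ss

params = ss.SynthParams(seed=1)           # 20 subjects, 50 regions, 2 stories
ds = ss.simulate_dataset(params, include_voxels=False)

# leave-one-out temporal ISC per subject, condition and region
isc = ss.temporal_isc(ds.parcel, ds.schedule, shift_s=5.0)
print(isc.groupby("condition")["isc"].mean()
         .reindex(list(ss.CONDITIONS)).round(3))

# boundary-locked network time course
tc = ss.network_epoch_timecourses(ds.parcel, ds.events, ds.parcellation,
                                  "boundary")
grand = tc["frontoparietal"].mean(axis=0)
print("peak offset:", grand.idxmax(), "s")
```

which prints

```
condition
clear     0.533
+14 dB    0.462
+9 dB     0.359
+4 dB     0.297
-1 dB     0.222
Name: isc, dtype: float64
peak offset: 5.0 s
```

The ISC means fall monotonically with masking, following the planted
per-condition synchrony weights (λ = 0.6 … 0.2 from clear to −1 dB; the
leave-one-out correlation of a pure λ-mixture is
λ²/√(λ² + (1 − λ²)/(n − 1)), and the default dataset's planted envelope,
clarity and boundary responses — shared across subjects — add a further
common component), and the boundary-evoked response peaks 5 s after the
boundary, the latency of the canonical HRF.

The same pipeline runs from the shell:

```sh
storysync run --out out_dir --seed 1      # simulate + all analyses
storysync report --out out_dir            # print the run manifest
```

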