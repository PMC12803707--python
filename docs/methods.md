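# Methods

## The analysis model

The pipeline operates on region-averaged BOLD time series sampled at
TR = 1 s while listeners hear continuous stories whose speech clarity
changes every 30–33 s among five conditions (clear speech and speech in
twelve-talker babble at +14, +9, +4 and −1 dB SNR), with no condition
repeating immediately and three pregenerated randomization versions, so
that all listeners of one version hear identical stimuli. The five
conditions carry fixed codes −2, −1, 0, +1, +2 from clear to −1 dB; the
codes serve both as contrast weights and as the abscissa of trend fits, so
positive linear effects mean "grows with masking".

Four analysis families share this substrate:

1. **Envelope and condition GLMs.** The stimulus envelope is the mean of
   |waveform| in 1 s bins; regressors are convolved per story with the
   canonical double-gamma HRF, h(t) = γ(t; 6, 1) − γ(t; 16, 1)/6 on
   [0, 32] s, whose positive lobe peaks at (6−1)·1 = 5 s. Stories are
   concatenated row-wise with one intercept column per story (the
   15-condition + 3-intercept design for three stories); convolution is
   done before concatenation so no response bleeds across stories. OLS per
   region, then a contrast: envelope columns weighted 1, or condition
   columns weighted by their codes. Envelope regressors are z-scored per
   story so contrast magnitudes are comparable across stories.
2. **Leave-one-out ISC.** Every series is first shifted 5 s (BOLD at
   t + 5 attributed to stimulus time t) to compensate the hemodynamic
   delay; all segment windows are taken in stimulus time, a volume
   belonging to a segment when its midpoint falls in [onset, offset).
   *Temporal* ISC mean-centers each segment, concatenates same-condition
   segments across segments and stories, and correlates each subject's
   concatenated course with the element-wise average of all the others —
   averaging before ranking, Spearman with average ranks at ties.
   *Spatial* ISC time-averages each voxel within a segment, averages
   same-condition segments, centers across the voxels of a region per
   story, concatenates stories, and applies the same leave-one-out
   Spearman across subjects. Subgroups (randomization versions) are
   processed independently and pooled without recomputation. Zero-variance
   inputs yield missing (NaN) ISC, logged, never silent zeros.
3. **Group inference.** ISC-on-clarity trends come from an OLS quadratic
   fit over the five code points (plain monomials; at five symmetric
   points the linear coefficient equals its orthogonal-polynomial
   counterpart). Each per-subject scalar effect is tested with a
   one-sample t against zero; t maps to a signed normal equivalent
   z = Φ⁻¹(F_t(t)), computed on the smaller tail and capped at ±8.2 (the
   double-precision quantile limit, logged). Maps are thresholded
   two-sidedly at Φ⁻¹(1 − α/m); α = 0.05 and m = 1000 give 3.89.
   Time-course statistics use Benjamini–Hochberg FDR across the 21 epoch
   offsets instead.
4. **Event boundaries.** Epochs of 21 samples (−10..+10 s) are extracted
   around boundary times and around event centers (midpoints between
   consecutive boundaries) from the *unshifted* series, so the
   hemodynamic delay stays visible in the time course; event times round
   to the nearest volume, and epochs crossing a run edge are dropped
   (padding would bias the pre/post means). The summary statistic is
   post-minus-pre: mean over offsets +1..+7 minus mean over −7..−1
   (7 samples each). Boundary vs center is a paired t per region; the
   clarity interaction is (boundary_high − boundary_low) −
   (center_high − center_low), where an event is "high" if its onset lies
   in a clear/+14 dB segment, "low" in +4/−1 dB, and excluded from the
   split (only) in +9 dB. The 2×2 within-subject rmANOVA (Speech Clarity ×
   Event Type) is computed by the standard sums-of-squares decomposition,
   each effect tested against its effect-by-subject interaction with
   df (1, n−1); in a 2×2 design each F equals the squared paired t of the
   corresponding contrast, which the tests verify against an independent
   implementation.

## The synthetic-data generator

Real data of this kind cannot be shared, so the generator plants every
effect the analyses estimate:

* Region r of subject i carries the mixture
  `noise_sd · (λ_c(t) s_r(t) + √(1 − λ_c(t)²) ε_ir(t))`, with s_r a
  unit-variance shared story signal and ε unit-marginal-variance AR(1)
  noise (φ = 0.3 by default, a minimal stand-in for BOLD autocorrelation).
  Because both components have unit variance, the population leave-one-out
  correlation has the closed form `λ² / √(λ² + (1 − λ²)/(n − 1))`, which
  the tests use as an oracle (Spearman ranking shrinks it slightly, by
  ≈ 0.015 at λ = 0.8 — inside the ±0.03 Monte-Carlo tolerance used).
* Deterministic, subject-shared terms add the planted treatment effects:
  the z-scored HRF-convolved envelope times a per-region-set coupling
  (positive 0.5 in the "auditory" set, negative −0.25 in the
  "cingulo-opercular" set, matching the opposite-signed envelope tracking
  of sensory versus effort-related cortex), an HRF-convolved code
  regressor times a per-set slope (−0.2 / +0.2), and HRF-convolved unit
  impulses at boundary times scaled per network (3.0 in the planted
  networks; the HRF kernel peak is ≈ 0.175, so the transient is ≈ 0.52 of
  the unit noise SD — SNR ≈ 0.5). An optional negative pre-boundary dip
  (off by default) can model the pre-boundary decrease seen in
  frontoparietal cortex.
* Voxel blocks add a condition-specific spatial pattern
  `s_λ_c p_r + √(1 − s_λ_c²) q_irc` (shared profile p, subject profile q,
  both mean-centered across voxels) plus voxel noise centered across
  voxels at every volume, so the region series equals the voxel mean
  exactly.
* Schedules are balanced no-immediate-repeat orders drawn by a greedy
  sampler with restart; boundary times are uniform draws with a minimum
  gap (default 12 per story, ≥ 20 s apart); the "waveform" is 8 Hz
  low-passed Gaussian noise, a stand-in at the time scale of syllabic
  envelope fluctuations. Everything is a pure function of the seed.

Default scale — 20 subjects, 50 regions, 10 voxels/region, 2 stories of
4 segments per condition (600 s each), one randomization version per
dataset — is a desk-scale stand-in for the real study's 40 subjects ×
1,000 regions × 3 stories; a multi-version cohort is simulated by three
calls with disjoint subject ids and pooled ISC tables. One deliberate
extension: `sync_region_set` confines the per-condition λ profile to one
region set while all other regions get a flat λ (the profile mean), giving
"affected" and "unaffected but synchronized" regions for specificity
checks. The generator separates synchrony (λ) from mean activation
(condition slope) and does not couple them, since nothing in the study
design fixes such a coupling.

### What the generator does not emulate

Hemodynamic nonlinearity, spatial autocorrelation between neighboring
regions, physiological noise structure beyond AR(1), motion artifacts,
inter-subject latency differences, and any semantic structure in the
"stories". Passing tests therefore show that the *procedures* recover what
they claim from data obeying the stated model — not that real cortex
behaves like the model.

## Numerical and procedural choices

* Volume k covers [k·TR, (k+1)·TR); segment membership uses half-open
  intervals, so every volume belongs to exactly one segment.
* The 5 s shift drops the first five BOLD samples rather than padding;
  the usable stimulus span shrinks accordingly and trailing windows are
  truncated.
* The mean-of-others is averaged on raw (centered) values *before*
  ranking; ties get average ranks.
* Rank-deficient designs raise an error that names the collinear columns;
  missing ISC entries propagate as missing coefficients and reduce the
  group n, with counts logged.
* t → z uses the smaller tail of the t distribution for accuracy and caps
  |z| at 8.2.
* Simulation-based tests use scaled-down problem sizes (e.g., 6–21
  regions, 1 story, 300–900 s) chosen so each check's Monte-Carlo error is
  small relative to its tolerance; the boundary-latency result is reported
  as the modal argmax over 100 seeded runs of the default-scale dataset.

## Known limitations

* **Leave-one-out ISC values are not independent samples.** Any two
  subjects' ISC values share n − 2 subjects in their reference averages,
  and shared stimulus-locked signal makes all subjects' estimates move
  together. A one-sample t across them is therefore anticonservative: in
  a fully independent-subject null simulation the trend-coefficient t has
  SD ≈ 1.5 (nominal ≈ 1.06), and flat shared signal raises it further.
  This is a property of the procedure itself (one reason permutation
  schemes are sometimes preferred), so the calibration tests target maps
  whose per-subject values are independent under the null (boundary vs
  center), and specificity of the ISC trend is judged by separation of
  affected from unaffected regions rather than by a nominal false-positive
  count.
* **Mean activation is not perfectly separable from ISC.** Segment
  mean-centering removes activation *levels* exactly, but HRF transients
  at segment edges leak a little shared variance, quadratic in the planted
  slope; at the default coupling the leakage is below Monte-Carlo error,
  at implausibly large slopes it is measurable.
* Calibration statements (FWE ≤ nominal, FDR ≤ q) are asserted with
  Monte-Carlo margins (two binomial SEs, or the stated ±0.02), since a
  strict inequality on a finite simulation of an exactly calibrated
  procedure would fail about half the time.
* No prewhitening of GLM errors (AR(1) noise inflates per-subject
  coefficient variance but group tests across subjects remain valid); no
  voxel-level GLM; no cluster-extent inference; no permutation-based ISC
  z-scores.
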