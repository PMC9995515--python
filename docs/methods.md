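# Methods

This note documents the models, estimators and design choices behind
`rseeg`, in the spirit of the methods appendices that accompany simulation
and statistics packages.

## Preprocessing

Recordings are processed per subject × condition:

1. **Band-pass 1–50 Hz.** Zero-phase (forward–backward) Butterworth, order 8
   per pass. The order was chosen so that a 60 Hz line component retains less
   than 10% of its RMS after filtering (a 4th-order zero-phase filter leaves
   ~20% at 60 Hz, which is too permissive for a 50 Hz band edge); the
   pass-band at 10 Hz is flat to <1%.
2. **Common average reference (CAR).** Each sample has the instantaneous
   cross-channel mean subtracted; the operation is idempotent and requires
   at least two channels.
3. **Epoching.** Consecutive non-overlapping two-second epochs; the trailing
   partial segment is dropped (three minutes at any rate gives 90 epochs).
4. **Amplitude criterion.** An epoch is rejected if any channel exceeds
   75 µV in absolute value. The threshold is interpreted as absolute (not
   peak-to-peak) amplitude, and applied per epoch — the strictest reading; a
   subject × condition whose epochs are all rejected is excluded and logged.
5. **Spectral-power criterion.** After features are computed, a subject ×
   condition is excluded from statistics when its channel-averaged total
   1–50 Hz absolute power deviates more than 3 SD from its group mean for
   that condition. The exclusion is per condition: a subject excluded only in
   EC still contributes EO power features, but no reactivity (which needs
   both). The group SD includes the candidate subject; note a lone outlier
   can only exceed 3 SD when the group has ≳11 members (max attainable
   z is (n−1)/√n), which the study-sized groups comfortably satisfy.

ICA-based artifact correction and visual data inspection are deliberately
out of scope: they are manual steps that cannot be reproduced or tested; the
two quantitative criteria above are the testable surface.

## Spectral estimation

Per-epoch spectra are mean-removed, untapered periodograms scaled so the bins
sum exactly to the epoch variance. This makes Parseval's identity hold per
realization (the package asserts it to 1%) and puts a bin-centred sinusoid
entirely in its own bin (a unit-amplitude sinusoid carries 0.5 µV²). A taper
would trade these exact identities for less leakage; with 2 s epochs and
0.5 Hz resolution the band integrals of interest are 6–40 bins wide and the
untapered estimator is the simpler, exactly-testable choice.

Band powers use half-open intervals [f_low, f_high), so the five default
bands tile [1, 50) without double-counting boundary bins (a 4.0 Hz component
is theta, not delta). Absolute band powers are averaged over retained epochs
first; relative powers are formed from those averages and sum to 1 by
construction. Reactivity is computed from absolute band power by default
(`reactivity_source="relative"` switches to relative power; both preserve
the sign of a genuine EC > EO alpha difference).

Coherence uses Welch estimation over the same retained two-second epochs:
per-segment mean removal, periodic Hann taper, no overlap; the
magnitude-squared coherence is clipped to [0, 1] and averaged over band bins.
With L segments the estimator has an O(1/L) positive bias for independent
signals (≈0.011 at the study's 90 segments), which the tests calibrate
directly. Coherence is computed on CAR-referenced data, consistently with the
power pipeline (`coherence_car=False` disables that).

## The synthetic cohort generator

Each channel is a sum of independent band-limited Gaussian noise components
(white noise → 4th-order zero-phase Butterworth band-pass → normalized to a
configured RMS in µV, one component per band) plus a 1/f^β background shaped
in the frequency domain (flat below 1 Hz, unit-RMS normalized; β = 1 by
default, background RMS 3 µV). Eyes-closed differs from eyes-open only in
the alpha amplitude, scaled by a group-specific EC gain ≥ 1; noise
realizations are independent between conditions while subject-level
parameters are shared.

Inter-channel coherence is induced by a single shared alpha source. Channel
c's alpha component is `A · (√s · g_c · shared + √(1−s) · private_c)` with
shared fraction s ∈ [0, 1] and a balanced random ±1 topography g_c per
subject. The topography matters: a shared source that enters every channel
with the same sign *is* the channel mean, so CAR would cancel it exactly and
no planted coherence could survive re-referencing. With balanced polarities —
as with any physical dipolar source topography — per-channel variance is
preserved, pairwise magnitude-squared coherence is ≈ s², and the channel mean
stays near zero, so the planted effect survives CAR.

Per-subject band amplitudes get mean-one lognormal jitter (CV 0.15 by
default) to create between-subject variability. The study-like preset uses
33/28/20 subjects (never/past/current smokers), 180 s per condition at
500 Hz, 31 channels, and plants: a theta deficit in both smoker groups
(RMS 3.0/2.4/2.2 µV for never/past/smoker), higher alpha amplitude (4.6 vs
4.0 µV EO), higher EC gain (1.6 vs 1.3) and higher shared alpha fraction
(0.45 vs 0.25) in current smokers only. These amplitudes sit in the typical
adult rsEEG range and produce relative-power, reactivity and coherence group
contrasts of the same sign pattern as the study's findings. The zero-effect
preset uses the never-smoker parameters for all groups.

The exact 31-channel montage is not part of the ground truth (the study does
not print it); the default is a standard 10-20 extended layout with Cz
omitted from the 32-label set.

Covariates are drawn per group to the study's demographic means/SDs and
bounds, with per-group missing-at-random rates matching the reported
missingness, ordinal measures rounded, and smoking measures structurally
missing for never-smokers. Planted correlations are realized by a linear
blend: the covariate's standardized value is `Σ wᵢ zᵢ + √(1 − wᵀr) ε` with
weights solving `R w = r` for the empirical feature correlation matrix R, so
the within-pool correlation with each feature equals its target. Because the
final covariate is then scaled by *group-specific* means and SDs, group-mean
structure that aligns with group feature effects (e.g. current smokers have
both higher FTND and lower theta) adds covariance on top of the blend, and
realized pooled correlations can run noticeably stronger than the blend
target (FTND × theta: planted −0.40, typically ≈ −0.55 at n≈39). This is a
property of any cohort in which a covariate differs between groups that also
differ in the feature; the blend target should be read as the within-pool
component.

### What the generator does and does not emulate

It reproduces the second-order spectral structure the pipeline measures:
band powers, 1/f background, EC/EO alpha modulation, shared-source
coherence, covariate distributions and correlations. It does **not** emulate
blink/muscle/line artifacts (beyond injectable amplitude spikes used to test
rejection), non-stationarity, volume conduction or realistic source
topographies, spatially structured coherence, or heavy-tailed
between-subject distributions. Passing parameter-recovery tests therefore
demonstrates that the pipeline correctly measures and tests the planted
spectral structure — not that it is robust to real-world artifacts, and not
that the study's real-cohort channel-level significance patterns are
reproduced (those depend on the raw data).

One side effect of a genuinely spectral generator is band-edge leakage: the
boosted smoker alpha component leaks into adjacent theta/beta bins, so the
effect preset produces secondary group contrasts in neighbouring bands
(physically plausible, and absent in the zero-effect preset). Relative-power
normalization likewise couples bands: raising alpha lowers every other
band's fraction.

## Statistics

- **Omnibus test:** Kruskal–Wallis on mid-ranks with tie correction, p from
  the χ² approximation (k−1 df). All-identical data is a defined degenerate
  case (H = 0, p = 1). Empirical type-I error at α = 0.05 is verified to sit
  in (0.04, 0.06) over 10,000 null replicates.
- **FDR:** Benjamini–Hochberg step-up, controlled within one family = one
  feature kind × band × condition (31 channels; 465 pairs for coherence,
  treated as a single family).
- **Post-hoc:** Tukey HSD on the raw feature values, run only where the
  omnibus test survives FDR, mirroring the published pairing of a rank-based
  omnibus with Tukey comparisons; a rank-based Dunn procedure is available
  (`posthoc="dunn"`). For family-level reports the studentized-range p is
  interpolated on a cached 200-point log-sf grid per (k, df) — error ≤ 1e-3
  on p, negligible against any decision threshold — while the elemental
  `posthoc_tukey` uses exact evaluation.
- **Summary-statistic tests:** pooled-variance two-sample t (df = n₁+n₂−2)
  and one-way ANOVA reconstructed from group means/SDs/ns; the two-group F
  equals the squared pooled t (tested as an identity).
- **Mann–Whitney U:** U = min(U₁, U₂); exact null distribution for tie-free
  samples with n₁·n₂ ≤ 400, tie-corrected normal approximation otherwise.
- **Bootstrap correlation:** Pearson r on pairwise-complete observations;
  B paired resamples with replacement (B = 10,000 in the pipeline); 2.5–97.5
  percentile CI; two-sided p = 2·min(frac(r* ≤ 0), frac(r* ≥ 0)), floored at
  2/B and capped at 1. Resamples with zero variance (a constant draw) carry
  no correlation and are dropped. Null calibration: rejection rate at 0.05
  within (0.03, 0.08) over 1,000 simulations.
- Missing covariates are handled by pairwise-complete deletion.

## Problem sizes used by tests and the acceptance script

Stochastic parameter-recovery checks run the full pipeline on study-shaped
cohorts (33/28/20 subjects, 31 channels) scaled to 24 s per condition at
250 Hz (12 two-second epochs per condition); the generator's defaults remain
the study conditions (180 s, 500 Hz). Recovery is evaluated over 20 seeds
(tests) or 5 seeds (acceptance script); the zero-effect false-positive rate
over 10 (tests) or 4 (script) seeds × 25 families. Estimator calibrations
use 10,000 Kruskal–Wallis null replicates, 1,000 bootstrap-correlation
simulations, and 12 independent white-noise pairs of 90 Welch segments.

## Numerical and degenerate-input conventions

Half-open band bins resolve boundary ambiguity; ties use mid-ranks with tie
correction everywhere; coherence with a single segment is identically 1 and
is rejected as an error; zero retained epochs, zero total power, zero
variance, empty channel sets, and invalid filter bands raise labelled
ValueErrors rather than propagating NaN. EDF output quantizes to 16 bits
over each channel's observed range (error ≤ range/65535); the internal
`.npy` + JSON fixture format round-trips exactly.

## Known limitations

Group sizes below ~11 cannot trigger the 3 SD power criterion for a single
outlier (see above). The Kruskal–Wallis χ² approximation is used at all
sample sizes (groups ≥ 3 in practice). CAR slightly redistributes power and
induces a small negative correlation (−1/(n_ch−1)) between otherwise
independent channels, which the coherence floor tests account for. The
bootstrap p is a sign-crossing proportion, not an inverted CI, and is
granular at 2/B.
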