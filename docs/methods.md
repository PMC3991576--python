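# Methods

## Input model

The unit of analysis is a 5-minute RR-interval segment: positive beat-to-beat
durations in milliseconds with one annotation symbol per interval (`N` =
normal sinus beat). Files are plain text, one interval per line with an
optional label token; values whose median is below 10 are interpreted as
seconds and converted (PhysioNet RR exports are in seconds, most HRV tools
use ms). Segments are taken from the start of the record by default
(`extract_segment(start_s=0, duration_s=300)`); other offsets are exposed.

Ectopic-beat handling is available (`filter_normal_beats(policy="strict")`
drops non-`N` intervals and their successors, the standard normal-to-normal
rule) but **off by default**: the reference group statistics bundled with the
package — a CHF-group SDNN of 298 ms with RMSSD larger than SDNN — are only
consistent with unfiltered series, so the default matches the data the
pipeline is meant to reproduce.

## The 12 measures

Time domain: SDNN is the sample SD (n−1); RMSSD the RMS of successive
differences; pNN50 the percentage of successive differences **strictly**
greater than 50 ms with n−1 in the denominator; CVrr = 100·SDNN/mean.

Frequency domain: the tachogram (interval value against cumulative beat time)
is resampled at 4 Hz by cubic-spline interpolation, linearly detrended,
Hann-tapered, and a single full-length FFT periodogram is computed
(`SpectralConfig` exposes rate, detrend, window and a Welch segment length).
The PSD is rescaled so that its trapezoidal integral over [0, Nyquist] equals
the variance of the detrended resampled signal — an exact Parseval contract
rather than a window-dependent approximation. Band powers integrate the PSD
over VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4), VHF [0.4, 1.0) and
TP [0, 0.4) Hz with interpolated band edges, so TP = VLF + LF + HF exactly on
the raw scale. Powers are reported as `ln(1 + ms²)` by default: the reference
group values (VLF ≈ 5.7–7.3, LF ≈ 2.6–3.5) are only plausible on a log
scale, and the +1 keeps the transform defined at zero power. LF/HF is formed
on whichever scale is selected; a zero HF power makes it NaN.

Entropies: canonical ApEn (Pincus; self-matches included) and SampEn
(Richman–Moorman; self-matches excluded, one template range for both
lengths), with Chebyshev template distance, m = 2, delay 1 beat, and
tolerance r = r_coeff·SD with **r_coeff = 0.2**. A tolerance of one full SD
would be incompatible with the reference healthy-group SampEn of 1.21, which
matches the conventional 0.2·SD; r_coeff is configurable. Zero-variance input
is an error (r degenerates); SampEn with no length-(m+1) matches returns NaN
(the statistic is infinite), not an exception.

## Screening and combination

Group comparison uses Welch's unequal-variance t-test (two-sided), either
from raw per-record feature tables or directly from summary statistics
(mean, SD, n per group); the pooled-variance test is available by flag. Welch
reproduces the reference accept/reject partition — rMSSD, VHF and LF/HF
rejected at α = 0.1, nine measures kept. The reference table's printed
per-feature p values themselves are not exactly recoverable from its own
means and SDs under either test variant; the partition, not the p values, is
the contract. No multiple-testing correction is applied, matching the
original screening procedure.

The combination formulas

    SUM_TD = SDNN + pNN50 − CVrr
    SUM_FD = VLF + LF + HF + TP
    SUM_IE = ApEn + SampEn

were fixed by requiring them to reproduce all six published combined-feature
group means from the published per-measure group means (six independent
constraints, all satisfied within 0.05, the resolution of the printed
inputs); CVrr enters negatively because it moves opposite to SDNN and pNN50
between groups. Combination acts on **raw** feature values — the published
SUM_TD magnitudes (75.6 / 307.5) are on the ms scale — while min-max
normalization to [0, 1] is kept as optional classifier preprocessing (KNN
uses it internally; a constant vector maps to zeros with a warning).

## Classifiers

The SVM is the standard soft-margin dual with inhomogeneous polynomial kernel
K(u, v) = (u·v + 1)^d, d = 2 by default (the fixed published boundary is
quadratic in SUM_TD, and degree/offset are configurable). When C is not
given it is selected from a powers-of-ten grid (1e−2…1e3) by stratified
k-fold cross-validated accuracy, ties toward the smallest C, seeded fold
shuffling. Fitting is delegated to scikit-learn's `SVC`; the trained model is
stored in explicit dual form (support vectors, dual coefficients, bias) so
that JSON-serialized models predict without refitting, and predictions are
computed from that dual form directly.

The fixed boundary `Z = SUM_FD − (0.0001·SUM_TD² + 0.0208·SUM_TD + 9.3036)`,
`Z < 0 ⇒ CHF`, ships as the built-in model `published-boundary`. The
orientation (polynomial predicts SUM_FD from SUM_TD) is the one under which
the two published group-mean points fall on the correct sides
(CHF: Z ≈ −6.86; healthy: Z ≈ +12.33); points exactly on the curve are
healthy by the strict inequality.

KNN uses Euclidean distance on features min-max normalized with the
training-set ranges, k = 3 by default; distance ties break toward the lower
sample index and vote ties toward CHF (sensitivity-conservative). These tie
rules are explicit package choices — no reference prescription exists.

## Evaluation

ACC, PRE, SEN, SPE are the usual confusion-matrix ratios in percent with CHF
positive; zero denominators yield NaN rather than an error. AUC is the
single-operating-point convention (SEN + SPE)/2: it reproduces every
published AUC cell from that row's published SEN/SPE to the printed
precision, whereas a ROC-integral AUC is not computable from one confusion
matrix. Cross-validation pools held-out predictions into a single confusion
matrix (per-fold averaging is undefined for LOOCV); resubstitution pools
training-set predictions. A k-fold split whose training side loses a class is
reshuffled once, then rejected.

## Synthetic cohorts

`simulate_rr` modulates the RR value directly: mean level, a three-sinusoid
1/f-weighted VLF drift (2, 3 and 5 cycles per 300 s), an LF and a second
configurable oscillation, plus white beat-to-beat noise. `regularity ∈ [0,1]`
shifts weight between the deterministic components and the noise, and the
whole modulation is rescaled analytically so the expected series SD equals
`sd_target` (measured SDNN recovers the target within a few percent over
seeded replicates). Modulators are evaluated on the nominal beat-time grid
k·mean_rr (open loop): feeding each generated interval back into the clock
would phase-lock oscillations near half the beat rate and shrink their
realized variance. Deterministic given the seed; intervals are clipped
positive and parameter sets whose deterministic envelope reaches zero are
rejected.

The default ("separable") cohort is 17 CHF-like and 30 healthy records,
mirroring the reference cohort size. The healthy preset (mean RR 950 ms,
SDNN target 81 ms spread over VLF/LF/HF, moderate noise) lands near the
healthy reference statistics: SUM_TD ≈ 88, SUM_FD ≈ 30, SampEn ≈ 1.4. The
CHF-like preset (mean RR 1050 ms, SDNN target 298 ms) puts almost all of its
variance into a **regular 0.45 Hz oscillation — inside the VHF band — 
mimicking beat-to-beat alternans**. That is the only way a self-consistent
generator can reproduce the reference CHF signature simultaneously: an
anomalously large SDNN *and* RMSSD > SDNN (anticorrelated successive beats)
*and* small VLF–HF band powers (low SUM_FD) *and* low entropy. Placing the
variance anywhere in 0–0.4 Hz would drag SUM_FD above the healthy class.
Consequences of this design: the generated CHF class has a pipeline-consistent
CVrr (≈ 28, not the reference table's 3.79, which is arithmetically
inconsistent with its own SDNN and any plausible mean RR) and a near-100
pNN50, so its SUM_TD (≈ 366) is higher than the printed 307; the geometry —
CHF far to the right and below the healthy cluster in the (SUM_TD, SUM_FD)
plane, linearly separable — is preserved, which is what the classifier layer
consumes. An "overlapping" preset with a milder CHF class exists for
non-separable experiments.

The generator is *not* physiological: no integral-pulse-frequency
modulation, no respiratory coupling, no ectopy morphology. Passing tests
therefore demonstrate the pipeline's correctness and the published decision
geometry, not clinical performance on real recordings.

## Problem sizes and determinism

The test suite and the acceptance script run on 5-minute segments
(~280–320 beats), cohorts of 47–60 records, 50-replicate calibration loops
and 200-replicate null-screen simulations; entropy implementations are
vectorized O(N²) and validated against brute-force loop oracles to 1e−10 at
N ≤ 400. All randomness flows through explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence.spawn`), so identical seeds give
bit-identical cohorts and fold splits.

## Known limitations

- The published cohort-level accuracies (e.g. 100% LOOCV on the original 47
  PhysioNet subjects) are reproduced on the synthetic separable cohort, not
  on the original recordings, whose selection and evaluation protocol are
  unpublished.
- The reference table's CHF CVrr and its printed per-feature p values are
  internally inconsistent; the package reproduces the derived contracts
  (accept/reject partition, combined-feature means) rather than those cells.
- Spectral estimates use a single Hann periodogram by default; the original
  FFT windowing/averaging is unstated, so absolute band powers of real
  records may differ from the reference values even for identical data.
- `lf_hf` on the log scale is a ratio of logs, chosen for consistency with
  the reference table's magnitudes; it is not the conventional raw-power
  ratio.
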