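# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `hypnohrv`, in the order data flows through the
pipeline.

## Signal model and preprocessing

ECG is modelled as a single channel sampled at ≥100 Hz (125 Hz in all
defaults, matching common polysomnography hardware). The acquisition
band-pass is a zero-phase (forward–backward) Butterworth filter,
default 0.5–45 Hz, order 4; zero-phase filtering is used throughout so
R-peak timing is not biased by group delay.

**R-peak detection** follows the Pan–Tompkins recipe: 5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, then adaptive
dual thresholds. The signal/noise running peak estimates are initialised
from the first 2 s of the integrated signal (SPKI = max, NPKI = mean;
threshold = NPKI + 0.25(SPKI − NPKI)), updated with the standard
0.125/0.875 exponential weights, with a 200 ms refractory period and a
search-back that accepts the best sub-threshold candidate above half
threshold whenever 1.66× the running RR average elapses without a beat.
Accepted peaks are refined to the local maximum of the band-passed input
within ±100 ms, which on synthetic Gaussian-QRS signals recovers beat
positions to the sample.

**Artifact handling.** The detection rule for ectopic/artifact beats is a
local-median test: a beat is flagged when its relative deviation from the
median of a centred 11-beat window exceeds 20 %. This is a standard
ectopic detector chosen because it needs no rhythm model and one
threshold; it reliably catches the premature-beat + compensatory-pause
pattern. Flagged beats are replaced by a cubic spline fitted over the
unflagged neighbours (beat index as abscissa); unflagged beats are never
modified, and a consecutive flagged run longer than half the series
raises an uncorrectable-segment warning. Recordings whose flagged
fraction *strictly exceeds* 20 % are excluded (exactly 20 % is kept).
The hypnopompic window is the half-open interval
[wake − 3600 s, wake), with beat membership decided by cumulative RR
time at the end of each interval.

## Linear HRV metrics

SDNN is the sample standard deviation (n−1 denominator) of all RR
intervals of the hour; RMSSD the root mean square of successive
differences. Spectral analysis operates per 5-minute segment (beats
assigned by interval start time; trailing partial segments dropped, so
one hour yields 12 segments): the tachogram is cubic-spline resampled to
4 Hz, linearly detrended, and a Welch periodogram (Hann window, 2-minute
sub-windows, 50 % overlap) is integrated by the trapezoidal rule over
bins whose centres fall in TP 0.003–0.4 Hz, LF 0.04–0.15 Hz and HF
0.15–0.4 Hz; the boundary bin at exactly 0.15 Hz belongs to HF.
HFnorm = HF/(LF+HF)×100, and band powers are averaged arithmetically
over segments. On a pure 0.10 Hz, 50 ms-amplitude tachogram this
recovers the Parseval value A²/2 = 1250 ms² within a few percent.
No PSD dialect is canonical for RR spectra; this one is standard
short-term practice and is fixed here so results are reproducible.

## Entropy metrics

**Sample entropy.** SampEn(m, r) = −ln(A/B), where B counts ordered
template pairs (i < j, both drawn from the N − m templates that admit an
extension) matching at length m under Chebyshev distance ≤ r
(inclusive), and A those that still match at length m + 1. Self-matches
are excluded. Defaults m = 2, r = 0.15·SD with SD the sample standard
deviation of the original series. When A or B is zero the value is
undefined and returned as NaN — never infinity — and subjects with any
undefined feature are dropped from modelling with a logged count. The
pair-counting kernel is a compiled double loop (numba); the test suite
holds it to *exact* equality with an independent pure-Python
pair-counting oracle.

**Multiscale profile.** For scales τ = 1..10 the series is coarse-grained
by non-overlapping τ-point averages and SampEn evaluated with the *same*
r fixed from the original series (no per-scale renormalisation). This
makes the profile scale-dependent in the informative way: white noise
loses variance under averaging relative to the fixed tolerance, so its
profile decreases strictly with scale, whereas 1/f noise keeps its
complexity and stays approximately flat — the classic signature the
multiscale analysis exists to detect.

**Modified permutation entropy.** Overlapping m = 4 vectors (delay 1)
are mapped to tied-rank ordinal patterns: each element's symbol is the
count of strictly smaller elements in its vector, so equal values share
a symbol. MPE is the Shannon entropy of the empirical pattern
distribution in **base 2**. There are exactly 75 tied-rank patterns of 4
items (verified by exhaustive enumeration), hence 0 ≤ MPE ≤ log₂75 ≈
6.23 bits; a tie-free i.i.d. series approaches log₂24 ≈ 4.58 bits. The
base and the unit delay are not universal conventions; base 2 is adopted
because published MPE magnitudes for RR series (≈5.6) exceed ln 75 and
are only attainable in bits, and delay 1 is the default of the tied-rank
formulation. Values above log₂24 require tied samples — which is
precisely the situation for RR intervals quantised by a 125 Hz sampling
grid (8 ms ticks), and the reason the tied-rank variant is used instead
of classic permutation entropy.

## Cohort statistics

Continuous variables pass through a Lilliefors normality gate per group:
the statistic is the Kolmogorov–Smirnov distance of the sample
(standardised by its own mean and SD) from the standard normal, and the
p-value comes from a Monte-Carlo null of 10,000 simulated normal samples
of the same size under a fixed internal seed (p = (1 + #{D₀ ≥ D})/10,001),
cached per sample size. A t-test is used when both groups pass at
α = 0.05, otherwise the two-sided Mann–Whitney U test; summaries mirror
the gate (mean ± SD vs median [Q1, Q3]). Categorical variables get a
chi-square test on the contingency table.

Similarity between an under-sampled control subset and its parent is
reported per variable as the two-sample KS statistic with asymptotic
p-value plus the Jensen–Shannon divergence of shared-bin histograms
(Freedman–Diaconis bin width on the pooled data, minimum 10 bins,
zero cells smoothed with machine-epsilon mass, base-2 logs so
JSD ∈ [0, 1]).

## Prediction pipeline

Feature vectors hold 11 clinical covariates (age, gender, BMI, height,
waist/hip ratio, smoking status, lifetime cigarette smoke, diabetes,
hypertension, AHI, RDI; categorical encodings declared in
`CATEGORY_CODES`) and 10 HRV metrics (TP, LF, HF, HFnorm, SDNN, RMSSD,
MSE1, MSE2, MSE10, MPE). For the short-term setting the control group is
under-sampled uniformly to the case count; draws are repeated (up to
100, deterministic seed sequence) until every continuous feature has
KS p > 0.05 against the full control group, else the best draw is
returned with a warning.

Cross-validation is stratified 5-fold (folds differ in size by ≤1; with
70 + 70 subjects every test fold is 14 + 14). Plain random folds would
occasionally produce heavily skewed class counts at these sample sizes,
and the published per-fold percentages are all multiples of 1/14, which
is what stratification yields. The learner is XGBoost with declared
defaults — max depth 3, learning rate 0.1, 100 rounds, logistic
objective, histogram trees, single thread — and a 0.5 probability
threshold. All stage randomness (under-sampling, folds, learner) derives
from one seed via a `SeedSequence` expansion.

Performance is computed from per-fold confusion matrices (Positive =
event group): ACC, TPR, TNR, PPV, F1 = 2·PPV·TPR/(PPV+TPR) and MCC.
Zero-denominator cells return 0 with a warning and MCC is 0 when any
marginal vanishes, keeping fold averages defined. Averaged metrics are
field-wise arithmetic means over folds. Feature importance is the number
of times a feature splits a tree node, pooled over the k fold models and
normalised to sum 1. Relative changes between models are
(new − reference)/reference × 100, formatted to one decimal in reports.

## Synthetic data: what it emulates, and what it does not

The RR generator superimposes a ~0.1 Hz LF sinusoid, a ~0.25 Hz HF
sinusoid and spectrally shaped 1/f^β Gaussian noise on a constant mean
RR, evaluated at nominal beat times; β is the single complexity knob
(0 = white, 1 = pink). Ectopic contamination shortens selected beats by
half and adds the removed time to the next beat; the truth mask marks
the shortened beats. ECG fixtures place Gaussian QRS templates
(σ = 12 ms) at prescribed beat times.

Cohort baselines match the published control-group summaries: age,
height, waist/hip ratio normal; BMI, AHI, RDI log-normal with location
and spread fitted to the printed medians and quartiles; gender, smoking
status, diabetes, hypertension Bernoulli/multinomial at the printed
percentages; pack-years zero for never-smokers and log-normal otherwise.
Study-condition defaults for the RR dynamics are mean RR 1000 ms, LF
amplitude 32 ms, HF amplitude 25 ms, noise SD 55 ms (SDNN ≈ 62 ms),
β = 0.5, and — for cohorts — RR values quantised to 8 ms, the beat-time
resolution of a 125 Hz ECG. The quantisation matters twice: the
tolerance r = 0.15·SD ≈ 9 ms must stay above the 8 ms tick for sample
entropy to behave continuously, and the resulting ties are what lift MPE
above the tie-free ceiling of log₂24 into the published ~5.4–5.6 bit
range.

Case-group effects shift covariates toward the published event-group
values and alter the RR dynamics by lowering LF/HF amplitudes and total
noise while raising β. The consequences reproduce every published HRV
contrast direction: LF, HF, SDNN, RMSSD, MSE1 and MSE2 fall; the flatter
(more 1/f-like) profile raises MSE10; and reduced variability on the
fixed quantisation grid produces more ties, raising MPE. Effect sizes
are deliberately larger than the real cohort's (which are a few percent
at the median), so that desk-scale cohorts of 40–140 subjects separate
reliably; synthetic cross-validated accuracies therefore run well above
the ~81 % reported on clinical data, and passing tests demonstrate
*recovery of planted structure*, not clinical-grade effect sizes. The
generator does not model sleep staging, apnea events, circadian drift,
non-stationarity within the hour, or realistic multi-lead ECG
morphology.

## Numerical and design choices

- SampEn template pairs are drawn from the N − m templates admitting an
  (m+1)-extension (the common computational convention); documented
  because the alternative (all N − m + 1 templates for B) shifts values
  slightly at small N.
- Sinusoid phases in the RR generator are randomised per seed so
  replicate series are not phase-locked.
- Segment assignment, band-edge ties (0.15 Hz → HF), the strict >20 %
  exclusion, and the half-open hypnopompic window are all deterministic
  tie-break rules chosen once and tested.
- Lilliefors Monte-Carlo rather than approximation formulas: exact by
  simulation at any n, at the cost of a one-off per-n table (cached).
- Undefined entropies propagate as NaN and the subject is dropped; no
  imputation anywhere.
- Problem sizes in tests and the acceptance script (cohorts of 40–300
  subjects, 10–60-minute RR series, 50–200 Monte-Carlo replicates) are
  desk-scale choices that keep the full suite fast while leaving every
  statistical check comfortably powered.

## Known limitations

- Absolute spectral powers depend on the PSD dialect (resampling rate,
  window, detrending); published absolute band powers are therefore only
  directionally comparable.
- The published per-fold classification values are not exactly
  reproducible even in principle: fold membership, learner
  hyperparameters and the under-sampling draw of the original study are
  unknown. The package reproduces the *arithmetic* among printed values
  exactly and the *qualitative* conclusions (short-term > long-term,
  HRV features indispensable for short-term prediction, entropy metrics
  ranking high in importance) on synthetic cohorts.
- The artifact-detection rule and interpolation order stand in for an
  unpublished method; both are documented knobs.
- MPE's base and delay are inferred conventions (see above).
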