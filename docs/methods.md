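# Methods

This note documents the models, defaults and numerical choices behind
`ecgstress`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The classification problem

Each observation is a 10 s single-lead ECG window labeled rest (0) or
stress (1). Two nested candidate feature pools are compared:

* **TFM pool (24 features)** — time-domain HRV statistics of the R-R (NN)
  interval series: MeanNN, SDNN, RMSSD, SDSD, CVNN = SDNN/MeanNN,
  CVSD = RMSSD/MeanNN, MedianNN, MadNN = 1.4826·median|RR − median|,
  MCVNN = MadNN/MedianNN, IQRNN, 20th/80th percentiles, MinNN, MaxNN,
  RangeNN, pNN50/pNN20/pNN10 (percent of successive differences strictly
  greater than the threshold), TINN, HTI, SDNN/RMSSD, skewness, kurtosis,
  and mean |successive difference|. Units: ms for intervals, % for pNN,
  dimensionless otherwise. Sample (n−1) standard deviations throughout.
* **NFM pool (36 features)** — the 24 above plus the mean and sd of the six
  within-beat apex-to-apex intervals PR, PS, PT, QS, QT, ST (ms), measured
  per beat on beats where both waves are present (≥ 3 beats required,
  otherwise the window fails quality filtering).

Naming notes. Two textual definitions circulating for these features are
deliberately not followed: MedianNN is the median of the RR intervals
themselves (not of successive differences), and pNNxx counts successive
differences, not raw intervals. "PS sd" is the sd of the P–S interval.

TINN is the base width M − N of the least-squares triangular fit to the RR
histogram (bin width 7.8125 ms = 1/128 s, configurable), apex pinned at the
modal bin, with (N, M) searched exhaustively over bin edges; HTI is the RR
count divided by the modal bin count. Both follow the classical geometric
definitions; on 10 s windows (≈ 12 beats) they are coarse, which is
faithful to how they behave on short windows generally.

Features are z-scored per column over the full table, pooled across
participants and conditions ((x − mean)/sd, sample sd). A train-only
scaling variant is not provided; pooled scaling is the package's single
convention and is idempotent to 1e-9.

## 2. Model selection and comparison

Selection is bidirectional stepwise AIC minimisation starting from the
empty set: at each iteration every single addition and single removal is
scored and the move with the lowest resulting AIC is applied; the search
stops when no move lowers the AIC (ties broken by candidate order, so the
procedure is deterministic given the table). The accepted-move AIC sequence
is strictly decreasing by construction. On ≤ 6 candidates the result is
verified in tests against exhaustive enumeration of all 2⁶ subsets.

The fit behind each AIC score is, by default, a maximum-likelihood logistic
regression (binomial likelihood; k = p + 1 parameters). A Gaussian option
fits an OLS linear-probability model instead (k = p + 2, counting the
residual variance); its log-likelihood can make AIC large and negative when
residuals are small, which is the regime that produces AIC scores in the
−2000 range on ~1000-row tables. The relative-likelihood comparison
exp((AIC_min − AIC_max)/2) ∈ (0, 1] is likelihood-family-agnostic and is
reported with explicit orientation ("the worse model is R times as probable
as the better to minimise information loss"). Model AICs for the final
TFM-vs-NFM comparison are evaluated on the reserved 33 % test split, after
selection on the 67 % training split.

Perfect separation under the binomial likelihood is detected (non-finite
standard errors or a log-likelihood at its supremum) and handled by
refitting with a light ridge penalty; such fits are flagged
(`separation=True`) and carry NaN p-values.

Per-feature validity is the point-biserial correlation
r_pb = ((M₁ − M₀)/s_n)·√(n₁n₀/n²) (population sd), identical to the Pearson
correlation with the 0/1 coding (verified to 1e-12 in tests); its p-value
uses the t transform with n − 2 df. No multiple-testing correction is
applied; p-values are reported raw.

Classifier benchmarks run LDA, logistic regression and SVC under stratified
k-fold CV (default k = 10, shuffled with a logged seed) on the reserved
test portion by default (`cv_scope="full"` uses the whole table). SVC
ranking scores for AUC come from the decision function. A 67/33 stratified
split precedes everything; folds require both classes (≥ k minority rows).

## 3. Delineation

R peaks: 5–15 Hz band-pass, derivative, squaring, 150 ms moving-window
integration, candidate peaks at ≥ 200 ms spacing, adaptive acceptance at
0.5 × an exponentially-weighted running mean of accepted integrated peaks
(initialised from the first 2 s), then refinement to the raw-signal apex
within ±100 ms.

Small waves, per beat (all bounds in ms, configurable in `SearchConfig`):

| wave | window | rule |
|---|---|---|
| Q | (R − 80, R) | most negative |
| S | (R, R + 80) | most negative |
| P | (max(R − 300, prev R + 410), R − 80) | most positive |
| T | (S + 80, min(R + 450, next R − 100)) | most positive |

A wave is *missing* when its excursion from the local segment median is
below 2 % of the beat's R amplitude (configurable). Beats whose search
windows would cross the signal edge are dropped. The `prev R + 410 ms`
clamp on the P window mirrors the `next R − 100 ms` cap on the T window: at
short RR a fixed 300 ms lookback would otherwise reach into the preceding
beat's T wave, whose tail can exceed the P apex — 410 ms is the latest
typical T apex (~330 ms) plus two T widths. A window passes quality
filtering when ≥ 5 beats (configurable) have all required waves present;
this makes the "reliably detected" exclusion reproducible.

Detection scoring matches detected to reference peaks one-to-one, nearest
pair first, within ±50 ms by default (a common beat-matching convention);
greedy matching is verified against brute-force optimal assignment in
tests. Precision with zero detections is 0 by convention. Study-level
evaluation samples 10 participants (seeded), pools counts over windows, and
restricts scoring to beats whose R lies in the delineator's valid region —
edge beats are undetectable by construction, so including them would score
the evaluation geometry, not the detector. Detectability analyses in the
tests and acceptance script use a ±20 ms tolerance: Q's search window is
only 80 ms wide, so under the looser 50 ms default every in-window Q
detection trivially matches and noise vulnerability would be invisible.

## 4. The synthetic study generator

Each beat is a sum of five Gaussians; each wave has an amplitude (mV), apex
offset from R (ms) and width (ms, Gaussian sd). Wave placement is driven by
four primitive apex-to-apex intervals — PR, QR, RS, ST — each with an
independent per-beat Gaussian jitter; every measurable interval decomposes
into primitives (PT = PR + RS + ST), so the planted six-interval structure
is exact while interval jitters remain only weakly coupled (this is what
makes low cross-correlation among small-peak features a plantable,
testable property). Six intervals over four waves anchored at R would be
overdetermined, hence the primitive parameterisation.

RR intervals follow a stationary AR(1) Gaussian process (mean, marginal sd,
lag-1 autocorrelation; clipped below at 200 ms), giving closed-form targets
for MeanNN/SDNN/RMSSD. Ground truth records the planted RR series, the
per-beat wave sample indices (rounded apex positions) and the label;
delineation can therefore be scored exactly.

Defaults (rest): RR 850 ± 50 ms, autocorrelation 0.3; PR 160 ± 6,
QR 40 ± 1.5, RS 40 ± 1.5, ST 260 ± 10 ms; amplitudes P 0.22, Q −0.08,
R 1.0, S −0.25, T 0.35 mV; widths 22/10/8/10/36 ms. Stress multiplies mean
RR by 0.95, RR sd by 0.7, interval means by 0.92 and interval sds by 0.7 —
a mild acute stressor: heart rate up a few beats per minute, variability
damped, conduction intervals shortened and tightened, so every
interval-based feature correlates negatively with the label. The narrow R
width (8 ms) keeps the R tail's pull on the Q/S apices below one sample, so
planted indices are exact extrema; the T apex at R + 300 ms keeps the
preceding T out of the P search region at these heart rates.

Participant-level variation (drawn from the master seed): per-wave
amplitude factors (Q by far the widest spread, factor 0.35–1.8 — Q waves
genuinely vary from prominent to near-absent across subjects, and this
drives the between-participant spread of Q detectability; the Q floor
0.35 × 0.08 = 0.028 mV stays above the delineator's 2 % prominence floor so
clean recordings remain fully delineable), width factors ±5 %, one common
interval-scale factor (0.9–1.1) and an RR-scale factor (0.9–1.15). Windows
are synthesized back-to-back into one continuous recording per participant
with an event log, stress and rest alternating.

Noise model: additive white Gaussian noise (default 0.1 mV — a noisy
wearable recording; after the 0.3-Nyquist low-pass the surviving in-band
noise is of the same order as the Q amplitude, so Q detectability degrades
first while P (0.22 mV) and T (0.35 mV) mostly survive), baseline wander
(0.05 mV at 0.25 Hz), powerline hum (0.01 mV), and Poisson motion-artifact
bursts (2/min, 0.4 mV, 150 ms Gaussian envelope).

What the generator does **not** emulate: real P/QRS/T morphology (no
asymmetric T, no biphasic waves), respiration-coupled RR dynamics, ectopic
beats, electrode-contact dropouts, or QT-RR coupling. Passing tests
therefore demonstrate that the pipeline recovers planted structure under a
controlled model of this study design — not that the classifiers would
reach the same operating points on real recordings.

## 5. Preprocessing choices

The "normalized cutoff 0.3" Butterworth is implemented as a low-pass at
0.3 × Nyquist (the conventional reading of a bare normalized Wn); the pass
type and cutoff are config-exposed since a high-pass reading is also
defensible. Filtering is zero-phase (filtfilt), because the features are
wave latencies and a causal filter would shift them; the two passes square
the magnitude response. The digital filter's closed-form magnitude uses the
bilinear-prewarped ratio tan(πf/2)/tan(πWn/2) — the analog ratio f/Wn
noticeably misstates the attenuation near Nyquist, and the tests assert the
warped form. Windows are anchored at event start (deterministic); events
shorter than the window are skipped with a logged warning.

## 6. Problem sizes and determinism

Everything is reproducible from a single master seed: the study generator
spawns one stream per participant and per window, and CV splits take an
explicit seed. The test suite and the acceptance script run scaled-down
studies chosen to keep a full run fast on one CPU while leaving the
measured properties stable across seeds: the full 57 × 32 layout is
generated at 250 Hz for the accounting checks; delineation fidelity uses
6 participants × 8 windows (zero noise) and 14 × 16 (default noise) at
500 Hz; validity-sign replication uses 100 ground-truth-only studies of
4 × 8 windows; the end-to-end model comparison uses 12 × 16 windows at
500 Hz. At 500 Hz and above, the low-pass cutoff (0.3 × Nyquist ≥ 75 Hz)
leaves the narrowest wave (R, 8 ms Gaussian) essentially undistorted.

## 7. Known limitations

* The AIC magnitudes of the default binomial fits are in the tens, not the
  −2000 range; reproducing the latter requires the Gaussian/OLS likelihood
  option and a comparable sample size.
* Stepwise AIC is a greedy heuristic; equality with best-subset search is
  guaranteed only where tested (small candidate sets with one strong
  signal).
* The quality filter's pass rate on synthetic data is near 100 % at the
  default noise level; it does not emulate the heavy attrition (≈ half of
  windows) seen with real wearable recordings.
* `window_quality` and the missing-wave rule interact: a wave below the
  prominence floor at zero noise can be "found" once noise lifts its
  excursion past the floor, so detectability is not strictly monotone in
  noise for sub-floor morphologies (the defaults avoid that regime).
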