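# Methods

This note documents the models, numerical choices and open design
decisions behind the package, and what the synthetic test bed does and
does not establish about real recordings.

## Conventions

Time is in seconds from record start, 0-based sample indexing; inter-beat
intervals are in milliseconds (the HRV/HRT convention). Records are tiled
into non-overlapping analysis segments (default 3600 s); a trailing
remainder is flagged partial and excluded by default (`allow_partial`
overrides). All thresholds live in one `PipelineConfig` (YAML-loadable);
there are no hidden constants.

## Signal quality gate

**ECG image grade.** Leads are rastered in paper-ECG layout (25 mm/s,
10 mm/mV, 4 px/mm, 30-mm strips, first 10 s of the segment) over a 1-mm /
5-mm grid. Similarity between two multi-lead images is the mean of
global-statistics SSIM over all M×M lead-strip pairs; consequently the
self-similarity of a multi-lead image is below 1 whenever its leads differ
from one another (the identity holds exactly for single-lead images). The
SSIM stabilizing constants are the standard K1 = 0.01, K2 = 0.03 relative
to the configured dynamic range; a literal reading of alternative
constants is available through the same config. Good/poor template images
are produced by average-linkage agglomerative clustering on (1 − SSIM)
within each quality group (default 3 clusters per group; the count is a
config key because no principled value exists), each cluster represented
by the member with maximal mean similarity to the cluster (ties to the
lowest index); an LDA classifier over SSIM-to-template feature vectors
makes the grade. When labelled training images are absent, an initial
good/poor partition is available as 2-means on mean pairwise similarity.

**Lead selection.** Per lead: bSQI = Jaccard agreement (150-ms matching)
between the pipeline QRS detector and an independent amplitude-threshold
picker; sSQI = Welch power fraction in 5–14 Hz relative to 1–40 Hz (the
QRS-energy band convention — the choice matters little for ranking leads);
kSQI = excess kurtosis. Each SQI is min–max scaled across leads and
combined by configurable weights (default equal); argmax wins, ties to the
lowest lead index.

**ABP pulse validation.** Pulses (onset to onset; onset = minimum within
0.5 s before each systolic peak) are spline-resampled to P = 100 points
and standardized to zero mean, unit SD. The signal subspace is the
smallest set of leading right-singular vectors of the reference pulse
matrix holding ≥ 95% of the energy; a pulse's score is the ratio of energy
inside the subspace to the residual energy (capped at 1e12 when the
residual vanishes), and the validity threshold is the minimum score over
the reference pulses themselves — so every reference pulse is valid by
construction. The packaged reference library is **synthetic**: 200
canonical arterial pulse shapes (fast systolic upstroke, exponential
diastolic decay, dicrotic bump) with physiological spread, generated from
a fixed seed. It is a stand-in, not clinical reference data; any
user-supplied pulse list fits the same interface. A segment passes when
the ECG image grades good **and** ≥ 80% of its ABP pulses are valid
(ABP-only mode drops the ECG criterion).

## Beat detection

QRS detection: 2-s windows advancing 1 s → 0.5–17 Hz Butterworth band-pass
(zero-phase) → correlation with a zero-sum enhancement kernel (−1 flanks,
+2k centre; half-width k = round(0.05·fs), i.e. 50 ms, spanning a QRS
upstroke) → per-window min–max normalization → scan of 0.3-s ranges with
threshold 0.5 **in normalized units** (an absolute millivolt threshold
after normalization to 1 would be contradictory) → R peak as the filtered
extremum within a 0.24-s interval at the fiducial. Overlapping windows are
deduplicated by a 0.2-s refractory that keeps the stronger candidate;
window edges are zero-padded. Systolic ABP peaks: Savitzky–Golay smoothing
(0.2 s, order 3) then prominence-gated maxima with a 0.3-s refractory; the
reported sBP is the smoothed amplitude. Non-pulsatile input (range < 5
units) returns no beats.

PVC labelling is rule-based and two-stage. Stage 1 flags beats meeting at
least two of: width > 120 ms (measured at half the beat's own peak
deviation), amplitude > 1.5× the median beat, correlation with the median
beat < 0.9 (all three are config keys; only qualitative guidance exists
for them). Stage 2: a solitary candidate still correlating ≥ 0.9 with the
median beat is demoted; with multiple candidates, widths (cW) are measured
at three-fourths the height of the smallest candidate, and a candidate is
kept only if its morphology deviation exceeds the **median deviation of
all beats** and its cW exceeds the **mean cW of all beats**. Comparing
against the full beat population rather than the candidate subset is
deliberate: a run of similar ectopic beats must not demote itself. A
plug-in hook accepts any external PVC-segment classifier (none is bundled;
by default every segment is scanned).

## Variability and turbulence

RMSSD uses successive differences only across temporally adjacent
intervals — excluding PVC-adjacent intervals leaves gaps, and differencing
across a gap would fabricate large deltas. Spectra use the Lomb–Scargle
periodogram on the mean-subtracted tachogram at its native uneven beat
times (grid 0.003–0.5 Hz, step 0.001 Hz), scaled by 2/(mean beat rate) so
the integral over the grid approximates the interval variance; band edges
are half-open [0.04, 0.15) / [0.15, 0.4]. LF/HF is reported missing when
HF power < 1e-6 ms² to avoid division blow-up.

HRT events require 2 sinus intervals before the coupling interval and 15
after the compensatory pause, plus couplI < the preceding sinus interval
and compI > it; a strict mode adds the classical filters (coupling ≤ 80%
and pause ≥ 120% of the reference, context intervals within 300–2000 ms).
TO and TS follow the standard definitions (TS = maximum least-squares
slope over the 11 five-interval windows among RR₁..RR₁₅; it may be
negative). Segment HRT runs only when the **detected** PVC count exceeds
10 — the gate counts PVCs before eligibility filtering — and means are
taken over eligible events only.

## Baroreflex sensitivity and coherence

PRSA: anchors are beats whose paired sBP strictly exceeds its predecessor
(equal values are not anchors); anchors within L = 15 beats of either edge
are excluded so the full offset window l ∈ [−L, L] exists (the 15-beat
window is read as 15 per side, satisfying the offset range of the
averaging formula). BRS is the quarter-sum (X₀+X₁−X₋₁−X₋₂)/4 of the
averaged profile. Useful oracle: for a ±1-mmHg random-walk pressure with
static gain G, the conditional expectation of the quarter-sum is G/2.
RR intervals are paired to the nearest ABP fiducial within 0.5 s;
unpaired intervals are dropped from BRS analysis.

ARX: RR_k = Σᵢ aᵢRR_{k−i} + Σⱼ bⱼsBP_{k−j} + e_k with one order N
(default 8; AIC selection behind `order="aic"`) for both sums and b
starting at j = 0, fit by least squares on mean-removed series; fits whose
AR polynomial has roots on or outside the unit circle are reported missing.
The model RR spectrum |H|²P_BP + innovation term over the Welch pressure
spectrum gives α_LF as the **plain LF-band PSD ratio, exactly as defined
here (units ms²/mmHg²)**; the conventional α index is its square root and
is reported alongside (`alpha_sqrt`), because the two differ by a square
and downstream classification must know which it is consuming.

Coherence: PPI and sBP beat series are cubic-interpolated to 4 Hz,
smoothed by a Gaussian kernel whose −3 dB point is 10 Hz on the continuous
representation (at a 2-Hz Nyquist this is nearly an identity — the
10-Hz exclusion is retained as specified but has negligible effect on
beat-derived series), then Welch magnitude-squared coherence (120-s
segments, 50% overlap, Hann).

## Aggregation and classification

Per-index subject values are the median over quality-passing segments
(mean available; median resists residual artifacts). The HRT index is TS
(the only turbulence quantity with a printed normative threshold); TO is
kept as an auxiliary output, and a joint TO+TS criterion is possible by
replacing the index column. z = (value − mean)/SD against an age-decade ×
sex reference table; abnormal iff |z| > 2.5 strictly, **two-sided** —
the literature disagrees on the direction of LF-power and LF/HF changes in
this population, so directions are reported but never used to classify.
Missing indices count as non-abnormal (conservative). eAD iff ≥ 3 of 5
indices are abnormal. The bundled reference table is a synthetic default:
printed healthy ranges (RMSSD 19–75 ms, TS > 2.5 ms/beat, BRS 4.87–34.07)
read as mean ± 2 SD, and placeholder values for LF power (600 ± 250 ms²)
and LF/HF (2.0 ± 1.0) where no range is printed; every entry carries a
provenance note and is meant to be replaced with study-appropriate norms.
A 5-day trajectory applies the same aggregation per 24-h bin.

## Synthetic generator

The generator is beat-domain first: RR_k = RR₀ + A_LF·sin(2πf_LF t_k) +
A_HF·sin(2πf_HF t_k) + ε_k with cumulative beat times. Additive RR-domain
modulation was chosen over integral pulse frequency modulation because it
has closed-form oracles (successive-difference RMS, spectral peak
location); an IPFM mode exists behind a flag for realism. Healthy defaults:
RR₀ = 850 ms, LF 30 ms at 0.10 Hz, HF 40 ms at 0.25 Hz, jitter SD 5 ms,
baroreflex gain 15 ms/mmHg (mid-range of healthy adult gains and the mean
of the healthy cohort distribution), sBP baseline 120 mmHg. PVCs use
couplI = 0.6× the preceding interval and a full compensatory pause
(compI = 2RR − couplI, the classical electrophysiology convention), with a
recovery that lengthens successive intervals by a per-beat increment
(default 8 ms/beat over 10 beats) so the true turbulence slope equals the
increment when modulation is off; sites are stride-placed with bounded
jitter so the requested count and ≥ 20-beat spacing are guaranteed or an
error is raised. The ±1-mmHg random-walk pressure reflects at ±20 mmHg
around baseline to stay physiological. Waveforms are rendered from
Gaussian-bump P-QRS-T templates (ectopic beats wide and large by
construction: ~130-ms QRS at 1.8× amplitude, no P wave) and a canonical
arterial pulse scaled to the per-beat systolic value; all channels share
one sampling rate (default 250 Hz). Corruption adds white noise, sub-0.5-Hz
baseline wander, flatline stretches and motion bursts.

What the generator does **not** emulate: respiration mechanics and
RSA–frequency coupling, IPFM spectral sidebands (outside the flag),
Windkessel pressure dynamics, electrode-contact artifact structure,
arrhythmias beyond isolated PVCs, and drug or ventilation effects. Tests
passing on this bed therefore establish the correctness of the numerics
and decision logic, not detector performance on clinical recordings.

## Problem sizes used in the test suite

The bundled checks run on scaled-down inputs chosen to exercise every code
path: 300–900-s rendered records for detector truth, 600–1200-s
tachograms for index recovery, 1200–2000-beat series for BRS, a
200-subject beat-domain cohort for classification recovery, and 10-seed
sweeps for stochastic properties. Cohort-scale checks use the beat-domain
path (no waveform rendering); the waveform path is exercised end to end on
the shorter records.

## Known limitations

The WFDB support is a minimal native dialect (format 16 signals, N/V/X
MIT-style annotations) sufficient for records this package writes; the
reference ranges and ABP reference library are synthetic stand-ins; the
PVC detector is rule-based and tuned for template-rendered morphologies —
on clinical data its thresholds should be revisited against annotated
recordings; and no claim of clinically validated norms is made anywhere.
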