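# Methods

`dyadsync` analyzes one experimental day of a human–dog pair wearing
synchronized physiological sensors: ECG on both torsos, tri-axial
accelerometry, and wrist electrodermal activity (EDA) and skin temperature
(ST) on the human. The session timeline alternates baseline, 10-min
interaction, and neutral subsessions; the dog is out of the room during the
human's neutral periods. All modalities are reduced onto one shared grid of
non-overlapping 10 s epochs.

## Data model and preprocessing

Channels are time-stamped series in fixed physical units (mV, m/s², µS,
°C); missing or artifactual samples are NaN, never interpolated into the
record. `synchronize` resamples each channel onto a uniform per-kind grid
anchored at the timeline origin (maximum induced shift 0.5/fs); sample gaps
longer than 2 s are flagged missing rather than bridged — 2 s is shorter
than any metric window and longer than device jitter. Epochs are half-open
10 s intervals that never straddle subsession boundaries; a trailing
partial interval is dropped so every epoch has identical support.

Outlier screening combines fixed physiological plausibility bounds
(human IBI 300–2000 ms, canine 250–1500 ms; EDA 0.01–60 µS; ST 20–42 °C;
|a| ≤ 8 g) with a Hampel test (1 s window, 5 scaled MADs) on the slow
channels. Two deliberate choices here: the Hampel test is **not** applied
to ECG — every QRS complex is a >5-MAD excursion from its 1 s local median,
so the test would mask the signal itself — and the MAD threshold has a
per-kind absolute floor (0.5 µS, 0.5 °C, 5 m/s²) so genuine small
transients (skin-conductance responses, activity onsets) survive while
gross spikes are still caught. Masking is idempotent; more than 50 %
masked within a subsession raises a quality error (spans that are 100 %
missing are absence-by-design, e.g. the dog's neutral periods, and are
skipped).

Filtering is zero-phase Butterworth (forward–backward), so epoch alignment
is never phase-shifted: ECG 0.5–40 Hz order 4; accelerometer 0.1–0.4·fs Hz
order 4 (the gravity-free dynamic component); EDA 1 Hz low-pass order 2;
ST 0.01 Hz low-pass. The EDA filter is a pure low-pass rather than a
nominal band with a sub-mHz high-pass corner: a zero-phase high-pass at
5·10⁻⁴ Hz removes the tonic level that the physical-unit EDA mean/max
epoch metrics must retain. Metrics are computed on filtered physical-unit
signals; z-scoring is reserved for plots and the optional scale-free DTW
mode.

## Metric extraction (ME and RE)

R peaks come from a Pan–Tompkins-style detector: band-pass (5–15 Hz human,
5–25 Hz canine), derivative, squaring, 150 ms moving integration, adaptive
signal/noise thresholds with search-back, then R-wave localization on the
band-passed waveform; refractory 200 ms (human) / 150 ms (canine). IBIs
outside species bounds or >30 % away from the median of the five
surrounding IBIs are rejected — a "normal sinus beats" proxy without
morphology typing.

Per 10 s epoch (ME): HR = 60000/mean(valid IBI) over beats whose R peak
falls in the epoch (a single pinned convention, rather than a mean of
instantaneous rates); SDNN = sample SD (n−1); RMSSD over valid successive
pairs (≥3 beats); their quotient (missing when RMSSD = 0); ST and EDA
means, EDA max; SCR peak count; per-axis acceleration mean/min/max, MAD
(mean absolute deviation about the epoch mean per axis) and IMA, the
time-averaged L1 modulus of dynamic acceleration (units m/s², so 10 s
epochs and 60 s windows are directly comparable). Epochs with more than
half their samples masked are missing.

EDA is decomposed as tonic = 8 s rolling median, phasic = signal − tonic;
an SCR peak is a phasic local maximum rising ≥0.03 µS from its onset
within 5 s. These two thresholds are declared substitutes for an external
tool's unpublished settings and are configurable.

RE evaluates the same metrics over a centered 60 s window sliding at
10 Hz; a tick at t uses only data in [t−30, t+30). Ticks with fewer than
2 beats (or under half the expected samples) are missing; ticks whose
window is truncated by the record edge are computed but flagged, and
synchrony slices never include flagged ticks.

## Behavior coding (PPSA) and surveys

Raters label each second −1/0/+1 or offscreen. An epoch's code is the
strict majority of its determinate seconds; **any** tie — including 5 s
neutral + 5 s positive, and a positive/negative 5/5 split — codes neutral,
generalizing the protocol's stated neutral bias. An epoch with at least
half its seconds offscreen is indeterminate and excluded from every
statistic. State percentages are taken over determinate epochs; dyadic
behavioral synchrony is the XNOR percentage (identical codes among jointly
determinate epochs); inter-rater reliability is unweighted Cohen's kappa
on the 3-category nominal scale, reported as the mean over rater pairs.

SAM valence/arousal use a 1–5 manikin with this protocol's orientation
(higher valence = more unhappiness, higher arousal = more calmness);
PANAS-SF positive/negative affect are sums of ten 1–5 items each
(range 10–50); MDORS is consumed as a provided total (lower = stronger
bond). Summaries pool BASE/NEU/POST as the neutral type and INT1/INT2 as
the interaction type. Session-type comparisons use the Wilcoxon
signed-rank test, paired per session-day (the study's unit of repeated
measurement; a per-subject pairing is exposed via the grouping argument):
zero differences dropped (Wilcoxon's original rule), midranks for ties,
exact tie-aware enumeration of all 2ⁿ sign assignments for n ≤ 12 with
p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))), and a continuity- and tie-corrected
normal approximation above; two-sided α = 0.05.

## Synchrony

For each interaction subsession, an 18-epoch (3 min) slice of the 10 Hz RE
series is taken from the temporal center, [mid−90 s, mid+90 s), torso
devices only (human chest, canine harness), for HR, SDNN, RMSSD and IMA.
Up to 5 % missing ticks are linearly interpolated; more invalidates the
slice. Two couplings are computed: lockstep Pearson r, and classic dynamic
time warping — full DP matrix, L1 local cost, steps {(1,0),(0,1),(1,1)},
boundary-anchored, no window constraint. DTW runs on raw metric units by
default, so the ~20 beats/min species offset dominates the HR path
distance (matching the magnitudes such tables report); a z-scored mode
removes level and scale.

## The synthetic dyad generator

No pilot dataset is released, so a simulator with recoverable ground truth
defines the study conditions. Defaults: human 75 beats/min (SDNN 50 ms,
RMSSD 40 ms), canine 95 beats/min (SDNN 60, RMSSD 55 — plausible
placeholders, not population claims about dogs); protocol BASE 5 min,
INT 10 min, NEU 5 min, INT 10 min, POST 5 min; ECG 200 Hz, ACC 32 Hz,
EDA/ST 4 Hz; ~4 SCR/min with interaction elevation of tonic EDA; ST drift
0.1 °C/min toward a plateau; neutral-heavy behavior dynamics giving
roughly 75–90 % neutral epochs during interactions.

**IBI construction.** Two timescales: a slow per-second AR(1) modulation
(φ = 0.95, ~20 s time constant) carrying 60 % of the IBI variance, plus a
fast beat-to-beat AR(1) whose lag-1 autocorrelation is solved from
RMSSD² = 2·Var·(1−φ) (after subtracting the slow component's small
contribution to successive differences), so one (SDNN, RMSSD) pair is
targeted exactly in expectation. The standalone IBI generator is a single
AR(1) with φ = 1 − RMSSD²/(2·SDNN²); feasibility requires
0 < RMSSD < 2·SDNN. ECG is rendered as three Gaussian bumps per beat
(P/R/T, R amplitude 1 mV, ~10 ms width) with beat times snapped to the
sample grid, so the recorded truth index is exactly the noiseless argmax.

**Dyadic coupling.** During interaction subsessions both subjects' slow
modulations load a shared latent AR(1) driver. `coupling_rho` is defined
as the *delivered* expected Pearson r of the mid-interaction 18-epoch RE
heart-rate slices. Because a 180 s slice of 60 s moving-average-smoothed
series has only a handful of effective degrees of freedom, the sample
correlation is biased toward zero — E[r] ≈ x − 0.3·x(1−x²) under this
geometry, with a further ≈0.95 dilution from beat-level noise surviving
the window — so the generator inverts that relation when choosing the
latent cross-correlation. Behavior coupling is separate: each second the
dog copies the human's current state with probability `copy_prob_kappa`,
otherwise follows its own chain, making the expected same-state fraction
κ + (1−κ)·chance. Surveys shift arousal and positive affect after
interactions with magnitudes scaled by the bond level
(mean of the two coupling parameters); MDORS decreases with bond.

**What the generator does not emulate.** Real ECG morphology and
pathological beats; motion artifacts correlated across channels;
respiratory sinus arrhythmia as an explicit oscillation; EDA
non-stationarity beyond a ramp; rater drift or systematic bias (rater
error is i.i.d. relabeling); any true causal link between behavior states
and physiology. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under known truth, not field validity
on real recordings.

## Numerical and testing choices

All randomness flows from one seed through named spawned streams, so
identical configurations reproduce byte-identically. Delta ties in the
heatmap render as "decrease" (the display is binary) but are counted and
reported; the SDNN/RMSSD quotient carries no direction and is excluded
from the heatmap by default. The correlation matrix uses
pairwise-complete Pearson over interaction sessions with a 3-pair minimum
per cell. Tests pin every statistic to an independent brute-force oracle
(literal formula evaluation, 2ⁿ sign enumeration for the exact Wilcoxon,
exhaustive monotone-path enumeration for DTW on short pairs, exhaustive
composition enumeration for the epoch-coding rules) and use simulation
scales chosen to keep the default suite fast: 5-min records and 20 seeds
for detector recovery, 30 seeds per coupling level (two interaction
slices each), 1000 replicate studies for test calibration, and one full
22-session study for the end-to-end smoke check.

## Known limitations

Epoch-level HR uses beats-in-epoch attribution; alternatives
(IBI-interpolated rates) differ slightly at epoch boundaries. The SCR
threshold set is a stand-in for an external tool's pipeline. The Wilcoxon
normal approximation is used above n = 12 regardless of tie structure.
DTW has no warping-window constraint, which is O(n·m) in time and memory
(1800-tick slices are the practical ceiling). The canine HRV targets are
placeholders; no breed- or size-specific cardiology is modeled.
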