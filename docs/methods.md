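# Methods

This package simulates and analyzes a combined dictator-game (DG) /
ultimatum-game (UG) EEG experiment.  Participants see one of five fixed
endowment splits per trial — self-shares {50, 60, 70, 80, 90}% as DG
allocator, {50, 40, 30, 20, 10}% as UG responder — and accept or refuse it
within 3 s.  Sessions run 5 blocks of 48 trials; each split occurs exactly
48 times per session in a seeded random order (single blocks need not be
balanced).

## Behavioral model

**Trial sets.** Valid DG trials are *selfish* (accepting self-shares 90/80
or refusing 60/50), *fair* (the opposite), or *neutral* (70:30).  Valid UG
trials are *altruistic* (accepting self-shares 10/20 or rejecting 40/50),
*conceit* (the opposite), or *neutral* (30:70).  Two indices contrast the
opposed sets:

    DG_selfishness = (N_selfish − N_fair) / (N_selfish + N_fair)
    UG_altruism    = (N_altruistic − N_conceit) / (N_altruistic + N_conceit)

Both live in [−1, 1]; percent frequencies work as well as counts because
the scale cancels.  An index is undefined (and the participant excluded
from clustering, never imputed) when both sets are empty.

**Decision policies.** Each group carries an explicit accept-probability
table per allocation — deliberately not a utility model, so it can be read
and calibrated directly.  With symmetric behavior q at the index-defining
allocations the expected index is exactly 2q − 1, so group tables are
calibrated as q = (1 + target index)/2 from the reference group medians
(e.g. DG q = 0.99 for the selfish group, 0.04 for the fair group).
Per-participant heterogeneity adds a single N(0, 0.04) shift to q (clipped
to [0.005, 0.995]), which reproduces the observed index spread within
groups.  A 0.011 per-trial omission probability yields ≈ 237.4 completed
trials of 240, matching the reference completion rate.

**Reaction times.** Shifted log-normals per (group, game, response):
RT = 200 ms + exp(N(log(median − 200), 0.85²)), redrawn (then clamped) to
stay in (0, 3000] ms.  Medians come from the reference group tables;
responses endorsing the split are faster in every cell by construction, and
trial-set offsets (+80 ms on altruistic UG trials, +20 ms on fair DG trials)
reproduce the set-level ordering.  σ = 0.85 makes mean − median ≈ 65–110 ms,
the long right tail typical of speeded decisions.  Within-cell z-scores
(mean 0, SD 1 per participant × game) are used for factorial RT analysis,
because raw RT variance differs strongly between participants.

## Phenotyping

Complete-linkage agglomerative clustering (Euclidean metric) on the
(UG_altruism, DG_selfishness) points.  k defaults to the largest relative
gap in merge heights over k ∈ [2, 6] (overridable); this deterministic rule
recovers planted k on well-separated cohorts.  Because complete linkage is
deterministic, seed sensitivity is emulated explicitly: 50 replicates with
input order shuffled and indices jittered by ε = 0.01 index units;
replicate labels are matched to the reference partition by Hungarian
assignment, and any participant whose label ever changes is split into an
extra "unstable" group (GrpA analogue).  Stable clusters are named by
centroid position: highest DG_selfishness → GrpS, lowest → GrpF; the
remainder take GrpC/GrpB/GrpA in descending UG_altruism, consistent with
the reference centroid ordering.  Linkage ties are broken by lowest
participant id (they do not occur on continuous data; documented so the
brute-force oracle test is exact).

## EEG model

Epochs span −200..800 ms around stimulus onset at 1024 Hz on Fz, FCz, Pz,
CPz (fixed topography weights, no volume conduction modeling).  Each trial
is a sum of components plus 1/f noise:

* **Measured components** N1, P2, MFN (fronto-central, maximal at FCz) and
  LPC (posterior-parietal, maximal at Pz) are unit-peak Gaussians with
  single-trial widths σ = 16/24/42/65 ms, latency jitter N(0, 10 ms), and
  unit-mean log-normal amplitude variability (CV 0.3).
* **A late positive pedestal** ("putative P3"/slow positivity; sigmoidal
  plateau rising at 220 ms, falling at 620 ms, 4 μV fronto-central with
  small posterior weight) is planted as background but never measured.  It
  is what lets the MFN appear as a *positive-valued* local minimum in some
  conditions, as the reference group tables show; without it a shallow MFN
  has no strict extremum at all.  Its posterior weight (0.15) is kept small
  so the background under the LPC window is nearly flat — a falling
  background was found to skew noisy LPC latency picks early.
* **Noise** is 1/f^α (α = 1) with 10 μV RMS per trial and channel,
  independent across channels; optional blink transients (> 100 μV,
  frontal-dominant, off by default) exercise the rejection stage.

**Calibration and ground truth.** Because components overlap, a bump
coefficient is not a measurable peak.  The generator therefore calibrates
coefficients and centers by damped fixed-point iteration until the
*expected average* waveform (jitter-smeared, noise-free composite) attains
prescribed windowed extrema — the group × game × response peak targets —
to < 1 ms / 0.03 μV.  The ledger records the composite-template extremum
per channel as planted truth; recovery is judged against that, which is the
estimand the measurement chain actually targets.  Response effects are
additive target offsets (DG: MFN latency ∓16 ms, LPC amplitude ±0.86 μV;
UG: MFN latency ±10 ms and amplitude ±0.33 μV, refusals faster/deeper).
Groups without published component values get midpoints of their behavioral
neighbors.  Per-participant trait shifts (N(0, 3 ms) latency, N(0, 0.3 μV)
amplitude per component) supply the between-participant variance the mixed
models estimate.

## ERP measurement chain

Band-pass 0.1–32 Hz, 6th-order IIR Butterworth (−36 dB/octave), applied
forward–backward so group delay is zero and latencies are unbiased.
`sosfiltfilt` runs with maximal padding: the 0.1 Hz pole settles over
seconds, and scipy's default ~39-sample pad biased late-component
amplitudes by ~0.35 μV on 1-s epochs.  Baseline is the −200..0 ms mean per
epoch and channel; epochs with any |sample| > 100 μV on an analysis channel
are rejected with a log.

Peaks are strict local extrema (sign change of the first difference) of the
stated polarity inside the component window — N1 110–160, P2 180–240,
MFN 260–400 ms at Fz/FCz; LPC 430–630 ms at Pz/CPz — on the average
waveform smoothed with a Gaussian kernel.  The most
extreme candidate wins; exact ties go to the earliest peak except for the
LPC, where the representative peak is the later one.  A peak counts as
*identified* only if its prominence exceeds 0.5 × the pre-stimulus SD of
the smoothed waveform; otherwise the measurement row carries no values,
which is how fewer-than-maximal measurement counts arise naturally.
The smoothing SD is 8 ms: wide enough to suppress spurious one-sample
extrema, narrow enough to attenuate the sharpest component (N1) by < 7%.

The three human observers of the original protocol are replaced by three
seeded bootstrap replicates: each replicate measures the average of a
same-size resample (with replacement) of the condition's trials, so the
repeated-measures structure of the statistics is preserved; a plain-average
mode (`bootstrap=False`) is available.  Amplitudes are peak values in μV
relative to the corrected baseline; a mean-amplitude mode is a possible
extension but not implemented.

## Statistics

* Levene's test (mean-centered; median option gives Brown–Forsythe) gates
  Student (pooled) vs Welch t-tests; Bonferroni adjustment is min(1, m·p)
  with caller-supplied m.  Cohen's d uses the pooled SD
  (categories 0.2/0.5/0.8); generalized η² categories are 0.01/0.06/0.14.
* The mixed model is a participant random intercept over replicate
  measurement rows, fitted by profiled REML (default) or ML: with
  θ = σ²_b/σ²_e each participant block inverts in closed form (Woodbury),
  leaving a 1-D optimization in log θ.  When θ is unidentified (one
  observation per participant) it is pinned at 0, reproducing classical
  ANOVA exactly; a boundary estimate pins σ²_b = 0 with a singular-fit
  warning.
* ANOVA-like tables are Type-III F tests under sum-to-zero coding.
  Denominator df follow Satterthwaite: df = 2f²/Var(f) with
  f = l'Cov(β)l, the gradient of f taken by central differences
  (relative step 1e-6) and the variance-parameter covariance from the
  finite-difference observed information of the (restricted) likelihood
  (relative step 1e-4, chosen to balance truncation against cancellation);
  multi-df effects combine eigencontrast dfs as in the standard
  Satterthwaite implementation for mixed models.  Under the null the
  condition-effect rejection rate at α = 0.05 calibrates to 0.03–0.07
  (checked over 1000 simulations).
* Generalized η² for a fixed effect is SS_effect / (SS_effect +
  SS_participant + SS_residual), with Type-III SS from the fixed-effect
  design and the participant stratum obtained by adding participant
  indicators.
* Polynomial fits (degree 1–2) report F vs the intercept model, R²,
  adjusted R², and for degree 1 the Pearson r with Fisher-z 95% CI.
* A-priori power for the within–between interaction uses the noncentral F
  with df1 = (g−1)(m−1)ε, df2 = (N−g)(m−1)ε and
  λ = f²·N·m·ε/(1−ρ), with the repeated-measures correlation ρ and
  nonsphericity ε exposed; the reference study's exact convention is not
  recoverable, so its printed sample size is a demonstration output, not a
  test target.

## Validation studies and problem sizes

* **Peak recovery** (`fairgame.recovery.component_recovery`): 39
  participants in five groups (8/3/10/8/10), four condition sets of 200
  trials each, default SNR.  Pooled over seeds, latency bias is ≤ 1.7 ms
  and amplitude bias ≤ 9% of the mean planted magnitude for all four
  components (thresholds: 2 ms, 15%).  Amplitude bias is normalized by the
  mean |planted| per component because planted MFN amplitudes change sign
  across conditions, making per-value relative error ill-posed.
* **Phenotype recovery**: 28-participant S/B/F cohorts; adjusted Rand index
  vs planted groups ≥ 0.9 in 20/20 seeds at default heterogeneity; a
  constructed participant equidistant from two cluster centroids is flagged
  unstable.
* **Contrast directions**: full simulate → cluster → measure passes on
  responder-game cohorts recover shorter fronto-central N1 latency in the
  selfish vs fair group (≈ −13 ms), larger posterior LPC amplitude in the
  selfish group (≈ +3.4 μV), and shorter MFN latency on rejections
  (≈ −14 ms), in ≥ 18/20 seeds.
* The demo pipeline (28 participants, both games with EEG) completes in
  about half a minute; single-block analyses scale linearly in trials ×
  channels.

## What the generator does and does not emulate

It emulates group-dependent decision frequencies, omissions, long-tailed
condition-ordered RTs, and stimulus-locked averages whose windowed peaks
match published group values, with realistic trial-level variability and
1/f noise.  It does **not** emulate volume conduction, ocular/muscle
physiology (blinks are stylized transients), inter-channel noise
correlation, drifting electrode impedance, or within-session
non-stationarity.  ICA-based ocular correction is replaced by threshold
rejection, which suffices because synthetic blinks are large by
construction.  Passing recovery tests therefore demonstrates correctness of
the analysis chain on data of known structure — not robustness to every
artifact class of real recordings.

## Known limitations

* Per-allocation acceptance rates are under-determined by published set
  frequencies; the symmetric-q calibration is one consistent choice.
* The exact reversal symmetry of the zero-phase filter is float-limited to
  ~1e-5 by the extreme 0.1 Hz corner; with a 4 Hz corner it holds to 1e-9.
* The UG rejected-RT median of the selfish group is set 10 ms above its
  accepted median so that every cell obeys the global
  "endorsements are faster" direction the generator guarantees; the
  reference cohort's printed medians invert it for that single cell.
* Component windows follow the primary definitions; alternative published
  window variants (P2 up to 260 ms, LPC 400–650 ms) are config-exposed.
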