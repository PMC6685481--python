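# Methods

This note documents the models, estimators, parameter choices and known
limitations of `nlsound`, in the order the pipeline runs them.

## Signal handling

All analysis operates on mono float64 waveforms with dimensionless
amplitude in [−1, 1]. Stereo WAV input is mixed down by channel mean
(every measure is defined on a single channel). No resampling is
applied on read: measures that are rate-sensitive validate per file
(e.g. band edges against Nyquist) rather than silently altering the
spectrum.

Banks are equalized to a common RMS before analysis so level
differences cannot drive any measure. Two modes exist: match the
loudest sound in the bank (the default, mirroring how curated sound
databases are usually levelled) or a configured absolute level; the CLI
expresses the absolute target in dB relative to full scale because a
bare "dB" without a reference is ambiguous. Normalization is a single
positive gain, so zero crossings and all scale-invariant measures are
unaffected; no silence trimming is performed before or after.

## Temporal measures

**Sample entropy** uses embedding m = 2 and tolerance r = 0.2·SD, the
standard defaults of the nonlinear time-series literature; both
template sets run over i = 0..n−m−1 and self-matches are excluded. The
quadratic pair count runs in a compiled kernel; `-ln(A/B)` returns
`inf` when no (m+1)-length pair matches (A = 0), the conventional
sentinel for an unobservable conditional probability.

**Permutation entropy** uses order 3, delay 1, reported in bits and
normalized by log₂(order!) to [0, 1]. Rank ties are resolved by order
of appearance (stable argsort); ties are measure-zero for real audio.

**LZ76 complexity** is the word count of the exhaustive-history
parsing, computed by the classic linear scan; the final, possibly
incomplete word counts as one word (the test suite pins this variant
against an independent literal parser over every binary string of
length ≤ 12). Three binary codings are provided: differential
(b_i = 1 iff x_{i+1} > x_i; ties → 0, a deterministic choice that is
measure-zero for audio), average (above/below the mean), and a
modified-zone coding (outside mean ± zone_factor·SD, zone_factor = 1
by default). The zone coding is one reasonable formalization of a
"zone" rule among several; it is isolated behind configuration so
alternatives can be swapped in.

**Entropy window.** SampEn, permutation entropy and LZ are computed on
a decimated, truncated copy of the signal (default: polyphase
resampling to 8 kHz, first 10 s) so the quadratic-cost estimators stay
tractable on long recordings; both knobs live in `TemporalConfig`.
Higuchi, NLD and the envelope measures see the full-rate signal.

**Higuchi FD** uses kmax = 8 and the standard curve-length
normalization; the fitted slope is clipped to the theoretically
meaningful band [1, 2] for reporting (`clip=False` returns the raw
slope). A straight line yields 1.0 and white noise 2.0 within the
estimator's known bias at these settings.

**NLD FD** z-scores each window (default 128 samples), takes the mean
absolute successive difference (the normalized length density), maps it
through FD = a·NLD^k + b and averages windows. The calibration triple
is configuration. The defaults are an analytic two-anchor fit chosen
here: b = 1 so that a smooth signal (NLD → 0) maps to FD 1, k = 1/2,
and a = 1/√(2/√π) so that z-scored Gaussian white noise
(E|Δz| = 2/√π) maps to FD 2. Any published calibration can be
substituted verbatim via `TemporalConfig.nld_calibration`. Zero-variance
windows are skipped; an all-degenerate signal raises.

**Peak measures** operate on the analytic-signal envelope smoothed by a
10 ms moving average; peaks are local maxima with prominence ≥ 10% of
the envelope maximum. A signal whose envelope has no interior peak
(steady tone, plateau, monotone ramp) is counted as a single peak with
relative amplitude 1 — the envelope, not the raw oscillation, is what
peak counting is meant to capture. Whether peaks should be counted on
the envelope or the raw waveform is genuinely open; the envelope was
chosen because raw-waveform maxima scale with carrier frequency rather
than event structure.

## Spectral measures

All frame-based measures share a Hann short-time transform
(frame 2048, hop 512) and a uniform silence gate: frames below 10% of
the loudest frame's RMS are excluded from frame averages so silent
tails cannot dilute a measure. Band powers are folded one-sided spectra
scaled by frame length and window energy, so summing bands that
partition 0..Nyquist reproduces the time-domain power (Parseval) to
within window-edge effects (< 2%).

The five default RMS bands (0–0.5, 0.5–1, 1–2, 2–4, 4–8 kHz) cover the
standard audiometric range in octave-like steps; the set is
configuration, with only the 1–2 kHz band playing a canonical role in
the salient-measure layouts.

**HNR** is computed natively with a frame-wise normalized
autocorrelation method in the style of the phonetics literature, not by
calling an external phonetics program, and no parity with any
particular program is claimed; accuracy is established against
synthetic mixtures with known harmonic/noise power (±1.5 dB over
−10..20 dB SNR). Three details matter and are deliberate:

1. *NCCF normalization* — r(τ) divides the lag-τ autocorrelation by the
   energies of the two overlapping segments (as in the RAPT/YIN family)
   rather than by frame energy with an (L−τ)/L correction. For an
   exactly periodic frame this gives r = 1 regardless of where the
   frame cuts the cycle; the simpler correction leaves an O(1/periods)
   segment-power bias that inflates high-SNR estimates by several dB.
2. *Pooled lag search* — the candidate period is the argmax of the
   frame-averaged r(τ) over lags in [1/fmax, 1/fmin] (defaults
   75–600 Hz); per-frame maxima are then taken only in a ±2-lag
   neighborhood. Maximizing each frame independently over hundreds of
   lags picks up the maximum of that many noise fluctuations and biases
   r upward, which the pooling suppresses. The cost is that sounds with
   strongly drifting f0 (chirps) read as low-HNR, which is the honest
   answer for a fixed-lag periodicity measure.
3. *Parabolic interpolation* of the per-frame peak recovers periods
   that fall between integer sample lags.

Frame values 10·log₁₀(r/(1−r)), with r clamped to [10⁻⁶, 1−10⁻⁶]
(bounding reported HNR to ±60 dB), are averaged over gated frames.

**Spectral flatness** floors zero bins at 10⁻¹² of the frame maximum
before the geometric mean. **SSI** is defined here as the mean
(1 − Pearson r) between adjacent gated frames' log-magnitude spectra —
0 for a stationary spectrum, approaching 2 for anti-correlated spectral
shapes. A spectral-structure formula is not standardized in the
literature; this adjacent-frame decorrelation is an explicit
interpretation, kept behind the module surface so an alternative can
replace it without touching callers.

## Salience pruning

Pairwise Pearson correlations are computed pairwise-complete (each
pair's n is reported) with two-sided p-values. Pruning acts within each
domain independently — temporal and spectral information are analyzed
separately throughout, and cross-domain correlations never cause a
drop. The rule is greedy: repeatedly drop the measure with the most
partners at |r| ≥ threshold (default 0.45); ties go to the larger mean
|r| against the remaining measures, then to the lexicographically
smallest name. The greedy order is one deterministic resolution of an
under-determined choice ("keep only one of each correlated pair" does
not say which); every drop is logged with its cause, and a forced
keep-list bypasses the rule entirely for replication-style runs. The
retained set provably satisfies the threshold post-condition, and
raising the threshold never shrinks it.

## Percept mapping

α = 0.05 throughout. Simple regressions report r, p, slope and
intercept per (measure, percept); multiple regressions are OLS with
intercept, restricted to same-domain predictor sets by default, with a
condition-number guard (10⁸ on the standardized design) against
collinear predictors. Percept inter-correlation flags any percept
correlated at |r| ≥ 0.7 with two or more others as redundant — the
typical fate of Familiarity, which tracks Complexity and naming
accuracy too closely to carry independent variance.

Category ANOVAs are classical one-way F tests; heteroskedasticity is
always checked with the Brown–Forsythe (median-centred Levene) test,
and a rejection stamps the result "unreliable" without suppressing it.
Post-hoc pairs use Tukey–Kramer with the studentized-range table
approximation for adjusted p-values (mean differences are exact; the
approximation is accurate to ~10⁻³ in p, ample at α = 0.05, and orders
of magnitude faster than numerically integrating the studentized-range
CDF). Categories with fewer than 2 members are dropped with a warning.
The homogeneity tally sums significant Tukey pairs across ANOVAs and
reports observed/possible — a descriptive summary, not a decision rule.

PCA standardizes by default (the measures' units differ wildly) and
fixes signs so each loading vector's largest-magnitude element is
positive, making biplots reproducible. Ward clustering standardizes
features before Euclidean distances for the same reason (a flag
disables it); cluster levels default to [10, 5, 3, 2], and clusters
with fewer than 3 sounds are reported but excluded from the cluster
ANOVAs (a significant difference resting on a two-sound cluster is not
evidence; `force_include_small` overrides). The PCA-space variant
clusters on the first two component scores per domain.

Per-sound mean ratings (not per-subject observations) enter all
analyses; subject-level modeling is out of scope.

## Synthetic data

The generator emulates a curated rated sound database at the scale the
analyses are designed for: banks of 60 sounds by default in the
acceptance runs (10 minimum), stratified over 8 signal kinds with
randomized parameters (durations 0.6–1.4 s — 1–2 s for click trains —
at 16 kHz, f0 200–4000 Hz log-uniform for tones, 3–8 harmonics,
AM rates 2–16 Hz, click rates 2–10 Hz, tone/noise SNRs −5..15 dB), 5 ms
raised-cosine ramps, RMS-equalized at 0.1. Each kind maps to one of the
nine source-category labels so category ANOVAs have 7–8 members per
group at n = 60. The stratification guarantees non-degenerate variance
in every measure; an optional `verify` flag additionally checks
coefficient of variation > 0.05 per measure post hoc and regenerates
with a stepped seed if violated.

The rating model plants percept structure **on the measures, not on
raw audio parameters**: recovery tests then validate the pipeline
(extraction → pruning → regression) irrespective of any single
measure's implementation details. Defaults follow the qualitative
structure of listener data: Complexity loads positively on spectral
centroid and negatively on HNR; Pleasantness loads on mean peak
relative amplitude with a weak negative link to Complexity;
Familiarity = 0.9·(−Complexity latent) + noise; Accuracy of Naming is
a logistic function of the Familiarity latent (it is a bounded
proportion, and naming accuracy rises with familiarity) with noise on
the logit. Noise SDs (0.5 on Complexity/Pleasantness, 0.8 on
Familiarity and the Accuracy logit) were chosen once so the percept
inter-correlations land in the realistic 0.7–0.9 band rather than near
1. Likert percepts are mapped affinely onto [1, 7] centred at 4, the
slope shrinking only as needed to fit the observed range — the map is
strictly linear over the sample, so planted correlations survive it
exactly — with optional integer rounding.

What the generator does **not** emulate: recording-channel artifacts,
reverberation, source-category acoustics (a "primate" label on a
harmonic complex is a label, not a vocalization), inter-subject rating
variance, or any nonlinear measure→percept relationship. Passing
recovery tests therefore shows the pipeline is correct and unbiased at
realistic n and noise levels — not that real percepts are linear in
these measures.

## Determinism and numerics

Every generator is a pure function of (spec/model, seed); the analysis
itself is deterministic, so a report is bit-for-bit replayable from its
manifest (config hash + seed). Ward merge ties are resolved by scipy's
deterministic ordering (ties are measure-zero for continuous data).
Degenerate inputs have defined behavior throughout: silent signals,
constant columns, undersized groups and all-identical ANOVA cells
(F = 0, p = 1 rather than 0/0) either raise named errors or degrade
with warnings as documented per function.

## Problem sizes in the validation suite

The test suite and acceptance script run the synthetic study at
n = 60 sounds × 20 seeds, 10 000-sample noise for fractal-dimension
limits, and 1-second 44.1 kHz mixtures for HNR recovery — sizes at
which the sampling error of every checked statistic is several times
smaller than its test tolerance, while a full run stays in the minutes
range on one core. Larger banks change nothing structurally; extraction
cost is linear in bank size and dominated by the entropy kernels.

## Known limitations

- SampEn/PE/LZ values depend on the entropy-window defaults
  (8 kHz/10 s); comparisons across configurations are not meaningful.
- The NLD calibration is an analytic default, not a published-constant
  match; absolute NLD FD values are comparable only within a
  configuration (the measure's use in the pipeline is correlational,
  which is unaffected).
- HNR assumes a quasi-stationary fundamental within the pooled search;
  frequency-swept sounds read low by construction.
- The modified-zone LZ coding and the SSI formula are explicit
  interpretations (flagged above) among several defensible ones.
- Tukey p-values use the table approximation; if exact studentized-
  range p-values are needed, swap in `scipy.stats.tukey_hsd` at ~400×
  the cost.
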