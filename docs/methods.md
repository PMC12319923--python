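# Methods

`toteeg` implements a complete analysis chain for quantifying time-on-task
(ToT) effects in EEG — slow, systematic drifts of brain measures with trial
order — and for separating genuine trial-wise brain–behaviour coupling from
coupling carried entirely by such shared drifts. Because real recordings are
not required, the chain is validated end to end on a synthetic session
generator whose latent structure is known exactly.

## The scientific problem

In a long experimental session, oscillatory alpha power (8–13 Hz) tends to
rise, alpha peak frequency tends to fall, and reaction times speed up. Any
two measures that both trend with time will correlate across trials even if
they never interact: a single-trial regression of alpha on RT then reports a
"brain–behaviour relationship" that is an artifact of shared drift. The
remedy studied here is to add trial order as a covariate to the single-trial
model and test whether the coupling survives. The package reproduces that
logic: in a *spurious* regime the alpha–RT association is abolished by ToT
control, while in a *genuine* regime (trial-wise coupling between
post-stimulus alpha/beta desynchronisation and decision confidence) the
association survives.

## Synthetic session generator (`synth`)

One session emulates a 2-AFC visual discrimination task: 900 trials in 5
blocks of 180 (desk-scale replicas shrink this; see *Problem sizes*), five
stimulus-contrast levels (0.075–0.375) balanced within block with shuffled
order, 32 channels at 512 Hz, epochs −2.5 to 1.5 s around stimulus onset.

**Signal model.** Every epoch is coloured Gaussian noise synthesised in the
frequency domain. The background PSD follows the fixed-mode aperiodic form
`10^b · f^(−χ)` (default b = 1.0, χ = 1.0, stationary across the session;
per-participant trait SDs 0.10 and 0.08). Alpha and beta oscillations are
narrowband Gaussian processes with Gaussian PSD bumps (widths 1.2 and 1.8 Hz)
centred on the trial's latent centre frequency. Latent oscillatory power is
parameterised as *peak height in log10 units above the aperiodic background*
— exactly the quantity the spectral parameterizer estimates — so recovery is
a like-for-like comparison. A smooth cosine gain profile across channels
stands in for topography (realistic head-model projection is out of scope).

**Drifts (the study conditions).** Magnitudes are not published as numbers,
only as directions and significance, so the defaults were calibrated once to
the qualitative published pattern and then frozen:

| parameter | default (session total) | rationale |
|---|---|---|
| alpha power drift | +0.40 log10 units | steep, clearly visible rise |
| alpha CF drift | −1.0 Hz | ~1 Hz slowing across a session |
| beta power drift | +0.10 log10 units | "weaker" beta effect |
| RT drift | −0.18 s | block-1 vs later-block speed-up |
| aperiodic exponent drift | 0 | generated stationary |
| within-block alpha reset | 50% power dip, decaying over ~12 trials (τ = 4) | block-break "reset" |

Regime factories hold these *session-total* drifts fixed when a smaller
trial count is requested, so a 125-trial replica preserves the session-level
drift structure of the 900-trial design. Trial-to-trial noise: alpha CF
0.3 Hz, alpha power 0.15 log10 units, RT additive lognormal (median 0.15 s,
σ = 0.4). Accuracy and confidence follow lapse-adjusted logistic
psychometric functions of contrast; a practice effect (accuracy decrement
and RT cost) is confined to blocks 1–2. With these values single-trial
alpha peaks are detected on ~90–95% of trials, matching the detection rates
typical of scalp-averaged single-trial parameterization.

**Coupling regimes.** `none`/`spurious`: no trial-wise coupling — under
drifts, alpha–RT correlation is borne entirely by trial order. `genuine`: a
standard-normal latent desynchronisation `d` per trial attenuates
post-stimulus (t ≥ 0) alpha power by 0.25 log10 units per SD (beta by half
that), raises the confidence logit by `genuine_conf_gain · d` (default 1.0),
and pre-stimulus alpha level adds `0.08 s` per log10 unit to RT.

**Randomness.** All draws come from Philox counter-based substreams spawned
from the single config seed with `(participant, stream, trial)` spawn keys,
so regenerating any participant (or epoch) is independent of order.

**What the generator does not emulate.** Volume conduction and realistic
topography, eye/muscle artifacts, non-Gaussian EEG features, autocorrelated
behavioural noise, attentional probes. Passing tests therefore show that the
*statistical machinery* behaves correctly under a known generative model
with realistic SNR, not that preprocessing of raw recordings is handled.

## Spectral decomposition (`spectral`)

Single-trial spectra: Hann-tapered FFT of a 1-s window ([−1, 0) pre-stimulus,
[0, 1) post-stimulus; half-open so the windows share no sample), zero-padded
to 10 s → exactly 0.1 Hz resolution over 1–40 Hz. Time–frequency power:
0.5-s Hann windows stepped by 0.02 s, padded to 1 s → 1 Hz resolution,
squared magnitude, restricted to −1…1 s. Windows that would extend past the
epoch edge yield missing values rather than zero-padded estimates, avoiding
edge bias in downstream regressions. Scaling follows a one-sided density
convention (`2/(fs·Σw²)`), which makes the estimator unbiased for the
generator's PSD; every downstream statistic is scale-invariant, so the
convention is a documentation choice, not a modelling one.

## Spectral parameterization (`specfit`)

A from-scratch fixed-mode periodic/aperiodic decomposition:
`log10 P(f) = b − χ·log10 f + Σ Gaussians`, fit range 3–40 Hz, peak
threshold 2 × SD of the flattened spectrum (recomputed after each peak
subtraction), full-width limits 2–15 Hz (Gaussian SD = width/2), at most 4
peaks, channel-averaged spectra per trial. The aperiodic fit is a robust
two-pass linear fit in log–log space (second pass masks points above the
first-pass line past the 2.5th flatness percentile). After a joint
multi-Gaussian refit, the aperiodic component is refit on a peak-free
spectrum; two numerical choices matter here and were made after observing
systematic biases in recovery experiments:

* only *substantial* peaks (height ≥ 0.1 log10 units) are subtracted in the
  refit — subtracting the fitted shape of near-noise peaks, which often come
  out at the maximal width, tilts the exponent systematically;
* a guard band of 1.25 × bandwidth around each substantial peak is excluded
  from the refit, so shape mismatch between the true oscillatory bump
  (Gaussian in linear power) and the fitted bump (Gaussian in log power)
  cannot leak oscillatory drift into the exponent. Without the guard band
  the generated-stationary exponent inherits a spurious block effect from
  the drifting alpha peak.

An absolute peak-height floor of 1e-3 log10 units prevents numerically flat
(noiseless) spectra from sprouting phantom peaks. Goodness of fit is the
squared correlation between model and data in log10 space (bounded [0, 1]
even for poor fits) plus the mean absolute error. Alpha peaks are the
highest-power fitted peak with centre frequency in 6–15 Hz; absence is a
value, and trials without a detected alpha peak are excluded listwise from
alpha-peak analyses (identically for both models of a nested comparison).
A non-convergent bounded Gaussian fit discards that peak with a logged
warning. Optimizer tolerances are 1e-3 (relative), i.e. ~0.01 Hz on an
alpha centre frequency — two orders below trial-to-trial noise.

## Cluster-based permutation statistics (`permstats`)

Point-wise dependent-samples statistics over channel × frequency (× time)
grids: a repeated-measures F across blocks, or a one-sample t of participant
regression coefficients against zero. Supra-threshold points (p < .05; for
two-tailed t, |t| above the α/2 quantile) are clustered via spatial channel
adjacency plus immediately adjacent frequency/time grid steps; the cluster
statistic is the summed point statistic. A cluster is kept only if at some
single frequency/time point it contains ≥ 2 distinct channels that are
adjacency-connected (the "two neighbouring electrodes" rule). The null
distribution records the maximum cluster statistic per permutation —
within-participant label permutation for F, participant sign-flips for t —
and Monte-Carlo p-values are +1-corrected. Two-tailed t tests use a cluster
threshold of .025 per tail; the F test uses .05. Degenerate zero-variance
points receive F = 0 (or a large sentinel when a perfect effect sits on zero
error variance) with a log entry.

The 32-channel adjacency is built by Delaunay triangulation of the standard
BioSemi-32 montage projected azimuthally to 2-D, pruning edges beyond 1.6 ×
the median edge length. This approximates the classical template
neighbourhood (mean degree ~5.1 vs the template's 6.0); the original
template is a binary file and is not reproduced exactly. Collinear layouts
fall back to mutual k-nearest neighbours.

## Single-trial regression (`trialreg`)

Stage one, per participant:
`EEG = a + b_conf·Confidence + b_diff·Difficulty + b_corr·Accuracy +
b_RT·rank(RT) [+ b_ToT·rank(TrialOrder)] + ε` by OLS. Binary predictors stay
binary, difficulty enters as the numeric contrast value, and all continuous
variables — including, by default, the EEG outcome itself — are
rank-transformed (average ties) to blunt outlying trials; ranking the
outcome is interpretive and sits behind `rank_outcome`. Constant predictors
leave the coefficient undefined (excluded from that predictor's group test)
rather than crashing. AIC uses the Gaussian form `n·ln(RSS/n) + 2k` with the
error variance counted in `k`; since both models of a comparison use the
same convention and identical trial sets, ΔAIC is convention-free.

Stage two: one-sample t per predictor across participants with Cohen's d and
Benjamini–Hochberg FDR within the predictor family (scalar measures), or
cluster permutation with sign-flip nulls (time–frequency coefficient maps).
ΔAIC = AIC(noToT) − AIC(withToT) is tested against zero by a two-tailed
paired t; the RT coefficient is additionally contrasted between models
(paired differences, withToT − noToT). Degenerate zero-variance group tests
report the smallest representable double as p rather than crashing.

## Behavioural statistics (`behavstats`)

RT trimming keeps trials strictly within 3 population SDs of the
participant's session-wide mean (zero-SD series keep everything; the trim
is applied once per participant, not per block — the finer scope is not
specified and session-wide is the conservative reading). Psychometric
summaries give proportion correct/confident and mean RT per block ×
contrast cell. The repeated-measures ANOVA supports one and two
fully-crossed within factors with classical sums of squares,
participant × effect error terms, per-effect Mauchly tests, partial η², and
the Greenhouse–Geisser ε estimated from the sample covariance of the
within-participant contrast scores (Huynh–Feldt is not implemented; both the
uncorrected p and p_GG are always reported, with the correction intended
when Mauchly's p < .05). When participants are fewer than the contrast
dimension (e.g. a 5 × 5 interaction with 12 participants) the Mauchly
statistic is undefined and reported as missing while the trace-based ε
remains valid. Tukey HSD uses the studentized-range distribution with a
caller-supplied error mean square, as appropriate for within-participant
follow-ups.

## Pipeline and problem sizes

`run_full_analysis` chains simulate → pre/post spectra → parameterization →
block cluster-F tests → behavioural and alpha-measure ANOVAs →
time–frequency and scalar regressions (± ToT) → AIC comparison →
coefficient contrast, writing CSV/JSON outputs, figures and a manifest
(config snapshot, seed, per-stage digests and timings). Outputs are
byte-reproducible for a fixed config and seed.

The validation suites run *desk-scale* replicas: 12 participants, 125
trials (5 blocks × 25), 8 channels, 2-s epochs, 200 permutations, with 20
studies per regime in the test suite and 12 per regime in the acceptance
script. These sizes keep a complete study (EEG synthesis, ~3000 single-trial
spectral fits, regressions) at roughly ten seconds while leaving the
group-level effects decisively powered; the full-scale design (36/900/32,
2000 permutations) remains the generator default and runs through the same
code paths.

## Known limitations

* The adjacency approximates, not reproduces, the classical 32-channel
  template (mean degree 5.1 vs 6.0).
* The measured aperiodic exponent retains a small residual sensitivity to
  very large oscillatory drifts; the guard-banded refit reduces this to
  within the nominal false-positive rate under the default conditions.
* EDF input is not implemented; epochs round-trip through a documented raw
  binary + JSON sidecar container instead (trial tables through CSV,
  configs through YAML/JSON).
* Mixed-effects single-stage estimation, regularised regression, TFCE and
  cluster-size statistics are out of scope by design.
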