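# toteeg — time-on-task EEG analysis

Over a long experimental session, EEG oscillations drift: alpha-band
(8–13 Hz) power rises with time on task, alpha peak frequency falls, beta
power rises weakly, while the broadband aperiodic (1/f) background stays
put. Behaviour drifts too — reaction times speed up with practice. Any two
measures that share such a drift will correlate across trials, so a
single-trial regression of alpha on RT can report a "brain–behaviour
relationship" that is pure shared trend. `toteeg` is a toolkit for
quantifying these drifts and for telling spurious from genuine coupling,
aimed at cognitive-neurophysiology researchers analysing single-trial EEG.

It provides, as composable modules:

- **`synth`** — a synthetic session generator (2-AFC contrast-discrimination
  design: 900 trials in 5 blocks, 32 channels at 512 Hz, epochs −2.5–1.5 s)
  with configurable time-on-task drifts, a within-block alpha "reset", and
  three coupling regimes (`none`, `spurious`, `genuine`), plus latent
  ground-truth columns for validation;
- **`spectral`** — Hann-tapered, zero-padded FFT spectra (0.1 Hz resolution
  over 1–40 Hz) and sliding-window time–frequency power (1 Hz × 0.02 s);
- **`specfit`** — fixed-mode periodic/aperiodic spectral parameterization:
  `log10 P(f) = b − χ·log10 f + Σ Gaussians`, ≤ 4 peaks, 2-SD detection
  threshold, 2–15 Hz width limits, alpha-peak extraction in 6–15 Hz;
- **`permstats`** — cluster-based permutation tests (dependent-samples F
  across blocks, sign-flip t for coefficient maps) over channel × frequency
  (× time) grids with a BioSemi-32 sensor adjacency;
- **`trialreg`** — hierarchical two-stage single-trial regression
  `EEG = a + b_conf·Conf + b_diff·Diff + b_corr·Acc + b_RT·rank(RT)
  [+ b_ToT·rank(TrialOrder)]`, group t-tests with FDR, AIC model comparison
  and between-model coefficient contrasts;
- **`behavstats`** — 3-SD RT trimming, psychometric summaries, one/two-way
  repeated-measures ANOVA with Mauchly's test and Greenhouse–Geisser
  correction, Tukey HSD;
- **`pipeline` / `toteeg` CLI** — the full study replica
  (simulate → spectra → fit → cluster stats → regressions → AIC) with
  reproducible report bundles.

## Worked example: a spurious alpha–RT correlation, explained away

Simulate a 12-participant study in the *spurious* regime (alpha power and RT
both drift with trial order, with no trial-wise coupling), parameterize
pre-stimulus single-trial spectra, and run the two-stage regression with and
without trial order:

```python
from toteeg import SessionConfig
from toteeg.pipeline import participant_alpha_measures, alpha_regression_suite

config = SessionConfig.spurious_regime(
    n_participants=12, trials_per_block=25, n_channels=8,
    epoch_window=(-1.0, 1.0), seed=7)
measures = {pid: participant_alpha_measures(config, pid, window=(-1.0, 0.0))
            for pid in range(1, config.n_participants + 1)}
suite = alpha_regression_suite(measures, outcomes=("alpha_pow",))["alpha_pow"]

no = suite["group_no_tot"].set_index("predictor")
wi = suite["group_with_tot"].set_index("predictor")
print(f"alpha power ~ RT   (no ToT):  t = {no.loc['rt','t']:.2f}, p_fdr = {no.loc['rt','p_fdr']:.2g}")
print(f"alpha power ~ RT   (with ToT): t = {wi.loc['rt','t']:.2f}, p_fdr = {wi.loc['rt','p_fdr']:.2g}")
print(f"alpha power ~ ToT  (with ToT): t = {wi.loc['tot','t']:.2f}, p_fdr = {wi.loc['tot','p_fdr']:.2g}")
print(f"dAIC (noToT - withToT): mean = {suite['aic'].mean_delta:.1f}, paired-t p = {suite['aic'].p:.2g}")
```

prints

```
alpha power ~ RT   (no ToT):  t = -12.16, p_fdr = 4.1e-07
alpha power ~ RT   (with ToT): t = -0.66, p_fdr = 0.57
alpha power ~ ToT  (with ToT): t = 7.52, p_fdr = 5.8e-05
dAIC (noToT - withToT): mean = 5.1, paired-t p = 0.018
```

Without trial order in the model, higher pre-stimulus alpha power predicts
faster responses overwhelmingly (t = −12.2) — yet the generator embedded no
trial-wise coupling at all. Adding trial order abolishes the effect
(t = −0.66), reveals the underlying drift (positive ToT coefficient), and
the ToT model wins the AIC comparison (positive ΔAIC). In the `genuine`
regime, the post-stimulus alpha–confidence association survives the same
control — the signature that separates real coupling from shared drift.

The same chain is available from the shell:

```bash
toteeg run-all --regime spurious --participants 6 --seed 1 --out results/run1
toteeg simulate --regime genuine --participants 2 --seed 2 --out scratch/sim
toteeg fit --epochs scratch/sim/epochs_p01 --window -1.0 0.0 --out scratch/fits.csv
```

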