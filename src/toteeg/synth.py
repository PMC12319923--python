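"""Synthetic session generator: behaviour plus multichannel EEG epochs.

The generator emulates the statistical structure of a 2-AFC visual
discrimination session with slow time-on-task (ToT) drifts:

* alpha-band oscillatory power increases over the session and dips at the
  start of each block (a within-block "reset" that decays over the first
  ~12 trials);
* alpha centre frequency decreases over the session;
* beta power increases weakly;
* the aperiodic 1/f background stays stationary;
* reaction times speed up with trial order and with stimulus contrast;
* accuracy and confidence follow lapse-adjusted logistic psychometric
  functions of contrast, with a practice decrement confined to early blocks.

Coupling regimes
----------------
``none`` / ``spurious``
    No trial-wise brain-behaviour coupling. Under the default drifts both
    alpha and RT trend with trial order, so their *marginal* correlation is
    entirely carried by time-on-task (the spurious regime); with all drift
    slopes zeroed there is no correlation at all.
``genuine``
    A per-trial latent desynchronisation ``d`` attenuates post-stimulus
    alpha/beta power and raises the probability of a confident response, and
    pre-stimulus alpha level additively slows RT. These couplings survive
    regressing out trial order.

Signal model
------------
Each epoch is coloured Gaussian noise synthesised in the frequency domain:
the background has power spectral density ``10**offset * f**-exponent``
(fixed-mode aperiodic form), and each oscillation is narrowband Gaussian
noise with a Gaussian-shaped PSD bump centred at the trial's latent centre
frequency. Latent oscillatory "power" is expressed as peak height in log10
units above the aperiodic background at the centre frequency — the same
quantity the spectral parameterizer estimates — so recovery tests compare
like with like. Post-stimulus modulation is applied as a time-domain
amplitude envelope on the oscillatory components (t >= 0 only).

Randomness uses counter-based per-participant / per-trial substreams spawned
from the single config seed, so regenerating one participant (or one trial's
epoch) is independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SessionConfig
from .containers import EpochArray
from .layouts import BIOSEMI32_NAMES

__all__ = ["generate_trial_table", "generate_session_eeg", "generate_study",
           "participant_traits", "ParticipantTraits"]

# substream tags (spawn keys) -- keep stable across versions
_STREAM_TRAITS = 0
_STREAM_BEHAV = 1
_STREAM_EEG = 2

_F_FLOOR = 0.75       # Hz; aperiodic PSD flattened below this to bound variance
_ALPHA_BAND_SD = 1.2  # Hz; Gaussian PSD bump width of simulated oscillations
_BETA_BAND_SD = 1.8


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed, spawn_key=key)))


@dataclass
class ParticipantTraits:
    """Per-participant random effects, drawn from a dedicated substream."""

    alpha_cf0: float
    alpha_pow0: float
    rt_base: float
    aperiodic_exponent: float
    aperiodic_offset: float


def participant_traits(config: SessionConfig, participant: int) -> ParticipantTraits:
    rng = _rng(config.seed, participant, _STREAM_TRAITS)
    z = rng.standard_normal(5)
    return ParticipantTraits(
        alpha_cf0=config.alpha_cf0 + config.alpha_cf0_sd * z[0],
        alpha_pow0=max(config.alpha_pow0 + config.alpha_pow0_sd * z[1], 0.0),
        rt_base=max(config.rt_base + config.rt_base_sd * z[2], 0.3),
        aperiodic_exponent=max(config.aperiodic_exponent + config.aperiodic_exponent_sd * z[3], 0.1),
        aperiodic_offset=config.aperiodic_offset + config.aperiodic_offset_sd * z[4],
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _block_reset_factor(config: SessionConfig, within_block_index: np.ndarray) -> np.ndarray:
    """Multiplicative dip of oscillatory alpha power at block starts."""
    if config.alpha_block_reset == 0:
        return np.ones_like(within_block_index, dtype=float)
    dip = config.alpha_block_reset * np.exp(-(within_block_index - 1) / config.alpha_reset_tau)
    return 1.0 - dip


def generate_trial_table(config: SessionConfig, participant: int) -> pd.DataFrame:
    """One row per trial: design, behaviour, and latent ground-truth columns.

    Contrast levels are balanced within each block (``trials_per_block / 5``
    repetitions each), with order shuffled within block. Latent columns are
    prefixed ``true_`` and describe what the EEG generator will embed.
    """
    config.validate()
    traits = participant_traits(config, participant)
    rng = _rng(config.seed, participant, _STREAM_BEHAV)

    n_levels = len(config.contrast_levels)
    reps = config.trials_per_block // n_levels
    contrast_idx = np.concatenate([
        rng.permutation(np.repeat(np.arange(n_levels), reps))
        for _ in range(config.n_blocks)
    ])
    contrast = np.asarray(config.contrast_levels)[contrast_idx]
    n = config.n_trials
    trial_order = np.arange(1, n + 1)
    block = 1 + (trial_order - 1) // config.trials_per_block
    wbi = 1 + (trial_order - 1) % config.trials_per_block
    stimclass = np.where(rng.random(n) < 0.5, "number", "letter")

    # latent oscillatory state ------------------------------------------------
    t = trial_order - 1
    cf = (traits.alpha_cf0 + config.alpha_cf_slope * t
          + config.alpha_cf_noise_sd * rng.standard_normal(n))
    cf = np.clip(cf, 6.5, 14.5)
    h_raw = (traits.alpha_pow0 + config.alpha_pow_slope * t
             + config.alpha_pow_noise_sd * rng.standard_normal(n))
    h_raw = np.maximum(h_raw, 0.0)
    # reset dip acts on linear oscillation power q = 10**h - 1
    q_pre = (10.0 ** h_raw - 1.0) * _block_reset_factor(config, wbi)
    true_alpha_pow = np.log10(1.0 + q_pre)

    desync = rng.standard_normal(n)
    genuine = config.coupling_mode == "genuine"
    h_post = true_alpha_pow - (config.desync_mag * desync if genuine else 0.0)
    h_post = np.maximum(h_post, 0.0)

    h_beta = (config.beta_pow0 + config.beta_pow_slope * t
              + config.beta_pow_noise_sd * rng.standard_normal(n))
    h_beta = np.maximum(h_beta, 0.0)
    h_beta_post = h_beta - (0.5 * config.desync_mag * desync if genuine else 0.0)
    h_beta_post = np.maximum(h_beta_post, 0.0)

    # behaviour ---------------------------------------------------------------
    thr, slope, lapse = config.psychometric
    pa1, pa2 = config.practice_acc
    practice = np.where(block == 1, pa1, np.where(block == 2, pa2, 0.0))
    p_correct = 0.5 + (0.5 - lapse) * _logistic((contrast - thr) / slope - practice)
    accuracy = (rng.random(n) < p_correct).astype(int)

    cthr, cslope, _ = config.confidence_psychometric
    conf_logit = (contrast - cthr) / cslope
    if genuine:
        conf_logit = conf_logit + config.genuine_conf_gain * desync
    confidence = (rng.random(n) < _logistic(conf_logit)).astype(int)

    pr1, pr2 = config.practice_rt
    rt_det = (traits.rt_base
              + config.rt_contrast_slope * contrast_idx
              + config.rt_tot_slope * t
              + np.where(block == 1, pr1, np.where(block == 2, pr2, 0.0)))
    if genuine:
        rt_det = rt_det + config.genuine_rt_gain * (h_raw - traits.alpha_pow0)
    rt_noise = np.exp(np.log(config.rt_noise_median)
                      + config.rt_noise_sigma * rng.standard_normal(n))
    rt = np.maximum(rt_det, 0.05) + rt_noise

    return pd.DataFrame({
        "participant": participant,
        "block": block,
        "trial_order": trial_order,
        "within_block_index": wbi,
        "contrast": contrast,
        "stimclass": stimclass,
        "accuracy": accuracy,
        "confidence": confidence,
        "rt": rt,
        "true_alpha_cf": cf,
        "true_alpha_pow": true_alpha_pow,
        "true_alpha_pow_post": h_post,
        "true_beta_pow": h_beta,
        "true_beta_pow_post": h_beta_post,
        "true_desync": desync,
    })


# --------------------------------------------------------------------------
# EEG synthesis

def _channel_names(n: int) -> list[str]:
    if n <= len(BIOSEMI32_NAMES):
        return list(BIOSEMI32_NAMES[:n])
    return [f"Ch{i + 1:02d}" for i in range(n)]


def _channel_power_gain(n: int) -> np.ndarray:
    """Smooth spatial profile of oscillatory power across channels, mean 1."""
    idx = np.arange(n)
    gain = 1.0 + 0.4 * np.cos(2.0 * np.pi * idx / max(n, 1))
    return gain / gain.mean()


def _colored_noise(rng: np.random.Generator, psd: np.ndarray, n_samples: int,
                   sfreq: float, size: tuple = ()) -> np.ndarray:
    """Gaussian noise with target one-sided PSD, synthesised via irfft.

    ``psd`` has shape (..., n_rfft); the analysis-side density convention
    (``spectral.epoch_power_spectrum``) returns an unbiased estimate of it.
    """
    shape = size + (psd.shape[-1],)
    z = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)
    amp = np.sqrt(psd * sfreq * n_samples / 2.0)
    return np.fft.irfft(z * amp, n=n_samples, axis=-1)


def generate_session_eeg(table: pd.DataFrame, config: SessionConfig,
                         participant: int | None = None) -> EpochArray:
    """Synthesise epochs matching a trial table from ``generate_trial_table``.

    Each epoch is aperiodic background + alpha + beta narrowband noise, with
    post-stimulus (t >= 0) oscillatory amplitude set by the ``*_post`` latent
    columns. Channels receive a smooth oscillatory gain profile and
    independent background noise.
    """
    if participant is None:
        pids = table["participant"].unique()
        if len(pids) != 1:
            raise ValueError("table must contain exactly one participant")
        participant = int(pids[0])
    n_trials = len(table)
    if n_trials != config.n_trials:
        raise ValueError(
            f"table has {n_trials} trials but config specifies {config.n_trials}")

    traits = participant_traits(config, participant)
    t0, t1 = config.epoch_window
    n_samples = config.n_samples
    times = t0 + np.arange(n_samples) / config.sfreq
    if not np.any(np.isclose(times, 0.0, atol=1e-9)):
        raise ConfigurationError("time 0 must lie on the sample grid")

    freqs = np.fft.rfftfreq(n_samples, 1.0 / config.sfreq)
    f_safe = np.maximum(freqs, _F_FLOOR)
    bg_psd = 10.0 ** traits.aperiodic_offset * f_safe ** (-traits.aperiodic_exponent)
    bg_psd[0] = 0.0

    nch = config.n_channels
    gain = _channel_power_gain(nch)
    post = times >= 0.0

    cf = table["true_alpha_cf"].to_numpy()
    h_pre = table["true_alpha_pow"].to_numpy()
    h_post = table["true_alpha_pow_post"].to_numpy()
    hb_pre = table["true_beta_pow"].to_numpy()
    hb_post = table["true_beta_pow_post"].to_numpy()

    def _bump(center: float, width: float, peak_density: float) -> np.ndarray:
        return peak_density * np.exp(-0.5 * ((freqs - center) / width) ** 2)

    data = np.empty((n_trials, nch, n_samples))
    for i in range(n_trials):
        rng = _rng(config.seed, participant, _STREAM_EEG, i)
        bg = _colored_noise(rng, bg_psd, n_samples, config.sfreq, size=(nch,))

        bg_at_cf = 10.0 ** traits.aperiodic_offset * cf[i] ** (-traits.aperiodic_exponent)
        q_alpha = 10.0 ** h_pre[i] - 1.0
        alpha_psd = _bump(cf[i], _ALPHA_BAND_SD, bg_at_cf * q_alpha)[None, :] * gain[:, None]
        alpha = _colored_noise(rng, alpha_psd, n_samples, config.sfreq)
        r_alpha = (np.sqrt((10.0 ** h_post[i] - 1.0) / q_alpha)
                   if q_alpha > 0 else 1.0)

        bg_at_beta = 10.0 ** traits.aperiodic_offset * config.beta_cf ** (-traits.aperiodic_exponent)
        q_beta = 10.0 ** hb_pre[i] - 1.0
        beta_psd = _bump(config.beta_cf, _BETA_BAND_SD, bg_at_beta * q_beta)[None, :] * gain[:, None]
        beta = _colored_noise(rng, beta_psd, n_samples, config.sfreq)
        r_beta = (np.sqrt((10.0 ** hb_post[i] - 1.0) / q_beta)
                  if q_beta > 0 else 1.0)

        alpha[:, post] *= r_alpha
        beta[:, post] *= r_beta
        data[i] = bg + alpha + beta

    return EpochArray(data=data, times=times, sfreq=config.sfreq,
                      ch_names=_channel_names(nch))


def generate_study(config: SessionConfig, participants: list[int] | None = None,
                   with_eeg: bool = True):
    """Yield ``(participant, table, epochs_or_None)`` for each participant."""
    if participants is None:
        participants = list(range(1, config.n_participants + 1))
    for pid in participants:
        table = generate_trial_table(config, pid)
        epochs = generate_session_eeg(table, config, pid) if with_eeg else None
        yield pid, table, epochs
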