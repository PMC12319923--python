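"""Fourier spectral and time-frequency decomposition.

Single-trial spectra are Hann-tapered FFTs of a fixed time window,
zero-padded to a configurable length: a 1-s window padded to 10 s yields the
0.1 Hz grid over 1-40 Hz used for spectral parameterization. Time-frequency
power uses overlapping 0.5-s Hann windows stepped by 0.02 s and padded to
1 s (1 Hz resolution).

Scaling follows a one-sided density convention,
``P(f) = |FFT(w*x)|^2 * 2 / (fs * sum(w^2))``,
which returns an unbiased estimate of the power spectral density of a
stationary input. All downstream analyses (ranks, log-ratios, within-grid
contrasts) are invariant to the overall scale, so any consistent convention
would do; this one makes generator recovery tests exact.

Analysis windows are half-open ``[t0, t1)`` so that pre-stimulus [-1, 0) and
post-stimulus [0, 1) windows do not share the t = 0 sample.
"""

from __future__ import annotations

import numpy as np
from scipy.signal.windows import hann

from .containers import EpochArray, PowerSpectrum, TFPower

__all__ = ["epoch_power_spectrum", "time_frequency", "band_average"]


def _window(n: int, taper: str | None) -> np.ndarray:
    if taper is None:
        return np.ones(n)
    if taper == "hann":
        return hann(n, sym=False)
    raise ValueError(f"unknown taper {taper!r}")


def epoch_power_spectrum(epochs: EpochArray,
                         time_window: tuple[float, float] = (-1.0, 0.0),
                         pad_length: float = 10.0,
                         freq_range: tuple[float, float] = (1.0, 40.0),
                         taper: str | None = "hann") -> PowerSpectrum:
    """Per-trial, per-channel tapered and zero-padded power spectra.

    Frequency spacing is exactly ``1 / pad_length``.
    """
    t0, t1 = time_window
    if t0 < epochs.times[0] - 1e-9 or t1 > epochs.times[-1] + 1.0 / epochs.sfreq + 1e-9:
        raise ValueError("time_window lies outside the epoch extent")
    mask = epochs.time_mask(t0, t1)
    n_win = int(mask.sum())
    if n_win < 2:
        raise ValueError("time_window too short")
    if pad_length < (t1 - t0) - 1e-9:
        raise ValueError("pad_length must be at least the window duration")

    w = _window(n_win, taper)
    n_fft = int(round(pad_length * epochs.sfreq))
    segment = epochs.data[..., mask] * w
    spec = np.fft.rfft(segment, n=n_fft, axis=-1)
    power = (spec.real ** 2 + spec.imag ** 2) * (2.0 / (epochs.sfreq * np.sum(w ** 2)))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / epochs.sfreq)

    sel = (freqs >= freq_range[0] - 1e-9) & (freqs <= freq_range[1] + 1e-9)
    return PowerSpectrum(
        freqs=freqs[sel], power=power[..., sel],
        meta={"taper": taper or "boxcar", "pad_length": pad_length,
              "time_window": [t0, t1], "sfreq": epochs.sfreq},
    )


def time_frequency(epochs: EpochArray,
                   win_length: float = 0.5,
                   step: float = 0.02,
                   pad_length: float = 1.0,
                   time_range: tuple[float, float] = (-1.0, 1.0),
                   freq_range: tuple[float, float] = (1.0, 40.0),
                   taper: str | None = "hann") -> TFPower:
    """Sliding-window Hann-tapered power; 1 Hz x 0.02 s grid by default.

    Window centres run over ``time_range``; a centre whose window would
    extend past the epoch edges yields NaN at that time point (missing, not
    zero-padded in time).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(round(win_length * epochs.sfreq))
    if n_win > epochs.times.size:
        raise ValueError("window longer than epoch")
    w = _window(n_win, taper)
    n_fft = int(round(pad_length * epochs.sfreq))
    if n_fft < n_win:
        raise ValueError("pad_length must be at least win_length")
    freqs = np.fft.rfftfreq(n_fft, 1.0 / epochs.sfreq)
    fsel = (freqs >= freq_range[0] - 1e-9) & (freqs <= freq_range[1] + 1e-9)
    scale = 2.0 / (epochs.sfreq * np.sum(w ** 2))

    n_steps = int(round((time_range[1] - time_range[0]) / step))
    centers = time_range[0] + step * np.arange(n_steps + 1)
    half = win_length / 2.0
    t_first = epochs.times[0]

    n_trials, n_ch, _ = epochs.data.shape
    out = np.full((n_trials, n_ch, int(fsel.sum()), centers.size), np.nan)
    for k, tc in enumerate(centers):
        start = int(round((tc - half - t_first) * epochs.sfreq))
        stop = start + n_win
        if start < 0 or stop > epochs.times.size:
            continue  # window exceeds epoch: left as missing
        seg = epochs.data[..., start:stop] * w
        spec = np.fft.rfft(seg, n=n_fft, axis=-1)
        out[..., k] = (spec.real ** 2 + spec.imag ** 2)[..., fsel] * scale

    return TFPower(power=out, freqs=freqs[fsel], times=centers,
                   meta={"win_length": win_length, "step": step,
                         "pad_length": pad_length, "taper": taper or "boxcar"})


def band_average(power: PowerSpectrum | TFPower,
                 band: tuple[float, float],
                 channels: list[int] | list[str] | None = None,
                 ch_names: list[str] | None = None,
                 zscore: bool = False) -> np.ndarray:
    """Mean power over a frequency band and channel subset.

    Returns one value per trial for a PowerSpectrum and a trials x times
    array for TFPower. ``channels`` may be indices, or names when
    ``ch_names`` is given. With ``zscore=True`` the trial series is
    z-scored across trials.
    """
    freqs = power.freqs
    fsel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not fsel.any():
        raise ValueError("band outside frequency grid")

    arr = power.power
    if channels is not None:
        if len(channels) == 0:
            raise ValueError("empty channel selection")
        if ch_names is not None and isinstance(channels[0], str):
            channels = [ch_names.index(c) for c in channels]
        arr = arr[:, np.asarray(channels, dtype=int)]

    if isinstance(power, TFPower):
        out = arr[:, :, fsel, :].mean(axis=(1, 2))
    else:
        out = arr[..., fsel].mean(axis=-1)
        if out.ndim == 2:  # trials x channels
            out = out.mean(axis=1)
    if zscore:
        mu = np.nanmean(out, axis=0)
        sd = np.nanstd(out, axis=0, ddof=1)
        out = (out - mu) / np.where(sd > 0, sd, 1.0)
    return out
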