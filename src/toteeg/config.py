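"""Session configuration for the synthetic time-on-task study generator.

The defaults replicate the design of a 2-AFC visual discrimination session:
36 participants, 900 trials in 5 blocks of 180, 32-channel EEG at 512 Hz,
4-s epochs from -2.5 to 1.5 s around stimulus onset, five stimulus-contrast
levels, and slow within-session drifts of alpha power (up), alpha centre
frequency (down) and beta power (weakly up) on top of a stationary 1/f
aperiodic background.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SessionConfig", "ConfigurationError", "COUPLING_MODES"]

COUPLING_MODES = ("none", "spurious", "genuine")


class ConfigurationError(ValueError):
    """Raised when a SessionConfig violates its invariants."""


@dataclass
class SessionConfig:
    """Parameters of one simulated study.

    Drift slopes are expressed per trial (session-global trial order), so a
    session-long effect is ``slope * (n_trials - 1)``. Power parameters are in
    log10-power units above the aperiodic background, matching the scale on
    which oscillatory peak height is measured by the spectral parameterizer.
    """

    # design
    n_participants: int = 36
    n_blocks: int = 5
    trials_per_block: int = 180
    contrast_levels: tuple[float, ...] = (0.075, 0.15, 0.225, 0.3, 0.375)
    sfreq: float = 512.0
    epoch_window: tuple[float, float] = (-2.5, 1.5)
    n_channels: int = 32

    # aperiodic background (log10 P(f) = offset - exponent * log10 f)
    aperiodic_offset: float = 1.0
    aperiodic_exponent: float = 1.0

    # alpha oscillation and its time-on-task drifts
    alpha_cf0: float = 10.5          # Hz at session start
    alpha_cf_slope: float = -1.0 / 900.0   # Hz per trial (<= 0)
    alpha_pow0: float = 0.55         # log10 units above aperiodic
    alpha_pow_slope: float = 0.40 / 900.0  # log10 units per trial (>= 0)
    alpha_block_reset: float = 0.5   # fractional power dip at block start
    alpha_reset_tau: float = 4.0     # trials; dip decays exp(-(i-1)/tau)

    # beta oscillation (weaker drift, no block reset)
    beta_cf: float = 20.0
    beta_pow0: float = 0.20
    beta_pow_slope: float = 0.10 / 900.0

    # behaviour
    rt_base: float = 0.85            # s
    rt_tot_slope: float = -2.0e-4    # s per trial (<= 0, speeding up)
    rt_contrast_slope: float = -0.05  # s per contrast step (easier = faster)
    psychometric: tuple[float, float, float] = (0.15, 0.04, 0.02)
    confidence_psychometric: tuple[float, float, float] = (0.18, 0.06, 0.0)
    # practice effects confined to the first two blocks: logit decrement on
    # accuracy and additive RT cost in (block 1, block 2)
    practice_acc: tuple[float, float] = (0.6, 0.25)
    practice_rt: tuple[float, float] = (0.08, 0.03)

    # brain-behaviour coupling regime
    coupling_mode: str = "none"
    genuine_conf_gain: float = 0.0   # logit units per SD of desync latent
    genuine_rt_gain: float = 0.0     # s per log10 unit of pre-stim alpha
    desync_mag: float = 0.25         # log10 units of post-stim alpha per SD

    # trial-to-trial noise
    alpha_cf_noise_sd: float = 0.3   # Hz
    alpha_pow_noise_sd: float = 0.15  # log10 units
    beta_pow_noise_sd: float = 0.10
    rt_noise_median: float = 0.15    # s, median of additive lognormal noise
    rt_noise_sigma: float = 0.40     # lognormal shape

    # between-participant heterogeneity (SDs of trait offsets)
    alpha_cf0_sd: float = 0.6
    alpha_pow0_sd: float = 0.10
    rt_base_sd: float = 0.08
    aperiodic_exponent_sd: float = 0.08
    aperiodic_offset_sd: float = 0.10

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.contrast_levels = tuple(float(c) for c in self.contrast_levels)
        self.epoch_window = (float(self.epoch_window[0]), float(self.epoch_window[1]))
        for name in ("psychometric", "confidence_psychometric",
                     "practice_acc", "practice_rt"):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be positive")
        cl = self.contrast_levels
        if any(not (0.0 < c <= 1.0) for c in cl):
            raise ConfigurationError("contrast levels must lie in (0, 1]")
        if any(b <= a for a, b in zip(cl, cl[1:])):
            raise ConfigurationError("contrast levels must be strictly increasing")
        if self.trials_per_block % len(cl) != 0:
            raise ConfigurationError(
                "trials_per_block must be divisible by the number of contrast "
                "levels for a balanced within-block design"
            )
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ConfigurationError("epoch_window must be an increasing pair")
        if self.sfreq <= 0:
            raise ConfigurationError("sfreq must be positive")
        if self.coupling_mode not in COUPLING_MODES:
            raise ConfigurationError(
                f"coupling_mode must be one of {COUPLING_MODES}, got {self.coupling_mode!r}"
            )
        if self.alpha_cf_slope > 0:
            raise ConfigurationError("alpha_cf_slope must be <= 0")
        if self.alpha_pow_slope < 0:
            raise ConfigurationError("alpha_pow_slope must be >= 0")
        if self.rt_tot_slope > 0:
            raise ConfigurationError("rt_tot_slope must be <= 0")
        if not (0.0 <= self.alpha_block_reset < 1.0):
            raise ConfigurationError("alpha_block_reset must be in [0, 1)")
        for name in (
            "alpha_cf_noise_sd", "alpha_pow_noise_sd", "beta_pow_noise_sd",
            "rt_noise_median", "rt_noise_sigma", "alpha_cf0_sd", "alpha_pow0_sd",
            "rt_base_sd", "aperiodic_exponent_sd", "aperiodic_offset_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sfreq))

    def replace(self, **kwargs) -> "SessionConfig":
        return dataclasses.replace(self, **kwargs)

    # ------------------------------------------------------------------
    # regime factories: the three coupling regimes used throughout.
    # Session-total drifts (alpha power +0.40 log10 units, alpha CF -1.0 Hz,
    # beta power +0.10, RT -0.18 s over the session) are held fixed when a
    # smaller trial count is requested, so a desk-scale replica preserves
    # the session-level drift structure of the full design.
    _SESSION_DRIFTS = {"alpha_pow_slope": 0.40, "alpha_cf_slope": -1.0,
                       "beta_pow_slope": 0.10, "rt_tot_slope": -0.18}

    @classmethod
    def _with_scaled_drifts(cls, base: dict, kwargs: dict) -> "SessionConfig":
        base.update(kwargs)
        n = base.get("n_blocks", 5) * base.get("trials_per_block", 180)
        for name, total in cls._SESSION_DRIFTS.items():
            if name not in base:
                base[name] = total / n
        return cls(**base)

    @classmethod
    def null_regime(cls, **kwargs) -> "SessionConfig":
        """No drifts, no coupling: alpha, beta, RT all stationary."""
        base = dict(
            coupling_mode="none",
            alpha_cf_slope=0.0, alpha_pow_slope=0.0, beta_pow_slope=0.0,
            rt_tot_slope=0.0, alpha_block_reset=0.0,
            practice_acc=(0.0, 0.0), practice_rt=(0.0, 0.0),
        )
        base.update(kwargs)
        return cls(**base)

    @classmethod
    def spurious_regime(cls, **kwargs) -> "SessionConfig":
        """Default drifts on, no trial-wise brain-behaviour coupling.

        Alpha and RT each drift with trial order, so their marginal
        correlation is carried entirely by time-on-task.
        """
        return cls._with_scaled_drifts(dict(coupling_mode="spurious"), kwargs)

    @classmethod
    def genuine_regime(cls, **kwargs) -> "SessionConfig":
        """Drifts on plus trial-wise coupling: post-stimulus alpha/beta
        desynchronisation raises confidence, pre-stimulus alpha slows RT."""
        return cls._with_scaled_drifts(
            dict(coupling_mode="genuine", genuine_conf_gain=1.0,
                 genuine_rt_gain=0.08), kwargs)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(self.to_dict()), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
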