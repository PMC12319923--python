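"""In-memory containers for epochs and spectral data, with text/binary IO.

EpochArray, PowerSpectrum and TFPower are light numpy wrappers: the arrays
stay plain ndarrays, the containers carry the axes (time, frequency, channel
names) and the provenance metadata downstream operations need. Arrays can be
round-tripped through a raw little-endian binary file plus a JSON sidecar
describing shape, dtype and axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochArray", "PowerSpectrum", "TFPower",
    "read_trial_table", "write_trial_table", "validate_trial_table",
    "TRIAL_TABLE_COLUMNS",
]

#: documented trial-table header; latent ground-truth columns are prefixed
#: ``true_`` and exist only for validation, never as analysis inputs
TRIAL_TABLE_COLUMNS = [
    "participant", "block", "trial_order", "within_block_index",
    "contrast", "stimclass", "accuracy", "confidence", "rt",
]


def _save_binary(path_prefix: str | Path, data: np.ndarray, meta: dict) -> None:
    prefix = Path(path_prefix)
    arr = np.ascontiguousarray(data, dtype=np.float32)
    arr.tofile(prefix.with_suffix(".bin"))
    sidecar = dict(meta)
    sidecar["shape"] = list(arr.shape)
    sidecar["dtype"] = "<f4"
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def _load_binary(path_prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".bin"), dtype=meta["dtype"])
    return data.reshape(meta["shape"]).astype(np.float64), meta


@dataclass
class EpochArray:
    """trials x channels x samples time series, time axis relative to stimulus."""

    data: np.ndarray
    times: np.ndarray          # seconds, uniform grid containing t = 0
    sfreq: float
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("EpochArray data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel name count does not match data")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for the half-open window [t0, t1)."""
        return (self.times >= t0 - 1e-9) & (self.times < t1 - 1e-9)

    def save(self, path_prefix: str | Path) -> None:
        _save_binary(path_prefix, self.data, {
            "kind": "epochs", "sfreq": self.sfreq, "ch_names": self.ch_names,
            "tmin": float(self.times[0]),
        })

    @classmethod
    def load(cls, path_prefix: str | Path) -> "EpochArray":
        data, meta = _load_binary(path_prefix)
        n = data.shape[2]
        times = meta["tmin"] + np.arange(n) / meta["sfreq"]
        return cls(data=data, times=times, sfreq=meta["sfreq"], ch_names=list(meta["ch_names"]))


@dataclass
class PowerSpectrum:
    """Linear-scale spectral power on a uniform frequency grid.

    ``power`` is trials x channels x frequencies (or any leading shape whose
    last axis matches ``freqs``). Scaling follows a one-sided density
    convention (power / Hz); every downstream use is scale-invariant.
    """

    freqs: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.shape[-1] != self.freqs.size:
            raise ValueError("last power axis must match frequency grid")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def average_channels(self) -> "PowerSpectrum":
        if self.power.ndim < 2:
            return self
        return PowerSpectrum(self.freqs, self.power.mean(axis=-2), dict(self.meta))

    def average_trials(self) -> "PowerSpectrum":
        if self.power.ndim < 2:
            return self
        return PowerSpectrum(self.freqs, self.power.mean(axis=0), dict(self.meta))

    def save(self, path_prefix: str | Path) -> None:
        _save_binary(path_prefix, self.power, {
            "kind": "spectrum", "fmin": float(self.freqs[0]), "df": self.df,
            **{k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, list))},
        })


@dataclass
class TFPower:
    """trials x channels x frequencies x times sliding-window power.

    Time points whose analysis window would extend past the epoch edges are
    NaN rather than zero-padded in time.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.power.ndim != 4:
            raise ValueError("TF power must be trials x channels x freqs x times")
        if self.power.shape[2] != self.freqs.size or self.power.shape[3] != self.times.size:
            raise ValueError("TF power axes do not match grids")
        with np.errstate(invalid="ignore"):
            if np.any(self.power < 0):
                raise ValueError("power must be non-negative")

    def save(self, path_prefix: str | Path) -> None:
        _save_binary(path_prefix, self.power, {
            "kind": "tfr", "fmin": float(self.freqs[0]),
            "df": float(self.freqs[1] - self.freqs[0]),
            "tmin": float(self.times[0]),
            "dt": float(self.times[1] - self.times[0]),
        })


# ----------------------------------------------------------------------
# trial table IO

def validate_trial_table(table: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for pid, sub in table.groupby("participant"):
        order = sub["trial_order"].to_numpy()
        if not (np.all(np.diff(order) > 0) and len(set(order)) == len(order)):
            raise ValueError(f"trial_order not strictly increasing for participant {pid}")
    if (table["rt"] <= 0).any():
        raise ValueError("rt must be positive")
    for col in ("accuracy", "confidence"):
        if not set(np.unique(table[col])) <= {0, 1}:
            raise ValueError(f"{col} must be binary 0/1")


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(table)
    table.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_trial_table(table)
    return table
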