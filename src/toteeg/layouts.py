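"""Sensor layouts: 2-D channel positions for adjacency construction.

The 32-channel layout mirrors the standard BioSemi 32 montage. Coordinates
come from the standard montage shipped with MNE-Python, projected to the 2-D
plane by azimuthal-equidistant projection (the usual topographic-map view);
they are unitless layout coordinates, adequate for neighbourhood geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ChannelLayout", "BIOSEMI32_NAMES", "biosemi32_layout"]

#: BioSemi 32-channel labels in standard A1..A32 order
BIOSEMI32_NAMES = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3", "CP1", "CP5",
    "P7", "P3", "Pz", "PO3", "O1", "Oz", "O2", "PO4", "P4", "P8",
    "CP6", "CP2", "C4", "T8", "FC6", "FC2", "F4", "F8", "AF4", "Fp2",
    "Fz", "Cz",
)


@dataclass
class ChannelLayout:
    """Named 2-D sensor positions (unitless layout coordinates)."""

    names: list[str]
    pos: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.pos = np.asarray(self.pos, dtype=np.float64)
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        if self.pos.shape != (len(self.names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "ChannelLayout":
        idx = [self.names.index(n) for n in names]
        return ChannelLayout(names=list(names), pos=self.pos[idx])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"name": self.names,
                      "x": self.pos[:, 0], "y": self.pos[:, 1]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelLayout":
        df = pd.read_csv(path)
        return cls(names=df["name"].tolist(), pos=df[["x", "y"]].to_numpy())


def _azimuthal_equidistant(xyz: np.ndarray) -> np.ndarray:
    """Project unit-sphere head points to the plane, vertex at the origin."""
    xyz = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    theta = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    r = theta / (np.pi / 2.0)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def biosemi32_layout(n_channels: int = 32) -> ChannelLayout:
    """Standard BioSemi-32 layout (optionally the first ``n_channels``)."""
    import mne  # lazy: only needed when geometry is requested

    montage = mne.channels.make_standard_montage("biosemi32")
    ch_pos = montage.get_positions()["ch_pos"]
    names = list(BIOSEMI32_NAMES[:n_channels])
    xyz = np.array([ch_pos[name] for name in names])
    return ChannelLayout(names=names, pos=_azimuthal_equidistant(xyz))
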