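"""The four-channel chromatogram container.

A :class:`Chromatogram` holds five detector traces (refractive index,
UV absorbance at 280 nm, right- and low-angle light scattering, and the
differential-viscometer pressure signal) on a common, strictly increasing
elution-volume grid, plus acquisition metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CHANNELS", "Chromatogram"]

CHANNELS = ("RI", "UV280", "RALS", "LALS", "DP")


@dataclass
class Chromatogram:
    volume: np.ndarray                      # mL, uniform strictly increasing grid
    channels: dict[str, np.ndarray]         # detector units per channel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 1 or len(self.volume) < 2:
            raise ValueError("volume grid must be a 1-D array with >= 2 points")
        if not np.all(np.diff(self.volume) > 0):
            raise ValueError("volume grid must be strictly increasing")
        missing = [ch for ch in CHANNELS if ch not in self.channels]
        if missing:
            raise ValueError(f"missing channel(s): {', '.join(missing)}")
        clean = {}
        for ch in CHANNELS:
            arr = np.asarray(self.channels[ch], dtype=float)
            if arr.shape != self.volume.shape:
                raise ValueError(f"channel {ch} length {arr.shape} != grid {self.volume.shape}")
            clean[ch] = arr
        self.channels = clean

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    @property
    def step(self) -> float:
        return float(self.volume[1] - self.volume[0])

    def copy(self) -> "Chromatogram":
        return Chromatogram(self.volume.copy(),
                            {ch: arr.copy() for ch, arr in self.channels.items()},
                            dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        data = {"volume_mL": self.volume}
        data.update({ch: self.channels[ch] for ch in CHANNELS})
        return pd.DataFrame(data)

    def plot(self, ax=None, normalise: bool = True):
        """Overlay the five channels (optionally peak-normalised)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for ch in CHANNELS:
            y = self.channels[ch]
            top = np.max(np.abs(y))
            if normalise and top > 0:
                y = y / top
            ax.plot(self.volume, y, label=ch)
        ax.set_xlabel("elution volume (mL)")
        ax.set_ylabel("normalised signal" if normalise else "detector signal")
        ax.legend(frameon=False)
        return ax
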