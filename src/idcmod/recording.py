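"""Multichannel extracellular recording container and epoch conventions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording", "EpochWindows", "DEFAULT_EPOCHS"]


@dataclass(frozen=True)
class EpochWindows:
    """Analysis windows (s) of the 90 s pre / during / post iDC protocol.

    A 500 ms guard at each epoch edge is excluded, leaving 29 s windows.
    """

    pre: tuple[float, float] = (0.5, 29.5)
    during: tuple[float, float] = (30.5, 59.5)
    post: tuple[float, float] = (60.5, 89.5)

    def __post_init__(self) -> None:
        seq = [*self.pre, *self.during, *self.post]
        if any(b <= a for a, b in zip(seq[:-1], seq[1:])):
            raise ValueError("epochs must be ordered and non-overlapping")


DEFAULT_EPOCHS = EpochWindows()


@dataclass
class Recording:
    """Channels x samples array (microvolts) with probe metadata.

    ``channel_depths_mm`` increase with row index (superficial to deep),
    matching the 32-contact, 50 um pitch laminar probe layout.
    """

    samples: np.ndarray          # (channels, time), microvolts
    sampling_rate: float = 24414.0
    channel_depths_mm: np.ndarray | None = None
    epochs: EpochWindows = field(default_factory=EpochWindows)
    onsets_s: np.ndarray | None = None   # stimulus onsets, seconds
    intensity_ma: float | None = None
    idc_amplitude_ua: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels, time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.channel_depths_mm is not None:
            self.channel_depths_mm = np.asarray(self.channel_depths_mm, dtype=float)
            if self.channel_depths_mm.size != self.samples.shape[0]:
                raise ValueError("one depth per channel required")
            if np.any(np.diff(self.channel_depths_mm) <= 0):
                raise ValueError("channel depths must be strictly increasing")
        if self.onsets_s is not None:
            self.onsets_s = np.asarray(self.onsets_s, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


def default_channel_depths(n_channels: int = 32, pitch_mm: float = 0.05,
                           top_mm: float = 0.1) -> np.ndarray:
    """Contact depths of the laminar probe: 50 um pitch spanning 1.55 mm."""
    return top_mm + pitch_mm * np.arange(n_channels)
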