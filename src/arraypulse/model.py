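"""Core containers for arrayed pulse recordings.

The sensor is a 3 x 4 grid of capacitive pressure elements strapped over the
radial artery: three transverse rows (the radial, intermediate and ulnar
passages, RP/IP/UP) times four positions along the artery axis.  A recording
is the 12-channel pressure time series sampled at a common rate (100 Hz by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, FormatError

N_CHANNELS = 12
GROUPS = ("RP", "IP", "UP", "mean")
PASSAGES = ("RP", "IP", "UP")


@dataclass(frozen=True)
class ChannelLayout:
    """Mapping from channel index (0..11) to a cell of the 3 x 4 grid.

    Rows are transverse passages (RP nearest the radius, then IP, UP);
    columns run along the artery axis.
    """

    channel_to_cell: Mapping[int, tuple[int, int]]
    row_labels: tuple[str, str, str] = ("RP", "IP", "UP")
    n_rows: int = 3
    n_cols: int = 4

    def __post_init__(self) -> None:
        if self.n_rows != 3 or self.n_cols != 4:
            raise ConfigError("layout must be a 3 x 4 grid")
        if len(set(self.row_labels)) != 3:
            raise ConfigError("row_labels must be 3 unique names")
        cells = set(self.channel_to_cell.values())
        expected = {(r, c) for r in range(3) for c in range(4)}
        if set(self.channel_to_cell) != set(range(N_CHANNELS)) or cells != expected:
            raise ConfigError(
                "channel_to_cell must map channels 0..11 bijectively onto the 3x4 grid"
            )

    @classmethod
    def default(cls) -> "ChannelLayout":
        """Channels 1-4 on the RP row, 5-8 on IP, 9-12 on UP, numbered axially."""
        return cls({ch: (ch // 4, ch % 4) for ch in range(N_CHANNELS)})

    def row_of(self, channel: int) -> int:
        return self.channel_to_cell[channel][0]

    def channels_in_row(self, row: int) -> list[int]:
        return sorted(ch for ch, (r, _) in self.channel_to_cell.items() if r == row)

    def channels_in_group(self, group: str) -> list[int]:
        """Channel indices belonging to a passage, or all 12 for 'mean'."""
        if group == "mean":
            return list(range(N_CHANNELS))
        try:
            row = self.row_labels.index(group)
        except ValueError:
            raise ConfigError(f"unknown group {group!r}") from None
        return self.channels_in_row(row)

    def frame(self, sample: np.ndarray) -> np.ndarray:
        """Arrange one 12-channel sample into the 3 x 4 spatial grid."""
        out = np.empty((3, 4), dtype=float)
        for ch, (r, c) in self.channel_to_cell.items():
            out[r, c] = sample[ch]
        return out


@dataclass(frozen=True)
class FootprintSpec:
    """Physical extent of the sensor footprint.

    ``width`` spans the three transverse rows (x axis), ``length`` the four
    axial columns (y axis).  The element pitch of the array is not published,
    so the default footprint is the unit square; physical dimensions scale
    every volume linearly and leave all ratio features unchanged.
    """

    width: float = 1.0
    length: float = 1.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.length > 0):
            raise ConfigError("footprint dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.length

    def cell_area(self, n_grid: int) -> float:
        """Per-cell area S = A_total / N^2 of the interpolation grid."""
        return self.area / (n_grid * n_grid)


@dataclass
class ArrayRecording:
    """Time x 12-channel pressure sample matrix with its layout and metadata."""

    samples: np.ndarray
    fs: float = 100.0
    layout: ChannelLayout = field(default_factory=ChannelLayout.default)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise FormatError(
                f"samples must be (n, {N_CHANNELS}); got {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ConfigError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, index: int) -> np.ndarray:
        return self.samples[:, index]

    def frame_at(self, sample_index: int) -> np.ndarray:
        """3 x 4 spatial frame of amplitudes at one sample time."""
        return self.layout.frame(self.samples[sample_index])

    def with_samples(self, samples: np.ndarray) -> "ArrayRecording":
        return ArrayRecording(samples, fs=self.fs, layout=self.layout, meta=dict(self.meta))
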