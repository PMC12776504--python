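"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """Sensor-space multichannel time series with subject metadata.

    data is channels x samples; fs in Hz.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str = ""          # "HC" | "stroke"
    session: str = ""        # "" for HC, "pre" | "post" for stroke
    lesion_side: str = "none"  # "left" | "right" | "none"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class SourceTimeSeries:
    """Region-level continuous time courses (regions x samples)."""

    data: np.ndarray
    fs: float
    region_labels: list[str]
    subject_id: str = ""
    group: str = ""
    session: str = ""
    lesion_side: str = "none"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be regions x samples")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("region label count mismatch")


@dataclass
class SourceEpochs:
    """Epoched region time courses, regions x samples_per_epoch x n_epochs.

    The default configuration (28 regions, 4 s epochs at 500 Hz, 29 epochs)
    yields the canonical 28 x 2000 x 29 layout.
    """

    data: np.ndarray
    fs: float
    region_labels: list[str]
    band_tag: str = "broadband"
    subject_id: str = ""
    group: str = ""
    session: str = ""
    lesion_side: str = "none"
    flipped: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be regions x samples x epochs")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("region label count mismatch")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kw) -> "SourceEpochs":
        return replace(self, **kw)


@dataclass
class ConnectivityMatrix:
    """Directed band-averaged PDC weights.

    Entry ``weights[i, j]`` quantifies flow FROM region j TO region i.
    Diagonal is zeroed; entries lie in [0, 1].
    """

    weights: np.ndarray
    band_tag: str
    region_labels: list[str]
    subject_id: str = ""
    group: str = ""
    session: str = ""
    lesion_side: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if len(self.region_labels) != n:
            raise ValueError("region label count mismatch")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]
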