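"""Filtering, re-referencing, epoching, hemisphere flipping and band
decomposition.

Filters are zero-phase forward-backward Butterworth (4th order per pass),
the standard choice for resting-state EEG. The five canonical bands are
delta, theta, alpha, beta, gamma; delta is filtered as 1-4 Hz because the
broadband 1-50 Hz high-pass has already removed content below 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .atlas import RegionAtlas, default_atlas
from .containers import Recording, SourceEpochs, SourceTimeSeries


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"invalid band edges for {self.name!r}")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


def _band_sos(low_hz: float, high_hz: float, fs: float, order: int = 4):
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) invalid for fs={fs}"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_filter(recording: Recording, low_hz: float, high_hz: float,
                    order: int = 4) -> Recording:
    """Zero-phase band-pass per channel; output length equals input length."""
    sos = _band_sos(low_hz, high_hz, recording.fs, order)
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(data=data)


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if recording.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data=data)


def segment_epochs(series: SourceTimeSeries, epoch_seconds: float = 4.0,
                   n_epochs: int = 29, selection: str = "first",
                   seed: int | None = None) -> SourceEpochs:
    """Cut consecutive non-overlapping epochs from the start of the series.

    With ``selection="random"`` a seeded subset of the available consecutive
    epochs is kept instead of the first ``n_epochs``.
    """
    samples_per_epoch = int(round(epoch_seconds * series.fs))
    n_avail = series.data.shape[1] // samples_per_epoch
    if n_avail < n_epochs:
        raise ValueError(
            f"series provides {n_avail} epochs of {epoch_seconds}s, "
            f"{n_epochs} requested"
        )
    if selection == "first":
        keep = np.arange(n_epochs)
    elif selection == "random":
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(n_avail, size=n_epochs, replace=False))
    else:
        raise ValueError(f"unknown epoch selection {selection!r}")
    R = series.data.shape[0]
    trimmed = series.data[:, : n_avail * samples_per_epoch]
    epochs = trimmed.reshape(R, n_avail, samples_per_epoch)[:, keep, :]
    return SourceEpochs(
        data=np.moveaxis(epochs, 1, 2),  # regions x samples x epochs
        fs=series.fs,
        region_labels=list(series.region_labels),
        subject_id=series.subject_id,
        group=series.group,
        session=series.session,
        lesion_side=series.lesion_side,
    )


def concatenate_epochs(epochs: SourceEpochs) -> SourceTimeSeries:
    """Inverse of :func:`segment_epochs` for consecutive epochs."""
    R, S, E = epochs.data.shape
    data = np.moveaxis(epochs.data, 2, 1).reshape(R, S * E)
    return SourceTimeSeries(
        data, epochs.fs, list(epochs.region_labels),
        subject_id=epochs.subject_id, group=epochs.group,
        session=epochs.session, lesion_side=epochs.lesion_side,
    )


def flip_hemispheres(epochs: SourceEpochs,
                     lesion_side: str | None = None,
                     atlas: RegionAtlas | None = None) -> SourceEpochs:
    """Swap homotopic regions for right-lesion subjects.

    After flipping, left-indexed labels uniformly denote the affected
    hemisphere; for ``lesion_side`` in {"left", "none"} this is the identity.
    """
    atlas = atlas or default_atlas()
    side = epochs.lesion_side if lesion_side is None else lesion_side
    if side in ("left", "none", ""):
        return epochs.copy_with(flipped=True)
    if side != "right":
        raise ValueError(f"unknown lesion side {side!r}")
    if list(epochs.region_labels) != list(atlas.labels):
        raise ValueError("region labels do not match the atlas")
    perm = atlas.flip_permutation()
    return epochs.copy_with(data=epochs.data[perm], flipped=True)


def band_decompose(epochs: SourceEpochs,
                   bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                   order: int = 4) -> dict[str, SourceEpochs]:
    """Zero-phase band-filter the epoched data into each requested band."""
    out = {}
    for band in bands:
        sos = _band_sos(band.low_hz, band.high_hz, epochs.fs, order)
        data = signal.sosfiltfilt(sos, epochs.data, axis=1)
        out[band.name] = epochs.copy_with(data=data, band_tag=band.name)
    return out
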