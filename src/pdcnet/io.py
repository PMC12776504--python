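"""Readers and writers for the on-disk artifact formats.

Recordings travel as delimited numeric matrices (TSV, channels x samples)
with a JSON sidecar carrying labels, sampling rate and subject metadata;
EDF files are read through :mod:`mne` when available. Connectivity matrices
are CSV with region-label headers plus a JSON sidecar; epoched source
arrays are stored as compressed ``.npz`` containers with a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConnectivityMatrix, Recording, SourceEpochs
from .synth import CouplingGraph


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def digest(array) -> str:
    arr = np.ascontiguousarray(np.asarray(array, dtype=float))
    return hashlib.sha256(arr.tobytes()).hexdigest()[:16]


def write_recording(recording: Recording, path) -> Path:
    """Write a recording as TSV (channels x samples) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, recording.data, delimiter="\t", fmt="%.8g")
    meta = {
        "fs": recording.fs,
        "channel_labels": list(recording.channel_labels),
        "subject_id": recording.subject_id,
        "group": recording.group,
        "session": recording.session,
        "lesion_side": recording.lesion_side,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path, fs_override: float | None = None) -> Recording:
    """Read a recording from TSV/CSV (+ sidecar) or EDF.

    When an EDF header and ``fs_override`` disagree, the file's rate wins
    and a warning is emitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar} for {path}"
        )
    meta = json.loads(sidecar.read_text())
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    data = np.loadtxt(path, delimiter=delim, ndmin=2)
    if len(meta.get("channel_labels", [])) != data.shape[0]:
        raise ValueError(
            f"{path}: sidecar lists {len(meta.get('channel_labels', []))} "
            f"channels, file has {data.shape[0]} rows"
        )
    fs = float(meta.get("fs", fs_override or 0))
    if fs <= 0:
        raise ValueError(f"{path}: invalid sampling rate {fs}")
    return Recording(
        data=data, fs=fs, channel_labels=list(meta["channel_labels"]),
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group", ""), session=meta.get("session", ""),
        lesion_side=meta.get("lesion_side", "none"),
    )


def _read_edf(path: Path) -> Recording:
    import warnings

    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Recording(
        data=raw.get_data(), fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group", ""), session=meta.get("session", ""),
        lesion_side=meta.get("lesion_side", "none"),
    )


def write_epochs(epochs: SourceEpochs, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, data=epochs.data)
    meta = {
        "fs": epochs.fs, "region_labels": list(epochs.region_labels),
        "band_tag": epochs.band_tag, "subject_id": epochs.subject_id,
        "group": epochs.group, "session": epochs.session,
        "lesion_side": epochs.lesion_side, "flipped": epochs.flipped,
    }
    real = path if path.suffix == ".npz" else path.with_suffix(".npz")
    _sidecar_path(real).write_text(json.dumps(meta, indent=1))
    return real


def read_epochs(path) -> SourceEpochs:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    with np.load(path) as z:
        data = z["data"]
    return SourceEpochs(
        data=data, fs=meta["fs"], region_labels=meta["region_labels"],
        band_tag=meta.get("band_tag", "broadband"),
        subject_id=meta.get("subject_id", ""), group=meta.get("group", ""),
        session=meta.get("session", ""),
        lesion_side=meta.get("lesion_side", "none"),
        flipped=meta.get("flipped", False),
    )


def write_connectivity(cm: ConnectivityMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cm.weights, index=cm.region_labels,
                      columns=cm.region_labels)
    df.to_csv(path)
    meta = {
        "band": cm.band_tag, "subject_id": cm.subject_id,
        "group": cm.group, "session": cm.session,
        "lesion_side": cm.lesion_side,
        "order": cm.meta.get("order"),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(_sidecar_path(path).read_text()) \
        if _sidecar_path(path).exists() else {}
    return ConnectivityMatrix(
        weights=df.to_numpy(float), band_tag=meta.get("band", ""),
        region_labels=list(df.columns),
        subject_id=meta.get("subject_id", ""), group=meta.get("group", ""),
        session=meta.get("session", ""),
        lesion_side=meta.get("lesion_side", "none"),
        meta={"order": meta.get("order")},
    )


def write_coupling_graph(graph: CouplingGraph, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"source": s, "target": t, "band": b, "weight": w}
            for s, t, b, w in graph.edges]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_coupling_edges(path) -> list[tuple[str, str, str, float]]:
    df = pd.read_csv(path)
    return [(r.source, r.target, r.band, float(r.weight))
            for r in df.itertuples()]
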