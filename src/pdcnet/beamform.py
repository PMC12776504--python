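"""LCMV beamforming: sensor covariance, spatial filters, virtual channels,
and SVD parcel reduction.

The beamformer is the scalar (single-orientation) linearly constrained
minimum variance filter: for source j with leadfield column l_j,

    w_j = (l_j^T C_reg^-1 l_j)^-1 l_j^T C_reg^-1,
    C_reg = C + lambda * mean(diag(C)) * I,

with the regularization fraction lambda defaulting to 0.05 (the "5%"
convention). Each filter has unit gain on its own leadfield column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import Recording, SourceEpochs, SourceTimeSeries
from .synth import LeadField

DEFAULT_REGULARIZATION = 0.05


@dataclass
class SpatialFilterSet:
    weights: np.ndarray              # sources x sensors
    source_labels: list[str]
    sensor_labels: list[str]
    regularization_fraction: float = DEFAULT_REGULARIZATION
    covariance_condition: float = np.nan
    meta: dict = field(default_factory=dict)


def sensor_covariance(data) -> np.ndarray:
    """Sample covariance over all samples (epochs pooled), channels x channels."""
    if isinstance(data, Recording):
        X = data.data
    elif isinstance(data, SourceEpochs):
        R, S, E = data.data.shape
        X = np.moveaxis(data.data, 2, 1).reshape(R, S * E)
    else:
        X = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite data")
    n_ch, n_s = X.shape
    if n_s <= n_ch:
        warnings.warn(
            f"covariance from {n_s} samples for {n_ch} channels is rank "
            "deficient or poorly conditioned", stacklevel=2,
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / max(n_s - 1, 1)
    return (C + C.T) / 2.0


def lcmv_filters(leadfield: LeadField, covariance: np.ndarray,
                 regularization_fraction: float = DEFAULT_REGULARIZATION,
                 ) -> SpatialFilterSet:
    """Compute unit-gain LCMV spatial filters for every leadfield column."""
    if regularization_fraction < 0:
        raise ValueError("regularization fraction must be >= 0")
    C = np.asarray(covariance, dtype=float)
    G = leadfield.gain
    lam = regularization_fraction * float(np.mean(np.diag(C)))
    C_reg = C + lam * np.eye(C.shape[0])
    cond = float(np.linalg.cond(C_reg))
    try:
        Cinv_G = np.linalg.solve(C_reg, G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"regularized covariance is singular (condition {cond:.3g})"
        ) from err
    # per-source normalization enforcing w_j . l_j = 1
    denom = np.einsum("ij,ij->j", G, Cinv_G)
    if np.any(np.abs(denom) < np.finfo(float).tiny):
        raise np.linalg.LinAlgError("degenerate leadfield column in LCMV")
    W = (Cinv_G / denom).T  # sources x sensors
    return SpatialFilterSet(
        weights=W,
        source_labels=list(leadfield.source_labels),
        sensor_labels=list(leadfield.sensor_labels),
        regularization_fraction=regularization_fraction,
        covariance_condition=cond,
    )


def extract_virtual_channels(filters: SpatialFilterSet,
                             recording: Recording) -> SourceTimeSeries:
    """Apply spatial filters to sensor data, yielding region time courses."""
    if recording.n_channels != filters.weights.shape[1]:
        raise ValueError("sensor count disagrees with filter weights")
    data = filters.weights @ recording.data
    return SourceTimeSeries(
        data, recording.fs, list(filters.source_labels),
        subject_id=recording.subject_id, group=recording.group,
        session=recording.session, lesion_side=recording.lesion_side,
    )


def svd_reduce(region_signals: np.ndarray) -> tuple[np.ndarray, float]:
    """Collapse a region's constituent signals to its dominant component.

    Parameters
    ----------
    region_signals : (k, n) array
        Constituent time courses of one parcel.

    Returns
    -------
    component : (n,) array
        Projection onto the first left singular vector, sign-fixed to
        correlate positively with the constituent mean.
    variance_captured : float
        Fraction of total variance captured by the component.
    """
    X = np.atleast_2d(np.asarray(region_signals, dtype=float))
    if X.shape[0] < 1 or not np.any(X):
        raise ValueError("region has no signal")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    comp = s[0] * Vt[0]
    mean_sig = X.mean(axis=0)
    if np.dot(comp, mean_sig) < 0:
        comp = -comp
    var_frac = float(s[0] ** 2 / np.sum(s**2))
    return comp, var_frac
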