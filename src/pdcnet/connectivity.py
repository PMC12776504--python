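"""Multivariate autoregressive modelling and partial directed coherence.

A single MVAR model of order p is fitted per subject by least squares,
pooling regressions across epochs without ever building lagged predictors
across an epoch boundary. Partial directed coherence is then evaluated on a
frequency grid from the coefficient Fourier transform

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs),
    pi_ij(f) = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2),

so that the squared outflows of every source column sum to one at each
frequency. Band-level connectivity is the mean of |pi_ij(f)| over the grid
frequencies inside the band, with the diagonal removed.

Entry (i, j) of every matrix here quantifies flow FROM region j TO region i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ConnectivityMatrix, SourceEpochs
from .preprocess import BandDefinition, DEFAULT_BANDS
from .synth import companion_spectral_radius

DEFAULT_FREQ_GRID = np.arange(1.0, 50.0 + 1e-9, 0.5)
DEFAULT_ORDER_CANDIDATES = tuple(range(2, 11))
# low-frequency EEG rhythms sampled at 500 Hz make the lagged design close
# to collinear; the SVD solver tolerates this up to the cap below
MAX_CONDITION = 1e10


@dataclass
class MVARModel:
    """Fitted MVAR coefficients A_1..A_p with innovation covariance."""

    order: int
    coefficients: np.ndarray        # (p, R, R); A[r][i, j]: lag r+1, j -> i
    noise_covariance: np.ndarray    # (R, R)
    fs: float
    n_samples_used: int = 0
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        p, R, R2 = self.coefficients.shape
        if R != R2 or p != self.order:
            raise ValueError("coefficient stack shape disagrees with order")
        if not self.region_labels:
            self.region_labels = [f"r{i}" for i in range(R)]
        sym_err = np.max(np.abs(self.noise_covariance - self.noise_covariance.T))
        if sym_err > 1e-8:
            raise ValueError("noise covariance not symmetric")
        if companion_spectral_radius(self.coefficients) >= 1.0:
            warnings.warn("fitted MVAR model is not stationary", stacklevel=2)

    @property
    def n_regions(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class PDCMap:
    """|pi_ij(f)| on a frequency grid; entry (i, j, f): flow j -> i."""

    values: np.ndarray              # (R, R, F) in [0, 1]
    freqs: np.ndarray               # (F,) Hz
    fs: float
    region_labels: list[str] = field(default_factory=list)


def _lagged_design(data: np.ndarray, order: int):
    """Per-epoch lagged regression blocks, never crossing epoch boundaries.

    data: regions x samples x epochs. Returns (X, Y): X is (n, R*p) with lag-1
    block first, Y is (n, R).
    """
    R, S, E = data.shape
    if S <= order:
        raise ValueError("epoch shorter than the AR order")
    Xs, Ys = [], []
    for e in range(E):
        seg = data[:, :, e]
        Y = seg[:, order:].T
        X = np.concatenate(
            [seg[:, order - r: S - r].T for r in range(1, order + 1)], axis=1
        )
        Xs.append(X)
        Ys.append(Y)
    return np.concatenate(Xs), np.concatenate(Ys)


def fit_mvar(source_epochs: SourceEpochs | np.ndarray, order: int,
             fs: float | None = None) -> MVARModel:
    """Least-squares MVAR fit pooled across epochs.

    Raises on an ill-conditioned pooled regression (condition number of the
    normal equations above 1e12).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if isinstance(source_epochs, SourceEpochs):
        data = source_epochs.data
        fs = source_epochs.fs
        labels = list(source_epochs.region_labels)
    else:
        data = np.asarray(source_epochs, dtype=float)
        if data.ndim == 2:
            data = data[:, :, None]
        labels = [f"r{i}" for i in range(data.shape[0])]
        if fs is None:
            raise ValueError("fs required for array input")
    R, S, E = data.shape
    if (S - order) * E <= order * R:
        raise ValueError("not enough samples for the requested order")
    X, Y = _lagged_design(data, order)
    B, _, _, sv = np.linalg.lstsq(X, Y, rcond=None)   # (R*p, R)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"ill-conditioned MVAR regression (condition {cond:.3g})"
        )
    resid = Y - X @ B
    n = Y.shape[0]
    sigma = resid.T @ resid / max(n - R * order, 1)
    A = np.stack([B[r * R:(r + 1) * R, :].T for r in range(order)])
    return MVARModel(order, A, (sigma + sigma.T) / 2, float(fs), n, labels)


def select_order(source_epochs: SourceEpochs | np.ndarray,
                 candidate_orders=DEFAULT_ORDER_CANDIDATES,
                 fs: float | None = None,
                 criterion: str = "bic"):
    """Pick the MVAR order minimizing an information criterion.

    All candidates are scored on the same sample set (the rows valid for the
    largest candidate) so criteria are comparable; ties break toward the
    smallest order. Returns (order, table) where table maps order -> score.
    """
    candidates = sorted(set(int(p) for p in candidate_orders))
    if not candidates:
        raise ValueError("empty candidate list")
    if isinstance(source_epochs, SourceEpochs):
        data = source_epochs.data
        fs = source_epochs.fs
    else:
        data = np.asarray(source_epochs, dtype=float)
        if data.ndim == 2:
            data = data[:, :, None]
    pmax = candidates[-1]
    R = data.shape[0]
    X, Y = _lagged_design(data, pmax)
    n = Y.shape[0]
    # one economy QR at the largest order scores every candidate: the lag-
    # major column layout means lags 1..p occupy the leading R*p columns,
    # whose span equals that of the leading QR columns
    Q, _ = np.linalg.qr(X)
    QtY = Q.T @ Y
    YtY = Y.T @ Y
    table: dict[int, float] = {}
    for p in candidates:
        k = R * p
        S = (YtY - QtY[:k].T @ QtY[:k]) / n   # residual cross-product
        S = (S + S.T) / 2
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            table[p] = np.inf
            continue
        n_params = k * R
        if criterion == "bic":
            table[p] = float(n * logdet + n_params * np.log(n))
        elif criterion == "aic":
            table[p] = float(n * logdet + 2 * n_params)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    if all(np.isinf(v) for v in table.values()):
        raise RuntimeError("all candidate orders failed to fit")
    best = min(table, key=lambda p: (table[p], p))
    return best, table


def pdc_spectrum(model: MVARModel, freqs=DEFAULT_FREQ_GRID) -> PDCMap:
    """Evaluate magnitude PDC on a frequency grid."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    p, R, _ = model.coefficients.shape
    lags = np.arange(1, p + 1)
    # phase[f, r] = exp(-i 2 pi f r / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / model.fs)
    Abar = np.eye(R)[None, :, :] - np.tensordot(phase, model.coefficients,
                                                axes=([1], [0]))
    mag = np.abs(Abar)                              # (F, R, R)
    col_norm = np.sqrt(np.sum(mag**2, axis=1))      # (F, R)
    values = mag / col_norm[:, None, :]
    return PDCMap(np.moveaxis(values, 0, 2), freqs, model.fs,
                  list(model.region_labels))


def band_average(pdc_map: PDCMap, band: BandDefinition) -> ConnectivityMatrix:
    """Mean |pi_ij(f)| over grid frequencies in [low, high); diagonal zeroed."""
    mask = (pdc_map.freqs >= band.low_hz) & (pdc_map.freqs < band.high_hz)
    if not np.any(mask):
        raise ValueError(
            f"band {band.name!r} has no grid points in "
            f"[{band.low_hz}, {band.high_hz})"
        )
    W = pdc_map.values[:, :, mask].mean(axis=2)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(W, band.name, list(pdc_map.region_labels))


def subject_connectivity(
    source_epochs: SourceEpochs,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    order="auto",
    order_candidates=DEFAULT_ORDER_CANDIDATES,
    freqs=DEFAULT_FREQ_GRID,
    squared: bool = False,
) -> dict[str, ConnectivityMatrix]:
    """Full per-subject connectivity: one pooled MVAR fit on the broadband
    epochs, PDC spectrum on the grid, then one band-averaged matrix per band.

    ``order="auto"`` selects the order by BIC over ``order_candidates``.
    """
    if order == "auto":
        chosen, table = select_order(source_epochs, order_candidates)
    else:
        chosen, table = int(order), {int(order): np.nan}
    model = fit_mvar(source_epochs, chosen)
    pdc = pdc_spectrum(model, freqs)
    if squared:
        pdc = PDCMap(pdc.values**2, pdc.freqs, pdc.fs, pdc.region_labels)
    out = {}
    for band in bands:
        cm = band_average(pdc, band)
        cm.subject_id = source_epochs.subject_id
        cm.group = source_epochs.group
        cm.session = source_epochs.session
        cm.lesion_side = source_epochs.lesion_side
        cm.meta = {"order": chosen, "criterion_table": table,
                   "squared": squared}
        out[band.name] = cm
    return out
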