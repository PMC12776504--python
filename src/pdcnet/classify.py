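"""Band-wise cohort classification from flattened connectivity features.

The classifier is an RBF-kernel SVM evaluated under leave-one-subject-out
cross-validation. Inside every outer fold — and only there — features are
z-score normalized, ranked by a ReliefF filter, and the SVM hyperparameters
(C, kernel scale, number of retained features) are chosen by an inner
5-fold grid search; the held-out subject never influences normalization,
ranking or model selection. "Kernel scale" follows the divisor convention
(gamma = 1 / scale^2); the "auto" entry uses gamma = 1 / (n_features * var).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_C_GRID = (0.1, 1.0, 10.0)
DEFAULT_SCALE_GRID = (0.01, 0.1, 1.0, "auto")
DEFAULT_K_GRID = (20, 50, 100)


@dataclass
class FeatureTable:
    """Subject-session samples x off-diagonal directed-edge features."""

    X: np.ndarray                       # (n_samples, n_features)
    labels: np.ndarray                  # (n_samples,) in {0, 1}
    subject_ids: list[str]
    feature_map: list[tuple[int, int]]  # column -> (target i, source j)
    band_tag: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any(~np.isfinite(self.X)):
            raise ValueError("features contain missing values")
        if self.X.shape[0] != self.labels.size or \
                self.X.shape[0] != len(self.subject_ids):
            raise ValueError("row/label/subject count mismatch")
        if self.X.shape[1] != len(self.feature_map):
            raise ValueError("feature map length mismatch")


@dataclass
class ClassifierConfig:
    c_grid: tuple = DEFAULT_C_GRID
    scale_grid: tuple = DEFAULT_SCALE_GRID
    k_grid: tuple = DEFAULT_K_GRID
    inner_folds: int = 5
    relief_k_neighbors: int = 3
    seed: int = 0
    subject_wise: bool = True

    def __post_init__(self):
        if not self.c_grid or not self.scale_grid or not self.k_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.inner_folds < 2:
            raise ValueError("inner folds must be >= 2")


@dataclass
class ClassificationMetrics:
    accuracy: float                     # all metrics on the 0-100 scale
    sensitivity: float
    specificity: float
    auc: float
    predictions: list[dict] = field(default_factory=list)
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tn, fp, fn, tp


def vectorize(matrices, labels, subject_ids, band_tag: str = "",
              ) -> FeatureTable:
    """Flatten connectivity matrices into off-diagonal feature vectors.

    Row-major over (i, j), i != j; the column map records (target, source)
    per feature so vectors can be unflattened.
    """
    mats = [np.asarray(getattr(m, "weights", m), dtype=float)
            for m in matrices]
    R = mats[0].shape[0]
    for m in mats:
        if m.shape != (R, R):
            raise ValueError("inconsistent matrix sizes")
    fmap = [(i, j) for i in range(R) for j in range(R) if i != j]
    X = np.array([[m[i, j] for i, j in fmap] for m in mats])
    return FeatureTable(X, np.asarray(labels, int), list(subject_ids),
                        fmap, band_tag)


def unflatten(vector, feature_map) -> np.ndarray:
    R = int(np.max(feature_map)) + 1
    M = np.zeros((R, R))
    for val, (i, j) in zip(np.asarray(vector, float), feature_map):
        M[i, j] = val
    return M


def zscore_train_apply(train: np.ndarray, test: np.ndarray):
    """Standardize test columns with TRAIN statistics only.

    Zero-variance training columns are centred but not divided.
    """
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (train - mu) / safe, (np.asarray(test, float) - mu) / safe


def relief_rank(features: np.ndarray, labels: np.ndarray,
                k_neighbors: int = 3):
    """ReliefF feature weights for binary labels.

    For every sample, accumulate range-normalized feature differences to its
    k nearest same-class hits (penalty) and k nearest other-class misses
    (reward): W[f] += sum(|diff to miss| - |diff to hit|) / (m * k).
    Deterministic: all samples are used, ties break by sample then feature
    index. Returns (weights, ranking) with ranking sorted by decreasing
    weight (feature index breaks ties).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("ReliefF here requires exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 samples per class")
    m, n_feat = X.shape
    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0
    Xn = X / span  # range normalization of the per-feature diffs
    # pairwise distances (Euclidean) on normalized features
    d2 = np.sum((Xn[:, None, :] - Xn[None, :, :]) ** 2, axis=2)
    W = np.zeros(n_feat)
    for a in range(m):
        for c in classes:
            same = c == y[a]
            idx = np.flatnonzero((y == c) & (np.arange(m) != a))
            k = min(k_neighbors, idx.size)
            order = idx[np.lexsort((idx, d2[a, idx]))][:k]
            diffs = np.abs(Xn[order] - Xn[a]).sum(axis=0) / k
            W += -diffs if same else diffs
    W /= m
    ranking = np.lexsort((np.arange(n_feat), -W))
    return W, ranking


def _gamma_from_scale(scale, X: np.ndarray) -> float:
    if scale == "auto":
        var = float(X.var())
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return 1.0 / float(scale) ** 2


def _fit_svm(X, y, C, scale, seed) -> SVC:
    clf = SVC(C=C, kernel="rbf", gamma=_gamma_from_scale(scale, X),
              random_state=seed)
    clf.fit(X, y)
    return clf


def _grid_search(Xtr, ytr, ranking, config: ClassifierConfig):
    """Inner 5-fold grid search over (C, kernel scale, k features)."""
    n = ytr.size
    folds = min(config.inner_folds, int(np.min(np.bincount(ytr))))
    if folds < 2:
        raise ValueError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=config.seed)
    splits = list(skf.split(Xtr, ytr))
    best = None
    for k in config.k_grid:
        cols = ranking[: min(k, Xtr.shape[1])]
        for C in config.c_grid:
            for scale in config.scale_grid:
                hits = 0
                for tr, va in splits:
                    Xi, Xv = zscore_train_apply(Xtr[np.ix_(tr, cols)],
                                                Xtr[np.ix_(va, cols)])
                    clf = _fit_svm(Xi, ytr[tr], C, scale, config.seed)
                    hits += int((clf.predict(Xv) == ytr[va]).sum())
                acc = hits / n
                key = (acc, -len(cols))  # prefer fewer features on ties
                if best is None or key > best[0]:
                    best = (key, {"C": C, "scale": scale, "k": int(k)})
    return best[1]


def loocv_evaluate(features: FeatureTable,
                   config: ClassifierConfig | None = None,
                   ) -> ClassificationMetrics:
    """Leave-one-subject-out evaluation with nested model selection.

    Both sessions of a held-out subject leave together (subject-wise CV);
    set ``config.subject_wise=False`` to hold out single samples instead.
    Metrics are pooled over the outer folds; AUC is computed from the
    decision values of the positive class.
    """
    config = config or ClassifierConfig()
    X, y = features.X, features.labels
    sids = np.asarray(features.subject_ids)
    if min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 samples per class")
    groups = (list(dict.fromkeys(sids)) if config.subject_wise
              else list(range(len(sids))))

    preds, truths, scores, log = [], [], [], []
    for g in groups:
        held = (sids == g) if config.subject_wise else \
            (np.arange(len(sids)) == g)
        tr = ~held
        ytr = y[tr]
        if np.unique(ytr).size < 2:
            raise ValueError(f"a class is absent from the training fold "
                             f"holding out {g!r}")
        # all fold-local: normalization, ranking, model selection
        Xtr_n, _ = zscore_train_apply(X[tr], X[tr])
        _, ranking = relief_rank(Xtr_n, ytr, config.relief_k_neighbors)
        params = _grid_search(X[tr], ytr, ranking, config)
        cols = ranking[: params["k"]]
        Xi, Xo = zscore_train_apply(X[np.ix_(tr, cols)],
                                    X[np.ix_(held, cols)])
        clf = _fit_svm(Xi, ytr, params["C"], params["scale"], config.seed)
        yhat = clf.predict(Xo)
        dval = clf.decision_function(Xo)
        if clf.classes_[1] == 0:  # orient decision values toward class 1
            dval = -dval
        preds.extend(yhat.tolist())
        truths.extend(y[held].tolist())
        scores.extend(np.atleast_1d(dval).tolist())
        log.append({"held_out": g, "params": params,
                    "true": y[held].tolist(), "pred": yhat.tolist()})

    truths = np.asarray(truths)
    preds = np.asarray(preds)
    tp = int(np.sum((preds == 1) & (truths == 1)))
    tn = int(np.sum((preds == 0) & (truths == 0)))
    fp = int(np.sum((preds == 1) & (truths == 0)))
    fn = int(np.sum((preds == 0) & (truths == 1)))
    acc = 100.0 * (tp + tn) / truths.size
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    auc = 100.0 * roc_auc_score(truths, scores)
    return ClassificationMetrics(acc, sens, spec, auc, log,
                                 (tn, fp, fn, tp))
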