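"""Population decoding of grating phase from firing-rate vectors.

The decoder treats each (repetition, phase) firing-rate vector as one sample
of a binary classification problem: which grating phase was shown?  Features
are standardized (z = (x - mu) / sigma with mu, sigma estimated on the
training rows only), classified with a support-vector machine using a radial
basis function kernel and C = 1, and evaluated with stratified k-fold
cross-validation (default 10 folds, shuffled at a fixed seed).  Performance
is summarised by the f1 score,

    f1 = 2 P R / (P + R) = TP / (TP + (FP + FN) / 2),

with phase 1 as the positive class; chance level for balanced phases is 0.5.

"Feature importance" for an rbf-kernel machine has no primal coefficients, so
it is operationalised as permutation importance: the drop in f1 when a single
unit's column is shuffled, averaged over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .stimulus import ConfigurationError

POSITIVE_LABEL = 1  # phase 1


@dataclass(frozen=True)
class DecoderConfig:
    n_folds: int = 10
    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    seed: int = 0
    holdout_fraction: float | None = None  # None => k-fold CV over all data
    importance_repeats: int = 10


@dataclass
class DecodingDataset:
    X: np.ndarray  # samples x units, Hz
    y: np.ndarray  # 1 for phase1 rows, 0 for phase2 rows
    unit_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ConfigurationError("X rows and y labels misaligned")
        if not self.unit_ids:
            self.unit_ids = tuple(range(self.X.shape[1]))


@dataclass
class ScalerParams:
    mean: np.ndarray
    std: np.ndarray  # population SD; zero-variance features flagged
    zero_variance: np.ndarray


@dataclass
class DecodingResult:
    f1_per_fold: tuple[float, ...]
    f1_mean: float
    f1_sd: float
    confusion: dict  # TP/FP/FN/TN pooled over test folds
    importance: np.ndarray | None
    unit_ids: tuple[int, ...]
    config: DecoderConfig

    @property
    def importance_rank(self) -> np.ndarray:
        """Unit indices sorted from most to least important."""
        if self.importance is None:
            raise ValueError("importance was not computed")
        return np.argsort(-self.importance, kind="stable")


def standardize(
    X_train: np.ndarray, X_apply: np.ndarray | None = None
) -> tuple[ScalerParams, np.ndarray]:
    """Column-wise standard score using training-set statistics only.

    Zero-variance columns map to 0 rather than dividing by zero.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ConfigurationError("empty training matrix")
    mu = X_train.mean(axis=0)
    sigma = X_train.std(axis=0)  # population convention (ddof=0)
    zero = sigma == 0
    safe = np.where(zero, 1.0, sigma)
    target = X_train if X_apply is None else np.asarray(X_apply, dtype=float)
    Z = (target - mu) / safe
    Z[:, zero] = 0.0
    return ScalerParams(mean=mu, std=sigma, zero_variance=zero), Z


def f1_from_confusion(tp: float, fp: float, fn: float) -> float:
    """f1 from confusion counts; both algebraic forms agree by construction."""
    if tp + fp + fn == 0:
        return 0.0
    direct = tp / (tp + 0.5 * (fp + fn))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    harmonic = (
        2.0 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    assert abs(direct - harmonic) < 1e-12
    return direct


def _confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    return {
        "TP": int(np.sum(pos & pred_pos)),
        "FP": int(np.sum(~pos & pred_pos)),
        "FN": int(np.sum(pos & ~pred_pos)),
        "TN": int(np.sum(~pos & ~pred_pos)),
    }


def _fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: DecoderConfig,
) -> np.ndarray:
    _, Z_train = standardize(X_train)
    _, Z_test = standardize(X_train, X_test)
    clf = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
    clf.fit(Z_train, y_train)
    return clf.predict(Z_test)


def cross_validated_decode(
    ds: DecodingDataset, config: DecoderConfig | None = None
) -> DecodingResult:
    """Stratified k-fold (or single held-out split) decoding of the phase.

    Scaling is re-fit on each training fold to avoid leakage into the test
    fold.  Deterministic for a fixed seed and config.
    """
    config = config or DecoderConfig()
    classes, counts = np.unique(ds.y, return_counts=True)
    if classes.size < 2:
        raise ConfigurationError("both phases must be present for decoding")

    if config.holdout_fraction is not None:
        X_tr, X_te, y_tr, y_te = train_test_split(
            ds.X,
            ds.y,
            test_size=config.holdout_fraction,
            stratify=ds.y,
            random_state=config.seed,
        )
        folds = [(X_tr, y_tr, X_te, y_te)]
    else:
        n_folds = config.n_folds
        if n_folds > counts.min():
            import warnings

            warnings.warn(
                f"reducing folds from {n_folds} to {counts.min()} "
                "(smallest class count)"
            )
            n_folds = int(counts.min())
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
        folds = [
            (ds.X[tr], ds.y[tr], ds.X[te], ds.y[te])
            for tr, te in skf.split(ds.X, ds.y)
        ]

    f1s = []
    pooled = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for X_tr, y_tr, X_te, y_te in folds:
        y_pred = _fit_predict(X_tr, y_tr, X_te, config)
        cm = _confusion_counts(y_te, y_pred)
        for k in pooled:
            pooled[k] += cm[k]
        f1s.append(f1_from_confusion(cm["TP"], cm["FP"], cm["FN"]))

    f1s_arr = np.array(f1s)
    return DecodingResult(
        f1_per_fold=tuple(f1s),
        f1_mean=float(f1s_arr.mean()),
        f1_sd=float(f1s_arr.std()),
        confusion=pooled,
        importance=None,
        unit_ids=ds.unit_ids,
        config=config,
    )


def feature_importance(
    ds: DecodingDataset, config: DecoderConfig | None = None
) -> np.ndarray:
    """Permutation importance of each unit: mean drop in held-out f1 when its
    column is shuffled.

    Drops are averaged over ``config.importance_repeats`` shuffles and over
    the same stratified folds used for decoding, which keeps the estimate
    usable even when a single test split is too small to resolve per-unit
    contributions.  Note that when the decoder sits at ceiling (f1 = 1 with
    heavy redundancy across units) permuting any one unit may not move f1 at
    all; importances are informative in the regime where the decoder is below
    ceiling.
    """
    config = config or DecoderConfig()
    if ds.X.shape[1] < 2:
        raise ConfigurationError("need at least 2 units for importances")
    rng = np.random.default_rng(config.seed)
    if config.holdout_fraction is not None:
        X_tr, X_te, y_tr, y_te = train_test_split(
            ds.X,
            ds.y,
            test_size=config.holdout_fraction,
            stratify=ds.y,
            random_state=config.seed,
        )
        folds = [(X_tr, y_tr, X_te, y_te)]
    else:
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        folds = [
            (ds.X[tr], ds.y[tr], ds.X[te], ds.y[te])
            for tr, te in skf.split(ds.X, ds.y)
        ]

    importance = np.zeros(ds.X.shape[1])
    for X_tr, y_tr, X_te, y_te in folds:
        _, Z_tr = standardize(X_tr)
        _, Z_te = standardize(X_tr, X_te)
        clf = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
        clf.fit(Z_tr, y_tr)

        def f1_of(Z):
            cm = _confusion_counts(y_te, clf.predict(Z))
            return f1_from_confusion(cm["TP"], cm["FP"], cm["FN"])

        baseline = f1_of(Z_te)
        for j in range(ds.X.shape[1]):
            drops = []
            for _ in range(config.importance_repeats):
                Zp = Z_te.copy()
                Zp[:, j] = rng.permutation(Zp[:, j])
                drops.append(baseline - f1_of(Zp))
            importance[j] += float(np.mean(drops))
    return importance / len(folds)


def fraction_contributing_units(
    importance: np.ndarray, threshold_fraction: float = 0.05
) -> dict:
    """Fraction of units whose importance exceeds ``threshold_fraction`` of
    the top importance (contributing cells)."""
    importance = np.asarray(importance, dtype=float)
    top = importance.max(initial=0.0)
    if top <= 0:
        return {"fraction": 0.0, "threshold": 0.0, "n_contributing": 0}
    thr = threshold_fraction * top
    n = int(np.sum(importance > thr))
    return {
        "fraction": n / importance.size,
        "threshold": float(thr),
        "n_contributing": n,
    }
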