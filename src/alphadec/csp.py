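"""CSP decoding of high- vs low-arousal epochs.

Common spatial patterns (CSP) solves the generalized eigenproblem of
(C_high, C_high + C_low) over the class-mean covariances of the 1-s epochs,
so eigenvalues lie in (0, 1) and swapping the class labels maps an
eigenvalue lambda to 1 - lambda.  Features are the log-variance of the four
most discriminative components (two from each end of the eigenvalue
spectrum), classified with an analytic-shrinkage LDA.

Two cross-validation schemes are provided:

* randomized stratified 10-fold CV scored by accuracy (1 - misclassification
  rate), the headline metric;
* "sub-blocked" chronological 10-fold CV: the epoch sequence is split into
  three contiguous sub-blocks, each fold's test set concatenates the f-th
  consecutive chunk from every sub-block.  This preserves temporal
  neighbourhood structure (limiting autocorrelation leakage) while keeping
  both classes present in most test sets.  Training folds are balanced with
  SMOTE; the (unbalanced) test fold is scored by ROC-AUC.

A block-permutation test (contiguous label blocks shuffled, internal order
preserved) provides autocorrelation-respecting nulls for either metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import eigh
from sklearn.covariance import ledoit_wolf
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .spoc import EpochCovariances, epoch_covariances

logger = logging.getLogger(__name__)

__all__ = [
    "CSPResult",
    "ShrinkageLDA",
    "csp_decompose",
    "csp_features",
    "smote_oversample",
    "randomized_cv",
    "subblocked_cv",
    "block_permutation_test",
]

_LOG_FLOOR = 1e-20


@dataclass
class CSPResult:
    """Decoding outcome shared by the accuracy and ROC-AUC branches."""

    filters_W: NDArray[np.float64]
    patterns_A: NDArray[np.float64]
    eigenvalues: NDArray[np.float64]
    feature_components: NDArray[np.int_]
    per_fold_metric: NDArray[np.float64]
    mean_metric: float
    metric_name: str = "accuracy"
    #: per-epoch predictions over the retained epochs (chronological order;
    #: +1 high, -1 low), pooled over the CV test folds
    predictions: NDArray[np.int_] = field(default_factory=lambda: np.array([], dtype=int))
    scores: NDArray[np.float64] = field(default_factory=lambda: np.array([]))
    null_distribution: NDArray[np.float64] = field(default_factory=lambda: np.array([]))
    p_value: float = np.nan

    @property
    def mean_accuracy(self) -> float:
        if self.metric_name != "accuracy":
            raise AttributeError("this result was scored by " + self.metric_name)
        return self.mean_metric

    @property
    def roc_auc(self) -> float:
        if self.metric_name != "roc_auc":
            raise AttributeError("this result was scored by " + self.metric_name)
        return self.mean_metric


def _as_covs(data: NDArray[np.float64] | EpochCovariances) -> NDArray[np.float64]:
    """Per-epoch covariance stack from a tensor or precomputed covariances.

    All CSP quantities (class-mean covariances, filters, log-variance
    features) are functions of the per-epoch covariances alone, so the
    cross-validation and permutation loops work on this stack and the
    expensive epochs x samples reduction happens once per call.
    """
    if isinstance(data, EpochCovariances):
        return data.covs
    return epoch_covariances(np.asarray(data, dtype=float)).covs


def csp_decompose(
    data: NDArray[np.float64] | EpochCovariances, labels: NDArray[np.int_]
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """CSP filters, patterns and eigenvalues for a binary label vector.

    ``data`` is epochs x samples x components (signal-band filtered, SSD
    space) or the matching :class:`EpochCovariances`; ``labels`` uses +1
    (high) / -1 (low).  Class-mean covariance = mean of per-epoch
    covariances.  Returns (filters_W, patterns_A, eigenvalues) with
    eigenvalues descending in (0, 1): components at the top capture
    variance specific to the high class, components at the bottom the low
    class.
    """
    covs = _as_covs(data)
    labels = np.asarray(labels).ravel()
    if covs.shape[0] != labels.size:
        raise ValueError("labels must match number of epochs")
    hi = labels == 1
    lo = labels == -1
    if not hi.any() or not lo.any():
        raise ValueError("both classes must be present")
    C_hi = covs[hi].mean(axis=0)
    C_lo = covs[lo].mean(axis=0)

    evals, evecs = eigh(C_hi, C_hi + C_lo)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    patterns = np.linalg.pinv(evecs).T
    return evecs, patterns, evals


def csp_features(
    tensor: NDArray[np.float64],
    filters: NDArray[np.float64],
    component_indices: NDArray[np.int_] | None = None,
) -> NDArray[np.float64]:
    """Log-variance features of the selected CSP components, per epoch.

    By default the four most discriminative components are used: two from
    each end of the eigenvalue spectrum.
    """
    k = filters.shape[1]
    if component_indices is None:
        if k < 4:
            raise ValueError("need at least 4 components for the default feature set")
        component_indices = np.array([0, 1, k - 2, k - 1])
    component_indices = np.asarray(component_indices, dtype=int)
    proj = np.einsum("etk,kc->etc", tensor, filters[:, component_indices])
    var = proj.var(axis=1)  # population variance: unit-variance epoch -> feature 0
    if np.any(var <= _LOG_FLOOR):
        logger.warning("zero-variance projected epoch; applying epsilon floor")
    return np.log(np.maximum(var, _LOG_FLOOR))


def _covs_features(
    covs: NDArray[np.float64],
    filters: NDArray[np.float64],
    component_indices: NDArray[np.int_],
) -> NDArray[np.float64]:
    # log(w' C(e) w); differs from csp_features only by the constant
    # log(n/(n-1)) from the ddof convention, which LDA is invariant to
    Wc = filters[:, component_indices]
    var = np.einsum("ekl,kc,lc->ec", covs, Wc, Wc)
    return np.log(np.maximum(var, _LOG_FLOOR))


class ShrinkageLDA:
    """Binary LDA with analytic (Ledoit-Wolf) covariance shrinkage.

    The pooled within-class covariance is estimated on class-centred
    training data with the closed-form optimal shrinkage intensity; the
    decision rule is the usual linear discriminant.  Signed decision
    scores (positive toward the +1 class) support ROC analysis.
    """

    def __init__(self) -> None:
        self.coef_: NDArray[np.float64] | None = None
        self.intercept_: float = 0.0
        self.shrinkage_: float = np.nan

    def fit(self, X: NDArray[np.float64], y: NDArray[np.int_]) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("ShrinkageLDA is strictly binary")
        neg, pos = classes.min(), classes.max()
        mu_n = X[y == neg].mean(axis=0)
        mu_p = X[y == pos].mean(axis=0)
        centred = X.copy()
        centred[y == neg] -= mu_n
        centred[y == pos] -= mu_p
        cov, self.shrinkage_ = ledoit_wolf(centred, assume_centered=True)
        try:
            w = np.linalg.solve(cov, mu_p - mu_n)
        except np.linalg.LinAlgError as err:  # pragma: no cover - shrinkage prevents this
            raise np.linalg.LinAlgError("covariance singular even after shrinkage") from err
        self.coef_ = w
        self.intercept_ = -float(w @ (mu_p + mu_n) / 2.0)
        self._classes = (int(neg), int(pos))
        return self

    def decision_function(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        if self.coef_ is None:
            raise RuntimeError("classifier not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: NDArray[np.float64]) -> NDArray[np.int_]:
        neg, pos = self._classes
        return np.where(self.decision_function(X) >= 0, pos, neg)


def smote_oversample(
    features: NDArray[np.float64],
    labels: NDArray[np.int_],
    seed: int | np.random.Generator = 0,
    k_neighbors: int = 5,
) -> tuple[NDArray[np.float64], NDArray[np.int_]]:
    """Balance a binary training set by synthetic minority oversampling.

    Each synthetic point is a convex combination of a minority sample and
    one of its k nearest minority neighbours.  Already balanced input is
    returned unchanged; a single minority sample is duplicated (logged).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).ravel()
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE here is strictly binary")
    if counts[0] == counts[1]:
        return features, labels
    minority = classes[np.argmin(counts)]
    n_extra = int(abs(counts[0] - counts[1]))
    Xm = features[labels == minority]
    rng = np.random.default_rng(seed)
    if Xm.shape[0] == 1:
        logger.warning("single minority sample: falling back to duplication")
        synth = np.repeat(Xm, n_extra, axis=0)
    else:
        k = min(k_neighbors, Xm.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        base = rng.integers(Xm.shape[0], size=n_extra)
        pick = idx[base, rng.integers(1, k + 1, size=n_extra)]
        gap = rng.uniform(0.0, 1.0, size=(n_extra, 1))
        synth = Xm[base] + gap * (Xm[pick] - Xm[base])
    X_out = np.vstack([features, synth])
    y_out = np.concatenate([labels, np.full(n_extra, minority, dtype=labels.dtype)])
    return X_out, y_out


def _fit_fold(
    covs: NDArray[np.float64],
    labels: NDArray[np.int_],
    train: NDArray[np.int_],
    test: NDArray[np.int_],
    smote_rng: np.random.Generator | None = None,
):
    W, _, _ = csp_decompose(EpochCovariances(covs=covs[train]), labels[train])
    k = W.shape[1]
    comp = np.array([0, 1, k - 2, k - 1]) if k >= 4 else np.arange(k)
    F_train = _covs_features(covs[train], W, comp)
    F_test = _covs_features(covs[test], W, comp)
    y_train = labels[train]
    if smote_rng is not None:
        F_train, y_train = smote_oversample(F_train, y_train, smote_rng)
    clf = ShrinkageLDA().fit(F_train, y_train)
    return clf.predict(F_test), clf.decision_function(F_test)


def _stratified_folds(
    labels: NDArray[np.int_], k: int, rng: np.random.Generator
) -> list[NDArray[np.int_]]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for f, part in enumerate(np.array_split(idx, k)):
            folds[f].extend(part.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def randomized_cv(
    data: NDArray[np.float64] | EpochCovariances,
    labels: NDArray[np.int_],
    k: int = 10,
    seed: int | np.random.Generator = 0,
) -> CSPResult:
    """Randomized, class-stratified k-fold CV scored by accuracy.

    CSP and LDA are fitted on each training split only; the mean over folds
    of 1 - misclassification rate is the outcome.  Pooled per-epoch
    predictions (chronological order) are retained for exact binomial
    tests.
    """
    covs = _as_covs(data)
    labels = np.asarray(labels).ravel()
    n = labels.size
    if k > n:
        raise ValueError("more folds than epochs")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    acc = np.empty(k)
    predictions = np.zeros(n, dtype=int)
    scores = np.zeros(n)
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        pred, sc = _fit_fold(covs, labels, train, test)
        acc[f] = np.mean(pred == labels[test])
        predictions[test] = pred
        scores[test] = sc
    W, A, evals = csp_decompose(EpochCovariances(covs=covs), labels)
    kk = W.shape[1]
    return CSPResult(
        filters_W=W,
        patterns_A=A,
        eigenvalues=evals,
        feature_components=np.array([0, 1, kk - 2, kk - 1]) if kk >= 4 else np.arange(kk),
        per_fold_metric=acc,
        mean_metric=float(acc.mean()),
        metric_name="accuracy",
        predictions=predictions,
        scores=scores,
    )


def subblocked_folds(n: int, k: int = 10, n_subblocks: int = 3) -> list[NDArray[np.int_]]:
    """Chronological fold indices stratified over contiguous sub-blocks.

    The n epochs are divided into ``n_subblocks`` contiguous sub-blocks;
    fold f's test set concatenates the f-th consecutive chunk (length
    n // (k * n_subblocks)) from each sub-block.  Remainder epochs are
    appended to the final chunk of each sub-block, preserving the partition
    property.
    """
    if n < k * n_subblocks:
        raise ValueError("fewer epochs than folds * sub-blocks")
    block_bounds = np.linspace(0, n, n_subblocks + 1).astype(int)
    folds: list[list[int]] = [[] for _ in range(k)]
    for b in range(n_subblocks):
        start, stop = block_bounds[b], block_bounds[b + 1]
        chunk = (stop - start) // k
        for f in range(k):
            lo = start + f * chunk
            hi = stop if f == k - 1 else start + (f + 1) * chunk
            folds[f].extend(range(lo, hi))
    return [np.asarray(f, dtype=int) for f in folds]


def subblocked_cv(
    data: NDArray[np.float64] | EpochCovariances,
    labels: NDArray[np.int_],
    n_subblocks: int = 3,
    k: int = 10,
    seed: int | np.random.Generator = 0,
) -> CSPResult:
    """Sub-blocked chronological k-fold CV scored by ROC-AUC.

    Training folds are SMOTE-balanced; test folds are left unbalanced and
    scored by ROC-AUC of the signed LDA decision values with the high
    class positive.  Folds whose test set contains a single class cannot be
    scored and contribute NaN (excluded from the mean, logged).
    """
    covs = _as_covs(data)
    labels = np.asarray(labels).ravel()
    n = labels.size
    rng = np.random.default_rng(seed)
    folds = subblocked_folds(n, k, n_subblocks)
    aucs = np.full(k, np.nan)
    predictions = np.zeros(n, dtype=int)
    scores = np.zeros(n)
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        pred, sc = _fit_fold(covs, labels, train, test, smote_rng=rng)
        predictions[test] = pred
        scores[test] = sc
        y_test = labels[test]
        if np.unique(y_test).size < 2:
            logger.warning("fold %d test set is single-class; AUC undefined", f)
            continue
        aucs[f] = roc_auc_score(y_test == 1, sc)
    W, A, evals = csp_decompose(EpochCovariances(covs=covs), labels)
    kk = W.shape[1]
    return CSPResult(
        filters_W=W,
        patterns_A=A,
        eigenvalues=evals,
        feature_components=np.array([0, 1, kk - 2, kk - 1]) if kk >= 4 else np.arange(kk),
        per_fold_metric=aucs,
        mean_metric=float(np.nanmean(aucs)),
        metric_name="roc_auc",
        predictions=predictions,
        scores=scores,
    )


def permute_blocks(
    labels: NDArray[np.int_], n_blocks: int, rng: np.random.Generator
) -> NDArray[np.int_]:
    """Shuffle contiguous label blocks, keeping each block's internal order."""
    labels = np.asarray(labels)
    n = labels.size
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    blocks = [labels[bounds[i] : bounds[i + 1]] for i in range(n_blocks)]
    order = rng.permutation(n_blocks)
    return np.concatenate([blocks[i] for i in order])


def block_permutation_test(
    data: NDArray[np.float64] | EpochCovariances,
    labels: NDArray[np.int_],
    metric_fn: Callable[..., float],
    n_blocks: int = 10,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, NDArray[np.float64]]:
    """Block-permutation null for a decoding metric.

    ``labels`` must be in chronological order.  Each permutation shuffles
    the ``n_blocks`` contiguous label blocks (internal structure intact)
    and recomputes ``metric_fn(data, permuted_labels)``.  ``data`` may be
    the epoch tensor or precomputed :class:`EpochCovariances` (covariances
    are label-independent, so permutations can share them).  Returns
    (observed metric, upper-tail p-value with +1 correction, null draws).
    """
    labels = np.asarray(labels).ravel()
    if n_blocks > labels.size:
        raise ValueError("more blocks than epochs")
    if not isinstance(data, EpochCovariances):
        data = EpochCovariances(covs=_as_covs(data))
    rng = np.random.default_rng(seed)
    observed = float(metric_fn(data, labels))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = metric_fn(data, permute_blocks(labels, n_blocks, rng))
    p = (np.sum(null >= observed) + 1.0) / (n_perm + 1.0)
    return observed, float(p), null
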