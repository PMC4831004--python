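"""Gender decoding from error-weight scalp maps.

Linear SVM (C = 1) on subject x electrode feature maps: exact class
balancing by seeded subsampling, a single global min-max scaling to [-1, 1],
Monte-Carlo cross-validation with stratified random 90/10 splits, label
permutation for inference, and a three-variant electrode searchlight
(singleton, contralateral pair, self + 7 nearest neighbours).
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from .containers import DecodingResult
from .cohort import as_rng
from .montage import Montage


class ScalingError(ValueError):
    pass


def balance_and_scale(features, labels, seed=None):
    """Subsample the larger class to the smaller and scale to [-1, 1].

    Scaling is a single affine map over ALL entries (channels and subjects
    jointly), so relative amplitudes between electrodes are preserved.
    Returns (features, labels(0/1 int), n_per_class).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "male").astype(int)
    else:
        y = y.astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be non-empty")
    rng = as_rng(seed)
    n = min(n0, n1)
    keep = np.concatenate([
        rng.choice(np.flatnonzero(y == 0), n, replace=False),
        rng.choice(np.flatnonzero(y == 1), n, replace=False)])
    keep.sort()
    X, y = X[keep], y[keep]
    lo, hi = X.min(), X.max()
    if hi == lo:
        raise ScalingError("constant feature matrix: zero scaling range")
    X = 2.0 * (X - lo) / (hi - lo) - 1.0
    return X, y, n


def _stratified_split(y, test_fraction, rng):
    test = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(test_fraction * idx.size)))
        test.append(rng.choice(idx, k, replace=False))
    test = np.concatenate(test)
    mask = np.zeros(y.size, dtype=bool)
    mask[test] = True
    return ~mask, mask


def mc_crossval_svm(features, labels, n_splits: int = 500,
                    test_fraction: float = 0.1, seed=None,
                    C: float = 1.0) -> DecodingResult:
    """Monte-Carlo cross-validated linear SVM accuracy.

    Repeated stratified random splits (90% train / 10% test by default);
    accuracy is the mean test accuracy over splits.  Splits whose test set
    would contain a single class are resampled (cannot happen with the
    stratified sampler, kept as a guard).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    rng = as_rng(seed)
    accs = np.empty(n_splits)
    for i in range(n_splits):
        for _ in range(100):
            tr, te = _stratified_split(y, test_fraction, rng)
            if len(np.unique(y[te])) == 2:
                break
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[tr], y[tr])
        accs[i] = float(np.mean(clf.predict(X[te]) == y[te]))
    return DecodingResult(accuracy=float(accs.mean()), fold_accuracies=accs,
                          n_per_class=int(np.bincount(y).min()))


def permutation_p_from_counts(count: int, n_perm: int) -> float:
    """max(count, 1)/n_perm convention: a never-exceeded observation with
    15000 permutations gives p = 1/15000 = 6.67e-5."""
    return max(int(count), 1) / n_perm


def permutation_pvalue(features, labels, observed_accuracy: float,
                       n_perm: int = 15000, n_splits: int = 100,
                       test_fraction: float = 0.1, seed=None,
                       C: float = 1.0):
    """Permutation p-value for a decoding accuracy.

    Class labels are randomly permuted per iteration and the mean CV
    accuracy recomputed with a reduced split count; the p-value uses the
    max(count, 1)/n_perm convention, so an observation exceeding every
    permutation with 15000 iterations gives p = 6.67e-5.
    Returns (p, null accuracies).
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = as_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y)
        null[i] = mc_crossval_svm(X, perm, n_splits=n_splits,
                                  test_fraction=test_fraction, seed=rng,
                                  C=C).accuracy
    count = int(np.sum(null >= observed_accuracy))
    return permutation_p_from_counts(count, n_perm), null


def searchlight_accuracy(features, labels, montage: Montage,
                         n_splits: int = 50, test_fraction: float = 0.1,
                         seed=None, C: float = 1.0) -> dict:
    """Per-electrode information map from three local decoders.

    For each electrode: (a) the electrode alone, (b) the electrode with its
    contralateral partner (midline electrodes self-pair, so this equals the
    singleton variant), (c) the electrode with its 7 nearest neighbours.
    The three CV accuracies are averaged with equal weight.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    feat_labels = list(montage.labels)
    if X.shape[1] != len(feat_labels):
        raise ValueError("feature columns do not match montage electrodes")
    rng = as_rng(seed)
    out = {}
    for label in feat_labels:
        i = montage.index(label)
        pair = sorted({i, montage.index(montage.contralateral(label))})
        cluster = sorted({i} | {montage.index(l)
                                for l in montage.neighbors(label, 7)})
        accs = []
        for cols in ([i], pair, cluster):
            r = mc_crossval_svm(X[:, cols], y, n_splits=n_splits,
                                test_fraction=test_fraction, seed=rng, C=C)
            accs.append(r.accuracy)
        out[label] = float(np.mean(accs))
    return out


def decode_gender(features, labels, montage: Montage | None = None,
                  n_splits: int = 500, test_fraction: float = 0.1,
                  n_perm: int = 15000, permutation_cv_splits: int = 100,
                  searchlight_splits: int = 50, seed=None,
                  C: float = 1.0) -> DecodingResult:
    """Full decoding analysis: balance, scale, CV SVM, permutations,
    searchlight (searchlight only when a montage is given)."""
    rng = as_rng(seed)
    Xb, yb, n = balance_and_scale(features, labels, seed=rng)
    res = mc_crossval_svm(Xb, yb, n_splits=n_splits,
                          test_fraction=test_fraction, seed=rng, C=C)
    res.n_per_class = n
    if n_perm:
        p, _ = permutation_pvalue(Xb, yb, res.accuracy, n_perm=n_perm,
                                  n_splits=permutation_cv_splits,
                                  test_fraction=test_fraction, seed=rng, C=C)
        res.permutation_p = p
        res.n_permutations = n_perm
        res.permutation_cv_splits = permutation_cv_splits
    if montage is not None:
        res.searchlight = searchlight_accuracy(
            Xb, yb, montage, n_splits=searchlight_splits,
            test_fraction=test_fraction, seed=rng, C=C)
    return res
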