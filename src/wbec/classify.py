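"""Session/group classification from connectivity features.

Feature vectors are built per session — the lower triangle of symmetric
FC/SC matrices, or the masked directed entries of an EC matrix — and
z-scored within each session.  Two classifiers are evaluated over repeated
random 80/20 splits: a 1-nearest-neighbour rule under the Pearson
correlation metric (captures global profile similarity) and a linear
maximum-margin SVM (captures localized discriminative weights).  Chance
level is established with label-shuffled surrogates, and accuracy
distributions are compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .containers import MOUModel, SCMask
from .errors import InvalidInputError, InvalidParameterError, StandardizationError

logger = logging.getLogger(__name__)

SVM_C = 1.0  # linear-SVM regularization constant


@dataclass
class FeatureSet:
    """samples x features table with labels and an edge-identity index."""

    matrix: np.ndarray
    labels: np.ndarray
    metric_tag: str  # "ec" | "fc" | "sc"
    feature_index: list[tuple[int, int]]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise InvalidInputError("feature matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise InvalidInputError("labels length must match sample count")
        if len(self.feature_index) != self.matrix.shape[1]:
            raise InvalidInputError("feature_index length must match feature count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_features(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(
            matrix=self.matrix[:, idx],
            labels=self.labels.copy(),
            metric_tag=self.metric_tag,
            feature_index=[self.feature_index[i] for i in idx],
            subject_ids=list(self.subject_ids),
        )


@dataclass
class AccuracyDistribution:
    accuracies: np.ndarray
    classifier_tag: str  # "1nn" | "svm"
    n_splits: int
    surrogate: bool
    seed: int

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.accuracies) != self.n_splits:
            raise InvalidInputError("need one accuracy per split")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    direction: str  # "a", "b" or "equal"


def _standardize_rows(m: np.ndarray, who=None) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    flat = np.where(sd.ravel() == 0)[0]
    if flat.size:
        name = who[flat[0]] if who is not None else str(flat[0])
        raise StandardizationError(f"sample {name!r} has zero feature variance")
    return (m - mu) / sd


def build_features(
    models_or_matrices,
    metric_tag: str,
    mask: SCMask | None = None,
    labels=None,
    subject_ids=None,
) -> FeatureSet:
    """Vectorize per-session connectivity into a standardized feature set.

    ``metric_tag='fc'`` or ``'sc'``: inputs are symmetric matrices; the
    strictly-lower triangle is taken in row-major order (n(n-1)/2 features).
    ``metric_tag='ec'``: inputs are :class:`MOUModel` or raw EC matrices;
    the entries of the directed mask are taken in row-major order.  Every
    sample vector is then z-scored across features.
    """
    if metric_tag not in ("ec", "fc", "sc"):
        raise InvalidParameterError("metric_tag must be 'ec', 'fc' or 'sc'")
    items = list(models_or_matrices)
    if not items:
        raise InvalidInputError("no input sessions")
    mats = [it.ec if isinstance(it, MOUModel) else np.asarray(it, float)
            for it in items]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise InvalidInputError("all inputs must share the same region count")

    if metric_tag == "ec":
        if mask is None:
            first = items[0]
            if isinstance(first, MOUModel) and first.mask is not None:
                mask = first.mask
            else:
                raise InvalidInputError("EC features require an SC mask")
        src, tgt = np.nonzero(mask.mask)
        index = list(zip(src.tolist(), tgt.tolist()))
        X = np.stack([m[src, tgt] for m in mats])
    else:
        iu, ju = np.tril_indices(n, k=-1)
        index = list(zip(iu.tolist(), ju.tolist()))
        X = np.stack([m[iu, ju] for m in mats])

    subject_ids = list(subject_ids) if subject_ids is not None else [
        getattr(it, "subject_id", str(i)) for i, it in enumerate(items)
    ]
    if labels is None:
        raise InvalidInputError("labels are required")
    X = _standardize_rows(X, who=subject_ids)
    return FeatureSet(
        matrix=X,
        labels=np.asarray(labels),
        metric_tag=metric_tag,
        feature_index=index,
        subject_ids=subject_ids,
    )


def _fit_predict(clf_tag, Xtr, ytr, Xte):
    if clf_tag == "svm":
        clf = SVC(kernel="linear", C=SVM_C)
        clf.fit(Xtr, ytr)
        return clf.predict(Xte)
    if clf_tag == "1nn":
        # nearest neighbour under distance 1 - Pearson r; argmax takes the
        # lowest training index on ties
        a = Xte - Xte.mean(axis=1, keepdims=True)
        b = Xtr - Xtr.mean(axis=1, keepdims=True)
        num = a @ b.T
        den = np.outer(np.linalg.norm(a, axis=1), np.linalg.norm(b, axis=1))
        r = num / np.where(den == 0, 1.0, den)
        return ytr[np.argmax(r, axis=1)]
    raise InvalidParameterError("classifier_tag must be 'svm' or '1nn'")


def _split_indices(rng, n, test_fraction, y, subject_ids=None, max_redraw=100):
    """Random train/test split; with ``subject_ids`` both sessions of a
    subject always land on the same side (subject-level split)."""
    if subject_ids is not None:
        subjects = sorted(set(subject_ids))
        sids = np.asarray(subject_ids)
        n_test_subj = max(1, int(round(test_fraction * len(subjects))))
        if n_test_subj >= len(subjects):
            raise InvalidParameterError("test fraction leaves no training subjects")
        for _ in range(max_redraw):
            perm = rng.permutation(len(subjects))
            held = {subjects[i] for i in perm[:n_test_subj]}
            test = np.nonzero(np.isin(sids, list(held)))[0]
            train = np.nonzero(~np.isin(sids, list(held)))[0]
            if len(np.unique(y[train])) >= 2:
                return train, test
            logger.info("redrawing subject split: training set lacked a class")
        raise InvalidInputError("could not draw a 2-class training set")
    n_test = max(1, int(round(test_fraction * n)))
    if n_test >= n:
        raise InvalidParameterError("test fraction leaves no training samples")
    for _ in range(max_redraw):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if len(np.unique(y[train])) >= 2:
            return train, test
        logger.info("redrawing split: training set lacked a class")
    raise InvalidInputError("could not draw a training set containing 2 classes")


def evaluate_classifier(
    fs: FeatureSet,
    classifier_tag: str,
    n_splits: int = 50,
    test_fraction: float = 0.2,
    seed: int = 0,
    split_unit: str = "session",
    _shuffle_labels: bool = False,
) -> AccuracyDistribution:
    """Accuracy over repeated random train/test splits.

    ``split_unit='session'`` holds out a fraction of the samples;
    ``split_unit='subject'`` holds out whole subjects, keeping both
    sessions of a subject on the same side of the split (no pairing
    leakage).  Splits whose training set lacks a class are redrawn.
    """
    if n_splits < 1:
        raise InvalidParameterError("n_splits must be >= 1")
    if not 0 < test_fraction < 1:
        raise InvalidParameterError("test_fraction must be in (0, 1)")
    if len(np.unique(fs.labels)) < 2:
        raise InvalidInputError("need at least 2 classes")
    if split_unit not in ("session", "subject"):
        raise InvalidParameterError("split_unit must be 'session' or 'subject'")
    subject_ids = None
    if split_unit == "subject":
        if not fs.subject_ids:
            raise InvalidInputError("subject-level splits require subject_ids")
        subject_ids = fs.subject_ids
    rng = np.random.default_rng(seed)
    accs = np.empty(n_splits)
    for s in range(n_splits):
        y = fs.labels
        if _shuffle_labels:
            y = y[rng.permutation(fs.n_samples)]
        train, test = _split_indices(rng, fs.n_samples, test_fraction, y,
                                     subject_ids=subject_ids)
        pred = _fit_predict(classifier_tag, fs.matrix[train], y[train],
                            fs.matrix[test])
        accs[s] = np.mean(pred == y[test])
    return AccuracyDistribution(
        accuracies=accs, classifier_tag=classifier_tag, n_splits=n_splits,
        surrogate=_shuffle_labels, seed=seed,
    )


def surrogate_distribution(
    fs: FeatureSet,
    classifier_tag: str,
    n_splits: int = 50,
    test_fraction: float = 0.2,
    seed: int = 0,
    split_unit: str = "session",
) -> AccuracyDistribution:
    """Chance-level accuracy distribution from label-shuffled surrogates.

    Labels are freshly permuted before every split, then evaluated exactly
    as in :func:`evaluate_classifier`.
    """
    return evaluate_classifier(
        fs, classifier_tag, n_splits=n_splits, test_fraction=test_fraction,
        seed=seed, split_unit=split_unit, _shuffle_labels=True,
    )


def compare_distributions(
    a: AccuracyDistribution, b: AccuracyDistribution
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test between two accuracy distributions."""
    if len(a.accuracies) == 0 or len(b.accuracies) == 0:
        raise InvalidInputError("empty accuracy distribution")
    stat, p = stats.ranksums(a.accuracies, b.accuracies)
    if a.mean > b.mean:
        direction = "a"
    elif b.mean > a.mean:
        direction = "b"
    else:
        direction = "equal"
    return ComparisonResult(statistic=float(stat), p_value=float(p),
                            direction=direction)
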