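"""Support-network extraction by SVM recursive feature elimination.

A linear SVM is fitted repeatedly; at each round the features with the
smallest absolute hyperplane weights are discarded, producing a full
importance ranking (rank 1 = last survivor).  Over several random
train/test repetitions, held-out accuracy is traced as features are added
in rank order, and the smallest feature-subset size whose mean accuracy is
maximal — with no improvement from adding more — defines the "support
network" of directed EC edges that carries the discriminative signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .classify import SVM_C, FeatureSet, _split_indices
from .errors import InvalidInputError

# below this many remaining features, eliminate one per round; above it,
# drop 5% per round (the final ranks that matter are single-stepped)
SINGLE_STEP_BELOW = 200
COARSE_FRACTION = 0.05


@dataclass
class SupportNetwork:
    """Directed edges selected by SVM-RFE, with their importance ranks."""

    edges: list[tuple[int, int, int]]  # (source, target, rank)
    node_set: set[int]
    annotation: pd.DataFrame | None = None
    mean_accuracy_trace: np.ndarray | None = None
    evaluated_sizes: np.ndarray | None = None
    selected_size: int = 0
    selected_accuracy: float = float("nan")

    def __post_init__(self):
        ranks = [r for (_, _, r) in self.edges]
        if len(set(ranks)) != len(ranks) or (ranks and min(ranks) < 1):
            raise InvalidInputError("edge ranks must be unique positive integers")
        endpoints = {s for (s, _, _) in self.edges} | {t for (_, t, _) in self.edges}
        if self.node_set != endpoints:
            raise InvalidInputError("node_set must be the union of edge endpoints")


def _svm_weights(X, y):
    clf = SVC(kernel="linear", C=SVM_C)
    clf.fit(X, y)
    return np.abs(np.asarray(clf.coef_).ravel())


def rfe_ranking(
    fs: FeatureSet, elimination_step: int | float | None = None, seed: int = 0
) -> np.ndarray:
    """Full SVM-RFE importance ranking (a permutation of 1..n_features).

    ``elimination_step``: features removed per round — an int, a fraction of
    the remaining features, or None for the default schedule (5% per round
    while more than 200 features remain, then one per round).  Within an
    eliminated batch, ranks are ordered by ascending |weight|, so the
    ranking is always a strict permutation.
    """
    if len(np.unique(fs.labels)) < 2:
        raise InvalidInputError("need at least 2 classes for RFE")
    if fs.n_features < 2:
        raise InvalidInputError("need at least 2 features for RFE")
    X, y = fs.matrix, fs.labels
    remaining = np.arange(fs.n_features)
    ranks = np.zeros(fs.n_features, dtype=int)
    next_rank = fs.n_features  # worst rank assigned first
    while remaining.size > 1:
        w = _svm_weights(X[:, remaining], y)
        if elimination_step is None:
            k = 1 if remaining.size <= SINGLE_STEP_BELOW else max(
                1, int(round(COARSE_FRACTION * remaining.size)))
        elif isinstance(elimination_step, float) and 0 < elimination_step < 1:
            k = max(1, int(round(elimination_step * remaining.size)))
        else:
            k = max(1, int(elimination_step))
        k = min(k, remaining.size - 1)
        order = np.argsort(w, kind="stable")  # ascending |weight|
        drop = order[:k]
        # weakest feature gets the worst remaining rank
        for j in drop[::-1]:
            ranks[remaining[j]] = next_rank
            next_rank -= 1
        keep = np.ones(remaining.size, dtype=bool)
        keep[drop] = False
        remaining = remaining[keep]
    ranks[remaining[0]] = 1
    return ranks


def _size_grid(p: int) -> np.ndarray:
    """Subset sizes at which the accuracy trace is evaluated: every size up
    to 200, geometric steps (x1.25) above."""
    sizes = list(range(1, min(p, SINGLE_STEP_BELOW) + 1))
    s = float(sizes[-1])
    while sizes[-1] < p:
        s *= 1.25
        sizes.append(min(p, int(np.ceil(s))))
    return np.unique(np.asarray(sizes, dtype=int))


def select_support_network(
    fs: FeatureSet,
    n_repetitions: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    split_unit: str = "session",
) -> SupportNetwork:
    """Extract the discriminative edge subset via repeated SVM-RFE.

    For each repetition a random 80/20 split is drawn, the RFE ranking
    computed on the training samples only, and held-out accuracy evaluated
    for growing rank-ordered feature prefixes.  The selected size is the
    smallest prefix whose mean accuracy across repetitions is maximal (no
    larger evaluated prefix exceeds it beyond 1e-6).  Edges are resolved
    through the feature index using the consensus (mean) ranking across
    repetitions.
    """
    rng = np.random.default_rng(seed)
    p = fs.n_features
    sizes = _size_grid(p)
    acc = np.zeros((n_repetitions, sizes.size))
    rank_sum = np.zeros(p)
    subject_ids = fs.subject_ids if split_unit == "subject" else None
    for rep in range(n_repetitions):
        train, test = _split_indices(rng, fs.n_samples, test_fraction,
                                     fs.labels, subject_ids=subject_ids)
        tr = FeatureSet(
            matrix=fs.matrix[train], labels=fs.labels[train],
            metric_tag=fs.metric_tag, feature_index=fs.feature_index,
            subject_ids=[fs.subject_ids[i] for i in train]
            if fs.subject_ids else [],
        )
        ranking = rfe_ranking(tr, seed=seed + rep)
        rank_sum += ranking
        order = np.argsort(ranking, kind="stable")  # best rank first
        for si, k in enumerate(sizes):
            cols = order[:k]
            clf = SVC(kernel="linear", C=SVM_C)
            clf.fit(fs.matrix[np.ix_(train, cols)], fs.labels[train])
            pred = clf.predict(fs.matrix[np.ix_(test, cols)])
            acc[rep, si] = np.mean(pred == fs.labels[test])
    mean_acc = acc.mean(axis=0)
    best = mean_acc.max()
    k_star = int(sizes[np.argmax(mean_acc >= best - 1e-6)])
    # consensus ordering: mean rank across repetitions, ties by feature index
    consensus = np.lexsort((np.arange(p), rank_sum))
    selected = consensus[:k_star]
    edges = [
        (fs.feature_index[f][0], fs.feature_index[f][1], r + 1)
        for r, f in enumerate(selected)
    ]
    nodes = {s for (s, _, _) in edges} | {t for (_, t, _) in edges}
    return SupportNetwork(
        edges=edges,
        node_set=nodes,
        mean_accuracy_trace=mean_acc,
        evaluated_sizes=sizes,
        selected_size=k_star,
        selected_accuracy=float(best),
    )


def annotate_support(
    net: SupportNetwork, parcellation: pd.DataFrame
) -> pd.DataFrame:
    """Annotate support-network edges with region names and networks.

    ``parcellation`` needs columns index/name/network.  Direction is
    preserved: source -> target is the direction of influence under the EC
    orientation convention.
    """
    lut = parcellation.set_index("index")
    rows = []
    for (s, t, r) in sorted(net.edges, key=lambda e: e[2]):
        for idx in (s, t):
            if idx not in lut.index:
                raise KeyError(f"region index {idx} not in parcellation")
        rows.append({
            "rank": r,
            "source_index": s,
            "source_name": lut.loc[s, "name"],
            "source_network": lut.loc[s, "network"],
            "target_index": t,
            "target_name": lut.loc[t, "name"],
            "target_network": lut.loc[t, "network"],
        })
    table = pd.DataFrame(rows, columns=[
        "rank", "source_index", "source_name", "source_network",
        "target_index", "target_name", "target_network",
    ])
    net.annotation = table
    return table
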