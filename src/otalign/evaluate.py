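"""Barycentric projection and alignment-quality metrics.

Metrics follow the conventions of the single-cell diagonal-integration
literature: FOSCTTM (fraction of samples closer than the true match) for
datasets with known 1-1 cell correspondence, label-transfer accuracy for
labeled but uncorresponded datasets, mass-on-known-pairs for feature
couplings, and cell-type-level aggregation of a sample coupling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .ot_core import Coupling, DimensionError

__all__ = [
    "barycentric_project",
    "foscttm",
    "label_transfer_accuracy",
    "feature_mass_on_pairs",
    "celltype_match_accuracy",
]

logger = logging.getLogger(__name__)


def barycentric_project(P, Y) -> np.ndarray:
    """Project the first domain into the second domain's feature space.

    ``Yhat[i] = sum_j (P[i,j] / P#1[i]) * Y[j]`` — each first-domain cell
    becomes the coupling-weighted average of second-domain measurements,
    producing an in-silico co-assay on the first domain's cells.  Rows of
    ``P`` with zero mass (possible after unbalanced solves) are set to NaN
    with a warning.
    """
    plan = P.plan if isinstance(P, Coupling) else np.asarray(P, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if plan.shape[1] != Y.shape[0]:
        raise DimensionError(
            f"plan has {plan.shape[1]} columns but Y has {Y.shape[0]} rows"
        )
    row_mass = plan.sum(axis=1)
    out = np.full((plan.shape[0], Y.shape[1]), np.nan)
    ok = row_mass > 0
    if not np.all(ok):
        logger.warning(
            "barycentric_project: %d zero-mass rows set to NaN", int((~ok).sum())
        )
    out[ok] = (plan[ok] / row_mass[ok, None]) @ Y
    return out


def foscttm(A, B, bidirectional: bool = True) -> float:
    """Fraction of samples closer than the true match (lower is better).

    Rows of ``A`` and ``B`` are assumed matched by index.  For each cell i,
    counts the fraction of cells j != i whose Euclidean distance to i is
    *strictly* smaller than the true match's distance (ties do not count as
    closer), then averages over cells and — by default — over both directions
    (A against B and B against A).  0 means every cell's nearest candidate is
    its true match; random alignments average 0.5.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise DimensionError(f"A {A.shape} and B {B.shape} must have equal shape")
    n = A.shape[0]
    if n < 2:
        raise ValueError("FOSCTTM requires at least 2 samples")

    def _one_direction(P, Qm):
        d = cdist(P, Qm)
        true = np.diag(d)
        closer = (d < true[:, None]).sum(axis=1)
        # strict inequality: the true match itself never counts
        return float(np.mean(closer / (n - 1)))

    if bidirectional:
        return 0.5 * (_one_direction(A, B) + _one_direction(B, A))
    return _one_direction(A, B)


def label_transfer_accuracy(
    train_points, train_labels, test_points, test_labels
) -> float:
    """Accuracy of a kNN label classifier transferred across the alignment.

    The classifier is trained on the original domain (``train_points``) with
    ``k`` equal to the number of distinct training labels, and evaluated on
    the projected domain (``test_points``).  Majority vote among the k
    nearest training points; vote ties are broken by the nearest neighbor's
    label.  Test labels never seen in training count as errors (warned).
    """
    train_points = np.asarray(train_points, dtype=float)
    test_points = np.asarray(test_points, dtype=float)
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    if len(train_points) == 0:
        raise ValueError("training set must be nonempty")
    if len(train_labels) != len(train_points) or len(test_labels) != len(test_points):
        raise DimensionError("labels must match point counts")

    classes = np.unique(train_labels)
    unseen = set(np.unique(test_labels)) - set(classes)
    if unseen:
        logger.warning(
            "label_transfer_accuracy: test labels %s unseen in training count as errors",
            sorted(map(str, unseen)),
        )
    k = min(len(classes), len(train_points))
    nn = NearestNeighbors(n_neighbors=k).fit(train_points)
    _, idx = nn.kneighbors(test_points)

    correct = 0
    for i in range(len(test_points)):
        neigh = train_labels[idx[i]]
        vals, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        winners = set(vals[counts == top])
        if len(winners) == 1:
            pred = next(iter(winners))
        else:
            # tie: the nearest neighbor among the tied classes decides
            pred = next(lab for lab in neigh if lab in winners)
        if pred == test_labels[i]:
            correct += 1
    return correct / len(test_points)


def feature_mass_on_pairs(Q, pairs) -> float:
    """Fraction of a feature coupling's mass lying on known feature pairs.

    A uniform coupling puts ``len(pairs) / (rows * cols)`` of its mass on the
    pair set, which is the random-matching baseline to compare against.
    Invariant to positive rescaling of ``Q``.
    """
    plan = Q.plan if isinstance(Q, Coupling) else np.asarray(Q, dtype=float)
    pairs = list(pairs)
    if not pairs:
        logger.warning("feature_mass_on_pairs: empty pair list, returning 0")
        return 0.0
    rows, cols = zip(*pairs)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if rows.max() >= plan.shape[0] or cols.max() >= plan.shape[1]:
        raise DimensionError("pair indices exceed coupling shape")
    total = plan.sum()
    if total <= 0:
        raise ValueError("coupling has zero total mass")
    return float(plan[rows, cols].sum() / total)


def celltype_match_accuracy(P, labels_x, labels_y, truth) -> tuple[float, "object"]:
    """Cell-type-level matching accuracy from an aggregated coupling.

    Aggregates ``P`` into a type-by-type alignment matrix
    ``A[t, u] = sum_{i in t, j in u} P[i, j]``; each row type's predicted
    counterpart is the argmax over column types, and accuracy is the fraction
    of row types (present in ``truth``) whose prediction matches
    ``truth[t]``.  Returns ``(accuracy, aggregated)`` where ``aggregated`` is
    a pandas DataFrame indexed by row/column types.
    """
    import pandas as pd

    plan = P.plan if isinstance(P, Coupling) else np.asarray(P, dtype=float)
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    if len(labels_x) != plan.shape[0] or len(labels_y) != plan.shape[1]:
        raise DimensionError("labels must cover all rows/columns of P")

    types_x = [t for t in pd.unique(labels_x)]
    types_y = [t for t in pd.unique(labels_y)]
    agg = pd.DataFrame(0.0, index=types_x, columns=types_y)
    for t in types_x:
        rows = labels_x == t
        for u in types_y:
            agg.loc[t, u] = plan[np.ix_(rows, labels_y == u)].sum()

    scored = 0
    correct = 0
    for t in types_x:
        if t not in truth:
            logger.warning("celltype_match_accuracy: type %r absent from truth, excluded", t)
            continue
        if agg.loc[t].sum() == 0:
            logger.warning("celltype_match_accuracy: type %r carries no mass, excluded", t)
            continue
        scored += 1
        if agg.loc[t].idxmax() == truth[t]:
            correct += 1
    if scored == 0:
        raise ValueError("no row types could be scored against the truth map")
    return correct / scored, agg
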