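"""From-scratch C4.5 decision-tree classifier for continuous features.

Splits are binary threshold tests ``value <= t`` / ``value > t`` on a
single gene, with thresholds at midpoints between consecutive distinct
sorted values.  The split criterion is Quinlan's gain ratio — information
gain divided by the entropy of the branch-size distribution — maximised
over every (gene, threshold) candidate whose information gain is positive
and whose branches both hold at least ``min_samples_leaf`` samples.

Tie-breaking is fully deterministic (higher gain, then lower gene index,
then lower threshold) so that the tree — and hence the swarm fitness built
on it — is bit-reproducible.

Optional pessimistic pruning replaces a subtree by a leaf when the leaf's
pessimistic error count (exact binomial upper confidence bound at the
configured confidence, scaled by the node size) does not exceed the sum of
the subtree's leaf bounds.  Pruning is off by default: it is irrelevant
inside the swarm fitness loop and only useful for final-model reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import beta as _beta

__all__ = [
    "C45Params",
    "SplitTest",
    "TreeNode",
    "entropy",
    "candidate_thresholds",
    "split_scores",
    "best_split",
    "grow_tree",
    "prune_tree",
    "predict",
    "predict_dataset",
    "classification_accuracy",
    "format_tree",
    "count_nodes",
]

# Information-gain gate: analytic zero gains compute to ~1e-16 in floating
# point; anything below this tolerance is treated as no gain.
MIN_GAIN = 1e-12


@dataclass(frozen=True)
class C45Params:
    """Tree-induction hyperparameters.

    min_samples_leaf : smallest branch size a split may create (default 2).
    pruning_enabled : apply pessimistic subtree replacement after growth.
    pruning_confidence : one-sided binomial confidence for the pessimistic
        error bound, in (0, 1); smaller is more pessimistic (default 0.25).
    max_depth : optional cap on tree depth (root = depth 0).
    """

    min_samples_leaf: int = 2
    pruning_enabled: bool = False
    pruning_confidence: float = 0.25
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if not (0.0 < self.pruning_confidence < 1.0):
            raise ValueError("pruning_confidence must be in (0, 1)")


@dataclass(frozen=True)
class SplitTest:
    """Threshold test on one gene: left branch is ``value <= threshold``."""

    gene_index: int
    threshold: float


@dataclass
class TreeNode:
    """Leaf (``test is None``) or internal binary node.

    ``class_counts`` holds the training class distribution at the node,
    indexed like the label ordering used at fit time; for internal nodes
    it equals the elementwise sum of the children's counts.
    """

    class_counts: np.ndarray
    class_label: object
    test: Optional[SplitTest] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.test is None


def entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count vector.

    Zero for pure nodes, at most log2(number of classes); all-zero counts
    are a contract violation.
    """
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero class counts")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values.

    Empty when the vector has fewer than two distinct values (constant
    genes admit no split).
    """
    distinct = np.unique(np.asarray(values, dtype=float))
    if distinct.size < 2:
        return np.empty(0)
    return (distinct[:-1] + distinct[1:]) / 2.0


def split_scores(values, labels, threshold: float):
    """Information gain, split info and gain ratio of one threshold test.

    ``gain`` is parent entropy minus the size-weighted child entropies;
    ``split_info`` is the entropy of the two branch sizes; the ratio is
    their quotient.  Both branches must be non-empty (callers should only
    pass :func:`candidate_thresholds` output).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    left = values <= threshold
    n_left = int(left.sum())
    n = values.size
    if n_left == 0 or n_left == n:
        raise ValueError(f"threshold {threshold} leaves an empty branch")
    classes, codes = np.unique(labels, return_inverse=True)
    parent = np.bincount(codes, minlength=classes.size)
    left_counts = np.bincount(codes[left], minlength=classes.size)
    right_counts = parent - left_counts
    gain = entropy(parent) - (
        n_left * entropy(left_counts) + (n - n_left) * entropy(right_counts)
    ) / n
    split_info = entropy(np.array([n_left, n - n_left]))
    ratio = gain / split_info
    return float(gain), float(split_info), float(ratio)


def _entropy_matrix(counts: np.ndarray) -> np.ndarray:
    """Entropy along the last axis of a stack of count vectors."""
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -plogp.sum(axis=-1)


def _best_split_arrays(
    X: np.ndarray, codes: np.ndarray, n_classes: int, min_leaf: int
) -> Optional[SplitTest]:
    """Vectorised gain-ratio search over every (gene, threshold) pair.

    Evaluates all candidates at once: columns are sorted, class counts
    are accumulated cumulatively, and the gain ratio of every distinct-
    value boundary is computed in one array pass.
    """
    m, n = X.shape
    if m < 2 or n == 0:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = codes[order]  # (m, n)
    onehot = np.zeros((m, n, n_classes))
    np.put_along_axis(onehot, ys[:, :, None], 1.0, axis=2)
    left_counts = np.cumsum(onehot, axis=0)  # (m, n, C): counts among first i+1
    total = left_counts[-1, 0]  # identical for every gene
    parent_entropy = entropy(total)

    # split position i = boundary after sorted row i; left size i+1
    sizes_left = np.arange(1, m, dtype=float)  # (m-1,)
    sizes_right = m - sizes_left
    valid = Xs[1:] > Xs[:-1]  # distinct-value boundary, (m-1, n)
    valid &= (sizes_left[:, None] >= min_leaf) & (sizes_right[:, None] >= min_leaf)
    if not valid.any():
        return None

    lc = left_counts[:-1]  # (m-1, n, C)
    rc = total[None, None, :] - lc
    h_left = _entropy_matrix(lc)
    h_right = _entropy_matrix(rc)
    gain = parent_entropy - (
        sizes_left[:, None] * h_left + sizes_right[:, None] * h_right
    ) / m
    p_l = sizes_left / m
    split_info = -(p_l * np.log2(p_l) + (1 - p_l) * np.log2(1 - p_l))
    ratio = gain / split_info[:, None]

    ok = valid & (gain > MIN_GAIN)
    if not ok.any():
        return None
    neg = -np.inf
    ratio_ok = np.where(ok, ratio, neg)
    best_ratio = ratio_ok.max()
    tied = ok & (ratio_ok == best_ratio)
    gain_tied = np.where(tied, gain, neg)
    best_gain = gain_tied.max()
    tied &= gain_tied == best_gain
    gene = int(np.nonzero(tied.any(axis=0))[0][0])  # lowest gene index
    pos = int(np.nonzero(tied[:, gene])[0][0])  # lowest threshold (sorted)
    thr = float((Xs[pos, gene] + Xs[pos + 1, gene]) / 2.0)
    return SplitTest(gene_index=gene, threshold=thr)


def best_split(dataset, params: C45Params = C45Params()) -> Optional[SplitTest]:
    """Best gain-ratio split of a dataset, or None when no candidate
    has positive information gain and admissible branch sizes.

    Ties resolve by higher information gain, then lower gene index, then
    lower threshold.
    """
    codes = dataset.label_codes()
    return _best_split_arrays(
        dataset.values, codes, len(dataset.classes), params.min_samples_leaf
    )


def grow_tree(dataset, params: C45Params = C45Params()) -> TreeNode:
    """Induce a C4.5 tree on a dataset.

    Recursion stops at pure nodes, when no admissible split remains, or at
    ``max_depth``.  Leaf labels are the majority class, ties resolved by
    label order.  A zero-gene dataset yields a single majority-class leaf
    (this is how an empty gene mask degrades upstream).  With
    ``min_samples_leaf=1``, no depth cap and no contradictory duplicate
    rows, the tree fits its training data exactly.
    """
    if dataset.n_samples == 0:
        raise ValueError("cannot grow a tree on an empty dataset")
    classes = dataset.classes
    codes = dataset.label_codes()
    X = dataset.values
    tree = _grow(X, codes, classes, params, depth=0)
    if params.pruning_enabled:
        tree = prune_tree(tree, params)
    return tree


def _grow(X, codes, classes, params, depth) -> TreeNode:
    counts = np.bincount(codes, minlength=len(classes)).astype(float)
    label = classes[int(np.argmax(counts))]  # argmax takes earliest on ties
    node = TreeNode(class_counts=counts, class_label=label)
    if (counts > 0).sum() <= 1:
        return node
    if params.max_depth is not None and depth >= params.max_depth:
        return node
    test = _best_split_arrays(X, codes, len(classes), params.min_samples_leaf)
    if test is None:
        return node
    go_left = X[:, test.gene_index] <= test.threshold
    node.test = test
    node.left = _grow(X[go_left], codes[go_left], classes, params, depth + 1)
    node.right = _grow(X[~go_left], codes[~go_left], classes, params, depth + 1)
    return node


def _pessimistic_errors(counts: np.ndarray, confidence: float) -> float:
    """Pessimistic error count of a leaf: N times the exact binomial
    (Clopper-Pearson) upper confidence bound on the error rate."""
    n = counts.sum()
    errors = n - counts.max()
    if errors >= n:
        return float(n)
    ub = float(_beta.ppf(1.0 - confidence, errors + 1, n - errors))
    return float(n * ub)


def _subtree_pessimistic(node: TreeNode, confidence: float) -> float:
    if node.is_leaf:
        return _pessimistic_errors(node.class_counts, confidence)
    return _subtree_pessimistic(node.left, confidence) + _subtree_pessimistic(
        node.right, confidence
    )


def prune_tree(tree: TreeNode, params: C45Params) -> TreeNode:
    """Bottom-up pessimistic subtree replacement.

    A subtree collapses to a leaf when the leaf's pessimistic error count
    is no larger than the summed pessimistic errors of the subtree's
    leaves.  No-op when ``pruning_enabled`` is off.  The input tree is not
    modified.
    """
    if not params.pruning_enabled:
        return tree
    return _prune(tree, params.pruning_confidence)


def _prune(node: TreeNode, confidence: float) -> TreeNode:
    if node.is_leaf:
        return TreeNode(
            class_counts=node.class_counts.copy(), class_label=node.class_label
        )
    left = _prune(node.left, confidence)
    right = _prune(node.right, confidence)
    as_leaf = _pessimistic_errors(node.class_counts, confidence)
    kept = (
        _subtree_pessimistic(left, confidence)
        + _subtree_pessimistic(right, confidence)
    )
    if as_leaf <= kept:
        return TreeNode(
            class_counts=node.class_counts.copy(), class_label=node.class_label
        )
    return TreeNode(
        class_counts=node.class_counts.copy(),
        class_label=node.class_label,
        test=node.test,
        left=left,
        right=right,
    )


def predict(tree: TreeNode, sample) -> object:
    """Classify one expression vector by root-to-leaf traversal."""
    sample = np.asarray(sample, dtype=float)
    node = tree
    while not node.is_leaf:
        idx = node.test.gene_index
        if idx >= sample.size or np.isnan(sample[idx]):
            raise ValueError(f"sample lacks a value for gene index {idx}")
        node = node.left if sample[idx] <= node.test.threshold else node.right
    return node.class_label


def predict_dataset(tree: TreeNode, dataset) -> np.ndarray:
    """Predicted label for every sample of a dataset."""
    return np.array([predict(tree, row) for row in dataset.values], dtype=object)


def classification_accuracy(tree: TreeNode, dataset) -> float:
    """Fraction of dataset samples the tree labels correctly."""
    if dataset.n_samples == 0:
        raise ValueError("accuracy undefined on an empty dataset")
    predicted = predict_dataset(tree, dataset)
    return float(np.mean(predicted == dataset.labels))


def count_nodes(tree: TreeNode) -> int:
    if tree.is_leaf:
        return 1
    return 1 + count_nodes(tree.left) + count_nodes(tree.right)


def format_tree(tree: TreeNode, gene_names, indent: str = "  ") -> str:
    """Indented text rendering: one test per line, leaves as
    ``class (count)``."""
    gene_names = np.asarray(gene_names, dtype=object)
    lines: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        pad = indent * depth
        if node.is_leaf:
            lines.append(f"{pad}{node.class_label} ({int(node.class_counts.sum())})")
            return
        name = gene_names[node.test.gene_index]
        thr = node.test.threshold
        lines.append(f"{pad}{name} <= {thr:g}")
        walk(node.left, depth + 1)
        lines.append(f"{pad}{name} > {thr:g}")
        walk(node.right, depth + 1)

    walk(tree, 0)
    return "\n".join(lines)
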