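"""C4.5 core: entropy, thresholds, splits, growth, pruning, prediction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psodt.data import subset_genes
from psodt.tree import (
    MIN_GAIN,
    C45Params,
    SplitTest,
    TreeNode,
    best_split,
    candidate_thresholds,
    classification_accuracy,
    count_nodes,
    entropy,
    format_tree,
    grow_tree,
    predict,
    predict_dataset,
    prune_tree,
    split_scores,
)

from .conftest import make_dataset


# ---------------------------------------------------------------- entropy

@pytest.mark.parametrize(
    "counts, expected",
    [
        ([2, 2], 1.0),
        ([4, 0], 0.0),
        ([9, 5], 0.940286),  # -(9/14)log2(9/14) - (5/14)log2(5/14)
        ([1, 1, 1, 1], 2.0),
    ],
)
def test_entropy_known_values(counts, expected):
    assert entropy(counts) == pytest.approx(expected, abs=1e-6)


def test_entropy_rejects_all_zero():
    with pytest.raises(ValueError):
        entropy([0, 0])


@given(st.lists(st.integers(0, 50), min_size=1, max_size=6).filter(lambda c: sum(c) > 0))
@settings(derandomize=True, max_examples=200)
def test_entropy_bounds(counts):
    h = entropy(counts)
    assert 0.0 <= h <= np.log2(len(counts)) + 1e-12


# ----------------------------------------------------- candidate thresholds

@pytest.mark.parametrize(
    "values, expected",
    [
        ([1, 2, 3], [1.5, 2.5]),
        ([5, 5, 5], []),
        ([2, 1], [1.5]),  # order-independent
        ([7], []),
    ],
)
def test_candidate_thresholds(values, expected):
    assert candidate_thresholds(values).tolist() == expected


# ------------------------------------------------------------ split scores

def test_split_scores_perfect_balanced_split():
    gain, info, ratio = split_scores([1, 2, 3, 4], ["A", "A", "B", "B"], 2.5)
    assert (gain, info, ratio) == (1.0, 1.0, 1.0)


def test_split_scores_uninformative_split():
    # children inherit the parent's class proportions -> zero gain
    gain, _, _ = split_scores([1, 2, 3, 4], ["A", "B", "A", "B"], 2.5)
    assert gain == pytest.approx(0.0, abs=1e-12)


def test_split_scores_rejects_empty_branch():
    with pytest.raises(ValueError):
        split_scores([1, 2, 3], ["A", "A", "B"], 5.0)


# ------------------------------------------------- best_split vs brute force

def brute_force_best_split(dataset, min_samples_leaf=1):
    """Independent oracle: enumerate every (gene, threshold), score with
    split_scores, apply the documented tie-breaks by explicit sorting."""
    candidates = []
    labels = dataset.labels
    for g in range(dataset.n_genes):
        col = dataset.values[:, g]
        for thr in candidate_thresholds(col):
            n_left = int((col <= thr).sum())
            if n_left < min_samples_leaf or dataset.n_samples - n_left < min_samples_leaf:
                continue
            gain, _, ratio = split_scores(col, labels, thr)
            if gain > MIN_GAIN:
                candidates.append((ratio, gain, g, float(thr)))
    if not candidates:
        return None
    best = max(candidates, key=lambda c: (c[0], c[1], -c[2], -c[3]))
    return SplitTest(gene_index=best[2], threshold=best[3])


def random_tiny_dataset(rng):
    n = rng.integers(2, 7)
    m = rng.integers(1, 4)
    values = rng.integers(1, 4, size=(n, m)).astype(float)
    labels = rng.choice(["A", "B"], size=n)
    return make_dataset(values, labels)


def test_best_split_matches_brute_force_oracle():
    rng = np.random.default_rng(20260922)
    for _ in range(300):
        ds = random_tiny_dataset(rng)
        got = best_split(ds, C45Params(min_samples_leaf=1))
        want = brute_force_best_split(ds)
        if want is None:
            assert got is None
        else:
            assert got == want


def test_best_split_perfect_gene_wins(separable_dataset):
    test = best_split(separable_dataset, C45Params(min_samples_leaf=1))
    assert test == SplitTest(gene_index=0, threshold=2.5)


def test_best_split_none_on_constant_genes():
    ds = make_dataset([[3, 3], [3, 3], [3, 3]], ["A", "B", "A"])
    assert best_split(ds, C45Params(min_samples_leaf=1)) is None


def test_best_split_tie_prefers_lower_gene_index():
    # identical duplicated gene: identical scores, gene 0 must win
    ds = make_dataset([[1, 1], [2, 2], [3, 3], [4, 4]], ["A", "A", "B", "B"])
    test = best_split(ds, C45Params(min_samples_leaf=1))
    assert test.gene_index == 0


def test_best_split_respects_min_samples_leaf():
    ds = make_dataset([[1], [2], [3], [4]], ["A", "B", "B", "B"])
    test = best_split(ds, C45Params(min_samples_leaf=2))
    assert test is None or min(
        (ds.values[:, test.gene_index] <= test.threshold).sum(),
        (ds.values[:, test.gene_index] > test.threshold).sum(),
    ) >= 2


# -------------------------------------------------------------- grow_tree

def test_grow_tree_single_gene(separable_dataset):
    tree = grow_tree(separable_dataset, C45Params(min_samples_leaf=1))
    assert tree.test == SplitTest(gene_index=0, threshold=2.5)
    assert tree.left.is_leaf and tree.right.is_leaf
    assert tree.left.class_label == "A" and tree.right.class_label == "B"


def test_grow_tree_pure_dataset_is_single_leaf():
    ds = make_dataset([[1], [2], [3]], ["A", "A", "A"])
    tree = grow_tree(ds)
    assert tree.is_leaf and tree.class_label == "A"


def test_grow_tree_zero_genes_majority_leaf():
    ds = make_dataset(np.empty((3, 0)), ["A", "A", "B"])
    tree = grow_tree(ds)
    assert tree.is_leaf and tree.class_label == "A"
    assert classification_accuracy(tree, ds) == pytest.approx(2 / 3)


def test_grow_tree_xor_stops_at_zero_gain(xor_dataset):
    # greedy gain-ratio induction cannot split XOR: every single-gene
    # split at the root has zero information gain, so the gate stops growth
    tree = grow_tree(xor_dataset, C45Params(min_samples_leaf=1))
    assert tree.is_leaf
    assert classification_accuracy(tree, xor_dataset) == 0.5


def test_grow_tree_max_depth_caps_structure(separable_dataset):
    tree = grow_tree(separable_dataset, C45Params(min_samples_leaf=1, max_depth=0))
    assert tree.is_leaf


def test_counts_conservation_and_consistency():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(4, 20))
        m = int(rng.integers(1, 5))
        ds = make_dataset(
            rng.normal(size=(n, m)), rng.choice(["A", "B", "C"], size=n)
        )
        tree = grow_tree(ds, C45Params(min_samples_leaf=1))
        _assert_counts_conserved(tree)
        # continuous values: duplicates almost surely absent -> exact fit
        assert classification_accuracy(tree, ds) == 1.0


def _assert_counts_conserved(node):
    if node.is_leaf:
        return
    np.testing.assert_array_equal(
        node.class_counts, node.left.class_counts + node.right.class_counts
    )
    assert node.left.class_counts.sum() >= 1
    assert node.right.class_counts.sum() >= 1
    _assert_counts_conserved(node.left)
    _assert_counts_conserved(node.right)


def test_label_permutation_equivariance():
    rng = np.random.default_rng(11)
    values = rng.normal(size=(12, 3))
    labels = rng.choice(["A", "B"], size=12)
    swap = {"A": "B", "B": "A"}
    ds1 = make_dataset(values, labels)
    ds2 = make_dataset(values, [swap[l] for l in labels])
    t1 = grow_tree(ds1, C45Params(min_samples_leaf=1))
    t2 = grow_tree(ds2, C45Params(min_samples_leaf=1))

    def structure(node):
        if node.is_leaf:
            return ("leaf",)
        return (node.test, structure(node.left), structure(node.right))

    assert structure(t1) == structure(t2)
    assert classification_accuracy(t1, ds1) == classification_accuracy(t2, ds2)


def test_monotone_transform_invariance():
    rng = np.random.default_rng(13)
    values = rng.normal(size=(15, 3))
    labels = rng.choice(["A", "B"], size=15)
    ds = make_dataset(values, labels)
    transformed = values.copy()
    transformed[:, 1] = np.exp(values[:, 1])  # strictly increasing
    ds_t = make_dataset(transformed, labels)
    t1 = grow_tree(ds, C45Params(min_samples_leaf=1))
    t2 = grow_tree(ds_t, C45Params(min_samples_leaf=1))
    np.testing.assert_array_equal(predict_dataset(t1, ds), predict_dataset(t2, ds_t))


# ---------------------------------------------------------------- pruning

def _leaf(counts, label):
    return TreeNode(class_counts=np.asarray(counts, dtype=float), class_label=label)


def test_prune_collapses_same_prediction_children():
    tree = TreeNode(
        class_counts=np.array([20.0, 0.0]),
        class_label="A",
        test=SplitTest(0, 0.5),
        left=_leaf([10, 0], "A"),
        right=_leaf([10, 0], "A"),
    )
    pruned = prune_tree(tree, C45Params(pruning_enabled=True))
    assert pruned.is_leaf and pruned.class_label == "A"


def test_prune_disabled_is_identity(separable_dataset):
    tree = grow_tree(separable_dataset, C45Params(min_samples_leaf=1))
    same = prune_tree(tree, C45Params(pruning_enabled=False))
    assert same is tree


def test_prune_pessimistic_bound_decides():
    """Decision matches the exact binomial (Clopper-Pearson) upper bound
    computed independently here.

    A split isolating 1 sample from 20 of the other class: the E=1
    replacement-leaf bound exceeds the two E=0 child bounds at every
    confidence level, so the split survives; a near-parity uninformative
    split collapses.
    """
    from scipy.stats import beta

    def pess(counts, cf):
        n, e = sum(counts), sum(counts) - max(counts)
        return n * beta.ppf(1 - cf, e + 1, n - e)

    isolating = TreeNode(
        class_counts=np.array([20.0, 1.0]),
        class_label="A",
        test=SplitTest(0, 0.5),
        left=_leaf([20, 0], "A"),
        right=_leaf([0, 1], "B"),
    )
    for cf in (0.05, 0.25, 0.5):
        expect_prune = pess([20, 1], cf) <= pess([20, 0], cf) + pess([0, 1], cf)
        pruned = prune_tree(
            isolating, C45Params(pruning_enabled=True, pruning_confidence=cf)
        )
        assert pruned.is_leaf == expect_prune
        assert not pruned.is_leaf  # frozen outcome: this split is never pruned

    parity = TreeNode(
        class_counts=np.array([10.0, 8.0]),
        class_label="A",
        test=SplitTest(0, 0.5),
        left=_leaf([5, 4], "A"),
        right=_leaf([5, 4], "A"),
    )
    assert pess([10, 8], 0.25) <= 2 * pess([5, 4], 0.25)
    assert prune_tree(parity, C45Params(pruning_enabled=True)).is_leaf


def test_prune_never_increases_nodes_and_preserves_noop_predictions():
    rng = np.random.default_rng(17)
    for _ in range(10):
        ds = make_dataset(
            rng.normal(size=(30, 4)), rng.choice(["A", "B"], size=30)
        )
        tree = grow_tree(ds, C45Params(min_samples_leaf=1))
        pruned = prune_tree(
            tree, C45Params(pruning_enabled=True, pruning_confidence=0.25)
        )
        assert count_nodes(pruned) <= count_nodes(tree)
        if count_nodes(pruned) == count_nodes(tree):
            np.testing.assert_array_equal(
                predict_dataset(pruned, ds), predict_dataset(tree, ds)
            )


# ------------------------------------------------------------- prediction

@pytest.fixture
def female_cancer_tree():
    """Hand-built three-marker tree distinguishing uterus, cervix uteri
    and ovary tumours by probe-set thresholds (gene order: 218934_s_at,
    206166_s_at, 212341_at)."""
    return TreeNode(
        class_counts=np.array([4.0, 3.0, 3.0]),
        class_label="cervix uteri",
        test=SplitTest(0, 2.7133),
        right=_leaf([0, 0, 3], "uterus"),
        left=TreeNode(
            class_counts=np.array([4.0, 3.0, 0.0]),
            class_label="cervix uteri",
            test=SplitTest(1, 2.5063),
            right=_leaf([2, 0, 0], "cervix uteri"),
            left=TreeNode(
                class_counts=np.array([2.0, 3.0, 0.0]),
                class_label="ovary",
                test=SplitTest(2, 10.026),
                left=_leaf([0, 3, 0], "ovary"),
                right=_leaf([2, 0, 0], "cervix uteri"),
            ),
        ),
    )


@pytest.mark.parametrize(
    "sample, expected",
    [
        ([3.0, 0.0, 0.0], "uterus"),
        ([2.0, 3.0, 0.0], "cervix uteri"),
        ([2.0, 2.0, 9.0], "ovary"),
        ([2.0, 2.0, 11.0], "cervix uteri"),
        # boundary values follow the <= convention
        ([2.7133, 2.5063, 10.026], "ovary"),
    ],
)
def test_marker_tree_assignments(female_cancer_tree, sample, expected):
    assert predict(female_cancer_tree, sample) == expected


def test_predict_missing_gene_value_errors(female_cancer_tree):
    with pytest.raises(ValueError):
        predict(female_cancer_tree, [2.0, np.nan, 9.0])
    with pytest.raises(ValueError):
        predict(female_cancer_tree, [2.0])


def test_classification_accuracy_cases(separable_dataset):
    tree = grow_tree(separable_dataset, C45Params(min_samples_leaf=1))
    assert classification_accuracy(tree, separable_dataset) == 1.0
    wrong = make_dataset(separable_dataset.values, ["B", "B", "A", "A"])
    assert classification_accuracy(tree, wrong) == 0.0


def test_format_tree_round_structure(separable_dataset):
    tree = grow_tree(separable_dataset, C45Params(min_samples_leaf=1))
    text = format_tree(tree, separable_dataset.gene_names)
    assert text.splitlines() == [
        "g1 <= 2.5",
        "  A (2)",
        "g1 > 2.5",
        "  B (2)",
    ]
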