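"""PSODT orchestration: cross-validated swarm gene selection.

The wrapper protocol: a binary particle encodes a gene subset; its fitness
is the mean held-out accuracy of a C4.5 tree trained on exactly those
genes, estimated by stratified cross-validation.  The swarm searches mask
space; the best mask per evaluation fold is then refit and scored on that
fold's untouched test samples.

Two protocols are provided:

``nested`` (default)
    Selection runs independently inside each outer training fold, with an
    internal stratified k'-fold (default 3) supplying the fitness.  Test
    samples never influence selection or fitting within their fold, so
    the reported outer accuracy is an unbiased estimate of the whole
    selection-plus-classification pipeline.

``naive``
    A single swarm run whose fitness is k-fold cross-validation on the
    full dataset — the literal reading of running the optimizer once and
    reporting its cross-validated fitness.  Optimistically biased (the
    selection has seen every sample); provided for comparison only.

Repeated runs with derived seeds give the per-run accuracy / gene-count
report shape, and gene-selection frequency across all outer folds of all
runs identifies the stably selected genes (``frequency >= 4`` flags a
gene as frequent by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionDataset, subset_genes
from .swarm import PSOParams, run as pso_run
from .tree import C45Params, TreeNode, classification_accuracy, grow_tree

__all__ = [
    "CVConfig",
    "FoldResult",
    "SelectionResult",
    "RunRecord",
    "RunSummary",
    "GeneFrequencyTable",
    "stratified_folds",
    "cv_fitness",
    "select_on_training",
    "run_psodt",
    "summarize_runs",
    "repeat_runs",
    "gene_selection_frequency",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol: ``k`` folds (default 5), stratified by
    class unless disabled, deterministic given ``seed``."""

    k: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class FoldResult:
    fold: int
    mask: np.ndarray
    test_accuracy: float
    fitness: float
    history: List[float]


@dataclass
class SelectionResult:
    """Outcome of one full PSODT run over the outer folds."""

    folds: List[FoldResult]
    mean_accuracy: float
    union_mask: np.ndarray
    intersection_mask: np.ndarray
    gene_names: np.ndarray
    seed: int
    mode: str
    config: dict
    final_tree: Optional[TreeNode] = None

    @property
    def n_union(self) -> int:
        return int(self.union_mask.sum())

    @property
    def n_intersection(self) -> int:
        return int(self.intersection_mask.sum())


@dataclass
class RunRecord:
    run: int
    seed: int
    accuracy_pct: float
    n_selected: int


@dataclass
class RunSummary:
    """Per-run accuracies and gene counts with mean / sample-sd footer."""

    runs: List[RunRecord]
    mean_accuracy_pct: float
    std_accuracy_pct: float
    mean_n_selected: float
    std_n_selected: float
    degenerate_std: bool
    results: List[SelectionResult] = field(default_factory=list)


@dataclass
class GeneFrequencyTable:
    """Per-gene selection frequency across fold x run selection events."""

    table: pd.DataFrame  # columns: gene, frequency, frequent
    threshold: int
    n_events: int

    def selected_at_least_once(self) -> pd.DataFrame:
        return self.table[self.table["frequency"] > 0].reset_index(drop=True)

    def frequent_genes(self) -> np.ndarray:
        return self.table.loc[self.table["frequent"], "gene"].to_numpy(dtype=object)


def stratified_folds(labels, k: int, rng) -> np.ndarray:
    """Deterministic balanced stratified fold assignment.

    Within each class, per-fold counts differ by at most one; overall
    fold sizes also differ by at most one (each class's remainder samples
    go to the currently smallest folds, lowest fold index first).
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    assignment = np.empty(n, dtype=np.intp)
    fold_sizes = np.zeros(k, dtype=np.intp)
    for cls in sorted(set(labels)):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        m = idx.size
        base, rem = divmod(m, k)
        # remainder goes to the smallest folds (stable ties by fold index)
        order = np.argsort(fold_sizes, kind="stable")
        per_fold = np.full(k, base, dtype=np.intp)
        per_fold[order[:rem]] += 1
        start = 0
        for f in range(k):
            assignment[idx[start : start + per_fold[f]]] = f
            start += per_fold[f]
        fold_sizes += per_fold
    return assignment


def _unstratified_folds(n: int, k: int, rng) -> np.ndarray:
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.intp)
    assignment[perm] = np.arange(n) % k
    return assignment


def _fold_assignment(labels, cv: CVConfig, rng) -> np.ndarray:
    if cv.stratified:
        return stratified_folds(labels, cv.k, rng)
    return _unstratified_folds(len(labels), cv.k, rng)


def _majority_proportion(labels) -> float:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return float(counts.max() / counts.sum())


def cv_fitness(
    mask: np.ndarray,
    train_data: ExpressionDataset,
    cv: CVConfig,
    tree_params: C45Params = C45Params(),
    fold_assignment: Optional[np.ndarray] = None,
) -> float:
    """Mean held-out C4.5 accuracy of a gene mask under k-fold CV.

    The all-zero mask scores the training majority-class proportion, so
    degenerate particles are dominated by any informative subset without
    raising.  A precomputed ``fold_assignment`` makes repeated calls with
    different masks use identical folds (required for a deterministic
    swarm fitness).
    """
    mask = np.asarray(mask)
    if mask.shape != (train_data.n_genes,):
        raise ValueError("mask length does not match gene count")
    if mask.sum() == 0:
        return _majority_proportion(train_data.labels)
    if fold_assignment is None:
        rng = np.random.default_rng(cv.seed)
        fold_assignment = _fold_assignment(train_data.labels, cv, rng)
    restricted = subset_genes(train_data, mask)
    accuracies = []
    for f in range(cv.k):
        test_idx = np.nonzero(fold_assignment == f)[0]
        train_idx = np.nonzero(fold_assignment != f)[0]
        if test_idx.size == 0 or train_idx.size == 0:
            continue
        tree = grow_tree(restricted.take_samples(train_idx), tree_params)
        accuracies.append(
            classification_accuracy(tree, restricted.take_samples(test_idx))
        )
    return float(np.mean(accuracies))


def _fold_seed_sequence(seed: int, fold: int) -> np.random.SeedSequence:
    # keyed on (seed, fold) only, so a fold's stream is independent of the
    # other folds and of how many samples the other folds held
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(fold),))


def select_on_training(
    train_data: ExpressionDataset,
    pso: PSOParams,
    tree_params: C45Params,
    inner_k: int,
    fold_seed: np.random.SeedSequence,
):
    """Swarm selection on one training portion.

    Fitness is inner stratified ``inner_k``-fold CV accuracy on
    ``train_data`` only.  Fitness values are cached per mask, which leaves
    results unchanged (the fitness is deterministic given the fixed inner
    folds) while skipping repeated tree inductions.

    Returns (mask, fitness, history).
    """
    inner_seed, pso_seed = fold_seed.spawn(2)
    inner_rng = np.random.default_rng(inner_seed)
    inner_cv = CVConfig(k=inner_k, stratified=True, seed=0)
    assignment = _fold_assignment(train_data.labels, inner_cv, inner_rng)
    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = cv_fitness(
                mask, train_data, inner_cv, tree_params, fold_assignment=assignment
            )
        return cache[key]

    return pso_run(
        fitness, train_data.n_genes, pso, np.random.default_rng(pso_seed)
    )


def run_psodt(
    dataset: ExpressionDataset,
    pso: PSOParams = PSOParams(),
    cv: CVConfig = CVConfig(),
    tree_params: C45Params = C45Params(),
    seed: int = 0,
    mode: str = "nested",
    inner_k: int = 3,
) -> SelectionResult:
    """Full PSODT evaluation: outer stratified k-fold with swarm gene
    selection, per-fold refit and held-out scoring.

    In ``nested`` mode each outer fold's selection sees only that fold's
    training samples.  In ``naive`` mode one swarm run is fitted with
    k-fold CV fitness on the full dataset and its single mask is then
    refit/scored per fold — a leaky protocol kept only for comparison.

    The reporting tree (``final_tree``) is grown on the full dataset
    restricted to the union mask; it illustrates the selected classifier
    structure and is not part of any accuracy estimate.
    """
    if mode not in ("nested", "naive"):
        raise ValueError(f"unknown mode {mode!r}")
    outer_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    assignment = _fold_assignment(dataset.labels, cv, outer_rng)

    shared = None
    if mode == "naive":
        # sentinel fold key outside the outer-fold range
        shared = select_on_training(
            dataset, pso, tree_params, cv.k, _fold_seed_sequence(seed, 2**31 - 1)
        )

    folds: List[FoldResult] = []
    for f in range(cv.k):
        test_idx = np.nonzero(assignment == f)[0]
        train_idx = np.nonzero(assignment != f)[0]
        train_ds = dataset.take_samples(train_idx)
        test_ds = dataset.take_samples(test_idx)
        if mode == "nested":
            mask, fitness, history = select_on_training(
                train_ds, pso, tree_params, inner_k, _fold_seed_sequence(seed, f)
            )
        else:
            mask, fitness, history = shared
        tree = grow_tree(subset_genes(train_ds, mask), tree_params)
        acc = classification_accuracy(tree, subset_genes(test_ds, mask))
        folds.append(
            FoldResult(
                fold=f,
                mask=np.asarray(mask, dtype=np.int8),
                test_accuracy=float(acc),
                fitness=float(fitness),
                history=list(history),
            )
        )

    masks = np.stack([fr.mask for fr in folds])
    union = (masks.max(axis=0) > 0).astype(np.int8)
    inter = (masks.min(axis=0) > 0).astype(np.int8)
    final_tree = grow_tree(subset_genes(dataset, union), tree_params)
    return SelectionResult(
        folds=folds,
        mean_accuracy=float(np.mean([fr.test_accuracy for fr in folds])),
        union_mask=union,
        intersection_mask=inter,
        gene_names=dataset.gene_names,
        seed=int(seed),
        mode=mode,
        config={
            "k": cv.k,
            "inner_k": inner_k,
            "stratified": cv.stratified,
            "pso": pso,
            "tree": tree_params,
        },
        final_tree=final_tree,
    )


def summarize_runs(
    accuracies_pct: Sequence[float], gene_counts: Sequence[int]
) -> dict:
    """Mean and sample (n-1) standard deviation of per-run accuracies (%)
    and selected-gene counts — the standard per-run report footer.

    A single run reports std 0 by convention, flagged ``degenerate_std``.
    """
    acc = np.asarray(accuracies_pct, dtype=float)
    cnt = np.asarray(gene_counts, dtype=float)
    if acc.size == 0:
        raise ValueError("no runs to summarize")
    degenerate = acc.size < 2
    return {
        "mean_accuracy_pct": float(acc.mean()),
        "std_accuracy_pct": 0.0 if degenerate else float(acc.std(ddof=1)),
        "mean_n_selected": float(cnt.mean()),
        "std_n_selected": 0.0 if degenerate else float(cnt.std(ddof=1)),
        "degenerate_std": degenerate,
    }


def repeat_runs(
    dataset: ExpressionDataset,
    pso: PSOParams = PSOParams(),
    cv: CVConfig = CVConfig(),
    tree_params: C45Params = C45Params(),
    n_runs: int = 5,
    master_seed: int = 0,
    mode: str = "nested",
    inner_k: int = 3,
) -> RunSummary:
    """Repeat :func:`run_psodt` with seeds derived from ``master_seed``.

    Each run reports its mean outer accuracy (as a percentage) and the
    number of genes in the union of its fold masks; the summary carries
    mean and sample standard deviation of both.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [
        int(s) % (2**31)
        for s in np.random.SeedSequence(int(master_seed)).generate_state(n_runs)
    ]
    records: List[RunRecord] = []
    results: List[SelectionResult] = []
    for i, s in enumerate(seeds, start=1):
        res = run_psodt(
            dataset, pso=pso, cv=cv, tree_params=tree_params, seed=s,
            mode=mode, inner_k=inner_k,
        )
        results.append(res)
        records.append(
            RunRecord(
                run=i,
                seed=s,
                accuracy_pct=100.0 * res.mean_accuracy,
                n_selected=res.n_union,
            )
        )
    stats = summarize_runs(
        [r.accuracy_pct for r in records], [r.n_selected for r in records]
    )
    return RunSummary(runs=records, results=results, **stats)


def gene_selection_frequency(
    results: Sequence[SelectionResult], threshold: int = 4
) -> GeneFrequencyTable:
    """Count, for every gene, the outer-fold selection events (across all
    given runs) that included it.

    The table lists every gene, sorted by frequency descending then name;
    genes at or above ``threshold`` are flagged frequent.
    """
    if not results:
        raise ValueError("no selection results given")
    names = results[0].gene_names
    for res in results[1:]:
        if res.gene_names.shape != names.shape or not np.array_equal(
            res.gene_names, names
        ):
            raise ValueError("selection results use different gene namespaces")
    counts = np.zeros(names.size, dtype=int)
    n_events = 0
    for res in results:
        for fr in res.folds:
            counts += fr.mask.astype(int)
            n_events += 1
    table = pd.DataFrame({"gene": names, "frequency": counts})
    table["frequent"] = table["frequency"] >= threshold
    table = table.sort_values(
        ["frequency", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return GeneFrequencyTable(table=table, threshold=threshold, n_events=n_events)
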