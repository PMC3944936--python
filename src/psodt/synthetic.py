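"""Synthetic microarray-like data with a planted informative-gene set.

Emulates the shape of the benchmark expression matrices the selection
pipeline targets — tens to hundreds of samples, hundreds to thousands of
continuous features, two or more classes — with known ground truth so
recovery can be measured without any external download.

Model: every gene is Normal(mu0, sigma) noise on a log-intensity-like
scale; each informative gene is assigned one "up" class whose samples
draw from Normal(mu0 + delta*sigma, sigma) instead.  This is the simplest
structure the wrapper assumes (a single axis-aligned threshold separates
the up class on each marker), mirroring tissue-specific marker genes.
Genes are independent; informative genes are interleaved at random
positions, never a prefix block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .data import ExpressionDataset

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "recovery_metrics"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    n_samples, n_genes, n_informative : problem size.
    n_classes : number of class labels (>= 2), named C0, C1, ...
    class_proportions : per-class sample fractions (default uniform);
        realised as exact largest-remainder counts so every class is
        populated even at small n.
    base_mean : background mean mu0, log2-intensity-like (cosmetic).
    noise_sd : within-class standard deviation sigma (> 0).
    effect_size : shift delta of an informative gene's up class, in sigma
        units (default 3.0, a strong marker).
    seed : generator seed; identical specs yield identical matrices.
    """

    n_samples: int = 60
    n_genes: int = 100
    n_informative: int = 5
    n_classes: int = 2
    class_proportions: Optional[Sequence[float]] = None
    base_mean: float = 8.0
    noise_sd: float = 1.0
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.size != self.n_classes or not np.isclose(p.sum(), 1.0):
                raise ValueError("class_proportions must sum to 1, one per class")


@dataclass
class SyntheticDataset:
    dataset: ExpressionDataset
    informative_indices: np.ndarray  # sorted gene indices carrying signal
    assignments: Dict[int, str]  # informative gene index -> up class
    spec: SyntheticSpec

    @property
    def truth_mask(self) -> np.ndarray:
        mask = np.zeros(self.dataset.n_genes, dtype=np.int8)
        mask[self.informative_indices] = 1
        return mask


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    p = (
        np.full(spec.n_classes, 1.0 / spec.n_classes)
        if spec.class_proportions is None
        else np.asarray(spec.class_proportions, dtype=float)
    )
    raw = p * spec.n_samples
    counts = np.floor(raw).astype(int)
    # largest remainders take the leftover samples
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(spec.n_samples - counts.sum()):
        counts[order[i % spec.n_classes]] += 1
    return counts


def generate(spec: SyntheticSpec, rng=None) -> SyntheticDataset:
    """Draw one dataset from the spec; deterministic given the seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    class_names = [f"C{i}" for i in range(spec.n_classes)]
    counts = _class_counts(spec)
    labels = np.repeat(np.array(class_names, dtype=object), counts)
    labels = labels[rng.permutation(spec.n_samples)]

    values = rng.normal(spec.base_mean, spec.noise_sd, (spec.n_samples, spec.n_genes))
    informative = np.sort(rng.choice(spec.n_genes, spec.n_informative, replace=False))
    assignments: Dict[int, str] = {}
    for j, g in enumerate(informative):
        up = class_names[j % spec.n_classes]  # cycle so each class gets markers
        assignments[int(g)] = up
        values[labels == up, g] += spec.effect_size * spec.noise_sd

    dataset = ExpressionDataset(
        values=values,
        gene_names=np.array([f"G{i + 1:06d}" for i in range(spec.n_genes)], dtype=object),
        sample_ids=np.array([f"S{i + 1:04d}" for i in range(spec.n_samples)], dtype=object),
        labels=labels,
    )
    return SyntheticDataset(
        dataset=dataset,
        informative_indices=informative.astype(np.intp),
        assignments=assignments,
        spec=spec,
    )


def recovery_metrics(selected, truth) -> tuple[float, float]:
    """Recall and precision of informative-gene recovery.

    ``selected`` may be a SelectionResult (its union mask), a
    GeneFrequencyTable (its frequent gene names), a boolean/0-1 mask, or
    a collection of gene indices; ``truth`` a SyntheticDataset, a mask,
    or an index collection.  A frequency table is matched by gene name,
    which requires ``truth`` to be a SyntheticDataset.  Empty selections
    score (0, 0).
    """
    from .selection import GeneFrequencyTable, SelectionResult

    if isinstance(selected, GeneFrequencyTable):
        if not isinstance(truth, SyntheticDataset):
            raise ValueError(
                "frequency-table recovery needs a SyntheticDataset truth"
            )
        sel = set(map(str, selected.frequent_genes()))
        tru = set(map(str, truth.dataset.gene_names[truth.informative_indices]))
    else:
        if isinstance(selected, SelectionResult):
            sel = set(np.nonzero(selected.union_mask)[0].tolist())
        else:
            sel = _index_set(selected)
        if isinstance(truth, SyntheticDataset):
            tru = set(int(i) for i in truth.informative_indices)
        else:
            tru = _index_set(truth)
    if not tru:
        raise ValueError("truth set is empty")
    if not sel:
        return 0.0, 0.0
    hit = len(sel & tru)
    return hit / len(tru), hit / len(sel)


def _index_set(obj) -> set:
    """Interpret a 0/1 (or boolean) mask as its support, anything else as
    a collection of indices."""
    arr = np.asarray(obj)
    if arr.dtype == bool:
        return set(np.nonzero(arr)[0].tolist())
    values = set(np.unique(arr).tolist()) if arr.size else set()
    if arr.size > 0 and values <= {0, 1} and arr.size > 2:
        return set(np.nonzero(arr)[0].tolist())
    return set(int(i) for i in arr.ravel())
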