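"""Expression-matrix I/O and run-report writers.

The in-memory container is :class:`ExpressionDataset`: a samples x genes
matrix of continuous expression values (log- or linear-scale intensities)
with ordered gene names, sample identifiers and one class label per sample.
All downstream modules (tree induction, swarm search, the selection
harness) consume this type.

File dialect: plain delimited text with a single header row; the first
column holds sample identifiers, one configurable column holds the class
label (default ``"class"``) and every other column is a gene.  A
genes-in-rows table is transposed on load so samples are always rows.
Missing or blank expression cells are a hard error — imputation is out of
scope and rejection keeps the classifier contract clean.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression_table",
    "write_expression_table",
    "subset_genes",
    "write_selection_report",
]

# 17 significant digits round-trips IEEE doubles exactly through text.
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ExpressionDataset:
    """Samples x genes expression matrix with per-sample class labels.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Continuous expression values; no missing entries allowed.
    gene_names : ndarray of str
        Ordered, duplicate-free gene (probe set) identifiers.
    sample_ids : ndarray of str
        Ordered sample identifiers, one per row.
    labels : ndarray of str
        Class label per sample.
    """

    values: np.ndarray
    gene_names: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        gene_names = np.asarray(self.gene_names, dtype=object)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        labels = np.asarray(self.labels, dtype=object)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        if values.shape[0] != labels.shape[0] or values.shape[0] != sample_ids.shape[0]:
            raise ValueError(
                f"row count {values.shape[0]} does not match "
                f"{labels.shape[0]} labels / {sample_ids.shape[0]} sample ids"
            )
        if values.shape[1] != gene_names.shape[0]:
            raise ValueError(
                f"column count {values.shape[1]} does not match "
                f"{gene_names.shape[0]} gene names"
            )
        counts: dict = {}
        for g in gene_names:
            counts[g] = counts.get(g, 0) + 1
        dups = sorted(str(g) for g, c in counts.items() if c > 1)
        if dups:
            raise ValueError(f"duplicate gene names: {', '.join(dups)}")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", gene_names)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct labels in sorted order (the canonical label ordering)."""
        return np.array(sorted(set(self.labels)), dtype=object)

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes into :attr:`classes`."""
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[l] for l in self.labels], dtype=np.intp)

    def take_samples(self, indices: np.ndarray) -> "ExpressionDataset":
        """Row subset (e.g. a CV fold) preserving order of ``indices``."""
        idx = np.asarray(indices)
        return ExpressionDataset(
            values=self.values[idx],
            gene_names=self.gene_names,
            sample_ids=self.sample_ids[idx],
            labels=self.labels[idx],
        )


def read_expression_table(
    path: str | os.PathLike,
    delimiter: str = "\t",
    label_column: str = "class",
    orientation: str = "samples",
) -> ExpressionDataset:
    """Load a delimited expression table.

    Parameters
    ----------
    path : path
        Delimited text file with one header row; first column is the
        sample id (or gene name when ``orientation="genes"``).
    delimiter : str
        Field separator; tab by default, ``","`` for CSV.
    label_column : str
        Name of the class-label column (a label *row* of that name when
        the file is genes-in-rows).
    orientation : {"samples", "genes"}
        ``"samples"``: rows are samples. ``"genes"``: rows are genes and
        the table is transposed on load.

    Raises
    ------
    ValueError
        On duplicate gene names, missing/blank expression cells (reported
        with row/column coordinates) or an absent label column.
    """
    if orientation not in ("samples", "genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "samples":
        # pandas silently renames duplicate header fields; inspect raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(delimiter)
        tokens = [t for t in header[1:] if t != label_column]
        counts: dict = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        dups = sorted(t for t, c in counts.items() if c > 1)
        if dups:
            raise ValueError(f"duplicate gene names: {', '.join(dups)}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if orientation == "genes":
        frame = frame.T
    if label_column not in frame.columns:
        raise ValueError(
            f"label column {label_column!r} not found "
            f"(columns present: {', '.join(map(str, frame.columns[:10]))}...)"
        )
    labels = frame[label_column].to_numpy(dtype=object)
    if pd.isna(labels).any():
        bad = frame.index[pd.isna(frame[label_column])][0]
        raise ValueError(f"blank class label for sample {bad!r}")
    expr = frame.drop(columns=[label_column])
    gene_names = expr.columns.to_numpy(dtype=object)
    counts: dict = {}
    for g in gene_names:
        counts[g] = counts.get(g, 0) + 1
    dups = sorted(str(g) for g, c in counts.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate gene names: {', '.join(dups)}")
    # numpy's string->float conversion round-trips exactly (pandas'
    # to_numeric fast path does not)
    values = np.empty(expr.shape, dtype=float)
    for c in range(expr.shape[1]):
        col = expr.iloc[:, c].to_numpy(dtype=object)
        try:
            values[:, c] = col.astype(float)
        except (ValueError, TypeError):
            for r, cell in enumerate(col):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"missing or non-numeric expression value at sample "
                        f"{expr.index[r]!r}, gene {expr.columns[c]!r}"
                    ) from None
            raise
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing or non-numeric expression value at sample "
            f"{expr.index[r]!r}, gene {expr.columns[c]!r}"
        )
    return ExpressionDataset(
        values=values,
        gene_names=gene_names,
        sample_ids=expr.index.to_numpy(dtype=object),
        labels=labels,
    )


def write_expression_table(
    dataset: ExpressionDataset,
    path: str | os.PathLike,
    delimiter: str = "\t",
    label_column: str = "class",
) -> None:
    """Write a dataset as delimited text; exact float round-trip."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(["sample", label_column, *map(str, dataset.gene_names)]))
        fh.write("\n")
        for i in range(dataset.n_samples):
            cells = [str(dataset.sample_ids[i]), str(dataset.labels[i])]
            cells.extend(_FLOAT_FMT % v for v in dataset.values[i])
            fh.write(delimiter.join(cells))
            fh.write("\n")


def subset_genes(dataset: ExpressionDataset, mask: np.ndarray) -> ExpressionDataset:
    """Restrict a dataset to the genes where ``mask`` is 1.

    Column order is preserved; labels and samples are untouched.  An
    all-zero mask yields a zero-gene dataset (the selection harness gives
    such masks baseline fitness rather than erroring).
    """
    mask = np.asarray(mask)
    if mask.shape != (dataset.n_genes,):
        raise ValueError(
            f"mask length {mask.shape} does not match {dataset.n_genes} genes"
        )
    keep = mask.astype(bool)
    return ExpressionDataset(
        values=dataset.values[:, keep],
        gene_names=dataset.gene_names[keep],
        sample_ids=dataset.sample_ids,
        labels=dataset.labels,
    )


def write_selection_report(result, summary, path: str | os.PathLike) -> list:
    """Write run reports for a repeated-runs experiment.

    Produces, under directory ``path``:

    ``runs.tsv``
        One row per run (index, accuracy %, number of selected genes)
        followed by ``Avg.`` and ``(Std.)`` footer rows.
    ``gene_frequency.tsv``
        Per-gene selection frequency across all outer folds of all runs,
        with the "frequent" flag.
    ``best_tree.txt``
        The reporting tree of the best run, as indented text.

    Parameters
    ----------
    result : SelectionResult
        The best single run (its reporting tree is exported).
    summary : RunSummary
        Aggregate over all runs.
    path : path
        Output directory; created if absent.

    Returns
    -------
    list of str
        Paths of the files written.
    """
    from .selection import gene_selection_frequency
    from .tree import format_tree

    if summary is None or not summary.runs:
        raise ValueError("empty run summary: nothing to report")
    os.makedirs(path, exist_ok=True)
    written = []

    runs_path = os.path.join(path, "runs.tsv")
    with open(runs_path, "w") as fh:
        fh.write("run\taccuracy_pct\tn_selected_genes\n")
        for rec in summary.runs:
            fh.write(f"{rec.run}\t{rec.accuracy_pct:.2f}\t{rec.n_selected}\n")
        fh.write(f"Avg.\t{summary.mean_accuracy_pct:.2f}\t{summary.mean_n_selected:.2f}\n")
        fh.write(f"(Std.)\t({summary.std_accuracy_pct:.2f})\t({summary.std_n_selected:.2f})\n")
    written.append(runs_path)

    freq = gene_selection_frequency(summary.results)
    freq_path = os.path.join(path, "gene_frequency.tsv")
    freq.table.to_csv(freq_path, sep="\t", index=False)
    written.append(freq_path)

    if result.final_tree is not None:
        tree_path = os.path.join(path, "best_tree.txt")
        with open(tree_path, "w") as fh:
            fh.write(format_tree(result.final_tree, result.gene_names))
            fh.write("\n")
        written.append(tree_path)
    return written
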