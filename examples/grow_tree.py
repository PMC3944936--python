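"""Grow and print a C4.5 tree on a tiny hand-made expression matrix.

A single gene (gA) separates the two classes; the tree should find its
midpoint threshold and fit the data exactly.
"""

import numpy as np

from psodt import C45Params, ExpressionDataset, classification_accuracy, format_tree, grow_tree

dataset = ExpressionDataset(
    values=np.array([[1.2, 5.0], [1.9, 5.1], [3.4, 4.9], [4.1, 5.2]]),
    gene_names=np.array(["gA", "gB"], dtype=object),
    sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
    labels=np.array(["normal", "normal", "tumor", "tumor"], dtype=object),
)

tree = grow_tree(dataset, C45Params(min_samples_leaf=1))
print(format_tree(tree, dataset.gene_names))
print(f"training accuracy: {classification_accuracy(tree, dataset):.2f}")
# The split threshold is the midpoint between the highest "normal" and
# lowest "tumor" value of gA; both leaves are pure, so accuracy is 1.00.
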