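"""Confusion matrices and variation-of-information distances between partitions.

The two partitions may cover different (overlapping) node sets, as happens
when comparing community structure across course weeks: the comparison is
restricted to the common nodes ("reduced groupings") before building the
confusion matrix.  VI is reported in bits and is a metric bounded by
log2(n) on n overlapping nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapeq import Partition

__all__ = ["ConfusionMatrix", "confusion_matrix", "variation_of_information", "vi_upper_bound"]


def _plogp(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * np.log2(x[mask])
    return out


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-tabulation N_kl of overlapping nodes shared between module k of
    partition X and module l of partition Y.  Modules with no overlapping
    nodes are retained as all-zero rows/columns."""

    table: pd.DataFrame  # rows: X modules, columns: Y modules
    n_overlap: int

    @property
    def matrix(self) -> np.ndarray:
        return self.table.to_numpy()


def confusion_matrix(px: Partition, py: Partition) -> ConfusionMatrix:
    overlap = px.nodes & py.nodes
    if not overlap:
        raise ValueError("partitions share no nodes")
    nodes = sorted(overlap)
    rows = pd.Categorical([px.label_of(n) for n in nodes], categories=sorted(px.communities()))
    cols = pd.Categorical([py.label_of(n) for n in nodes], categories=sorted(py.communities()))
    table = pd.crosstab(rows, cols, dropna=False)
    table.index.name = "X"
    table.columns.name = "Y"
    return ConfusionMatrix(table=table, n_overlap=len(nodes))


def variation_of_information(px: Partition, py: Partition) -> float:
    """VI(X, Y) = H(X) + H(Y) - 2 I(X; Y) in bits, on the node overlap.

    Computed from the confusion matrix with base-2 logarithms and the
    convention 0 log 0 = 0.  Zero iff the two partitions agree on the
    overlap; at most log2(n_overlap).
    """
    cm = confusion_matrix(px, py)
    joint = cm.matrix / cm.n_overlap
    hx = -_plogp(joint.sum(axis=1)).sum()
    hy = -_plogp(joint.sum(axis=0)).sum()
    hxy = -_plogp(joint).sum()
    return float(max(2.0 * hxy - hx - hy, 0.0))


def vi_upper_bound(n_overlap: int) -> float:
    """Maximum possible VI between two partitions of n overlapping nodes."""
    if n_overlap < 1:
        raise ValueError("need at least one overlapping node")
    return float(np.log2(n_overlap))
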