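"""Per-cell annotation-confidence scores from the expression kNN graph.

A cell's label is more trustworthy when its transcriptomic neighborhood is
label-pure.  Given the symmetric weighted kNN connectivity matrix ``w_ij``
(diagonal zeroed, the same graph used for Leiden clustering) and labels
``y_i in {1..L}`` with L = 11 (the raw vocabulary minus Less10, which is
filtered out before graph construction), each cell gets

    p_il   = sum_j w_ij 1[y_j = l] / sum_j w_ij
    H_i    = -sum_l p_il ln(p_il + eps),  eps = 1e-12
    H~_i   = H_i / ln(L)
    confidence_i = 1 - H~_i      (neighborhood purity, in [0, 1])
    support_i    = p_{i, y_i}    (weighted neighbor agreement with own label)

plus the top-3 alternative labels by p and the row sum ``sum_j w_ij``
(knn_row_sum; all scores are NaN when it is zero).  A second, independent
reliability cue is per-cell RNA depth: ``log(1 + c)`` and its within-slide
rank quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .schemes import CONFIDENCE_LABELS

__all__ = [
    "KnnGraph",
    "prepare_graph",
    "neighborhood_distribution",
    "confidence_scores",
    "rna_depth",
    "EPSILON",
]

EPSILON = 1e-12


@dataclass
class KnnGraph:
    """Symmetric non-negative connectivity matrix over cells (diagonal zeroed)."""

    weights: sparse.csr_matrix
    cell_ids: tuple[str, ...]

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


def prepare_graph(weights: sparse.spmatrix, cell_ids: Sequence[str]) -> KnnGraph:
    """Validate and normalize a raw connectivity matrix: non-negative finite
    weights, diagonal set to zero before any computation."""
    w = sparse.csr_matrix(weights, copy=True).astype(float)
    if w.shape[0] != w.shape[1] or w.shape[0] != len(cell_ids):
        raise ValueError("graph must be square and match the cell list")
    if w.nnz and w.data.min() < 0:
        raise ValueError("connectivity weights must be non-negative")
    if w.nnz and not np.all(np.isfinite(w.data)):
        raise ValueError("connectivity weights must be finite")
    w.setdiag(0.0)
    w.eliminate_zeros()
    return KnnGraph(w, tuple(cell_ids))


def neighborhood_distribution(
    graph: KnnGraph,
    labels: Sequence[str],
    label_order: Sequence[str] = CONFIDENCE_LABELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Connectivity-weighted neighbor label distribution ``p`` (n x L).

    Rows with zero connectivity are returned as NaN and flagged in the second
    return value (boolean ``defined`` mask).
    """
    if len(labels) != len(graph.cell_ids):
        raise ValueError("labels must cover every graph node")
    idx = {l: k for k, l in enumerate(label_order)}
    try:
        y = np.array([idx[l] for l in labels])
    except KeyError as e:
        raise KeyError(f"label {e.args[0]!r} outside the confidence alphabet") from None
    onehot = sparse.csr_matrix(
        (np.ones(len(y)), (np.arange(len(y)), y)),
        shape=(len(y), len(label_order)),
    )
    mass = np.asarray((graph.weights @ onehot).todense())
    rs = graph.row_sums
    defined = rs > 0
    p = np.full(mass.shape, np.nan)
    p[defined] = mass[defined] / rs[defined, None]
    return p, defined


def confidence_scores(
    p: np.ndarray,
    labels: Sequence[str],
    graph: KnnGraph,
    label_order: Sequence[str] = CONFIDENCE_LABELS,
    eps: float = EPSILON,
    k_alt: int = 3,
) -> pd.DataFrame:
    """Entropy-based confidence table for every cell.

    Alternatives exclude the assigned label and break probability ties by
    ascending label-order index.  Undefined rows (zero graph support) carry
    NaN in every score column.
    """
    L = len(label_order)
    if L < 2:
        raise ValueError("need at least two labels")
    idx = {l: k for k, l in enumerate(label_order)}
    y = np.array([idx[l] for l in labels])
    defined = ~np.isnan(p).any(axis=1)

    H = np.full(len(y), np.nan)
    pd_rows = p[defined]
    H[defined] = -(pd_rows * np.log(pd_rows + eps)).sum(axis=1)
    H_norm = H / np.log(L)
    confidence = 1.0 - H_norm
    support = np.full(len(y), np.nan)
    support[defined] = p[defined, y[defined]]

    alt_labels = np.full((len(y), k_alt), None, dtype=object)
    alt_probs = np.full((len(y), k_alt), np.nan)
    for i in np.flatnonzero(defined):
        others = [(float(-p[i, l]), l) for l in range(L) if l != y[i]]
        others.sort()
        for j in range(min(k_alt, len(others))):
            alt_labels[i, j] = label_order[others[j][1]]
            alt_probs[i, j] = -others[j][0]

    table = pd.DataFrame({
        "cell_id": list(graph.cell_ids),
        "final_label": list(labels),
        "ct_entropy": H,
        "ct_entropy_norm": H_norm,
        "ct_confidence": confidence,
        "ct_support": support,
        "knn_row_sum": graph.row_sums,
    })
    for j in range(k_alt):
        table[f"ct_alt{j + 1}"] = alt_labels[:, j]
        table[f"ct_alt{j + 1}_prob"] = alt_probs[:, j]
    return table


def rna_depth(counts: Sequence[int], cell_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-cell RNA-depth table: ``log(1 + c)`` and the within-slide rank
    quantile ``(mean fractional rank - 1) / (n - 1)`` in [0, 1] (ties share
    the mean rank; a single cell gets 0.5)."""
    c = np.asarray(counts, dtype=float)
    if c.size and c.min() < 0:
        raise ValueError("counts must be non-negative")
    log1p = np.log1p(c)
    n = c.size
    if n == 1:
        quant = np.array([0.5])
    else:
        ranks = rankdata(c, method="average")
        quant = (ranks - 1.0) / (n - 1.0)
    table = pd.DataFrame({
        "rna_total_counts": c.astype(int),
        "rna_depth_log1p": log1p,
        "rna_depth_quantile": quant,
    })
    if cell_ids is not None:
        table.insert(0, "cell_id", list(cell_ids))
    return table
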