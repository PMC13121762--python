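"""Agreement analytics between alternative per-cell labelings.

Annotation can be run from nucleus RNA counts, whole-cell RNA counts, or other
strategies; these utilities quantify how much two labelings of the same cells
agree:

* exact-match concordance, ``100/N * sum 1[A_i = B_i]``, optionally after
  excluding low-information labels (e.g. Less10, or Less10 + Unknown) from
  both vectors;
* row-normalized cross-annotation confusion matrices;
* chance-adjusted partition agreement (ARI, and AMI normalized by
  ``max(H(X), H(Y))``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

__all__ = [
    "LabelingPair",
    "align_labelings",
    "concordance",
    "cross_confusion",
    "adjusted_rand",
    "adjusted_mutual_info",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelingPair:
    """Two aligned label vectors over a shared cell-id set."""

    a: np.ndarray
    b: np.ndarray
    cell_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=object)
        self.b = np.asarray(self.b, dtype=object)
        if self.a.shape != self.b.shape:
            raise ValueError("label vectors must have equal length")

    def exclude(self, labels: Sequence[str]) -> "LabelingPair":
        """Drop cells carrying any excluded label in either vector."""
        bad = set(labels)
        keep = np.array([x not in bad and y not in bad for x, y in zip(self.a, self.b)])
        ids = tuple(np.asarray(self.cell_ids, dtype=object)[keep]) if self.cell_ids else ()
        return LabelingPair(self.a[keep], self.b[keep], ids)


def align_labelings(a: Mapping[str, str], b: Mapping[str, str]) -> LabelingPair:
    """Align two per-cell label maps on their shared cell ids; cells present in
    only one labeling are dropped with a logged count."""
    shared = sorted(set(a) & set(b))
    dropped = len(set(a) ^ set(b))
    if dropped:
        logger.info("align_labelings: dropped %d cells present in only one labeling", dropped)
    return LabelingPair(
        np.array([a[c] for c in shared], dtype=object),
        np.array([b[c] for c in shared], dtype=object),
        tuple(shared),
    )


def concordance(pair: LabelingPair, exclude: Sequence[str] = ()) -> float:
    """Percentage of exact per-cell label matches (strict identity check)."""
    p = pair.exclude(exclude) if exclude else pair
    n = len(p.a)
    if n == 0:
        raise ValueError("no cells left after exclusion")
    return 100.0 * float(np.mean(p.a == p.b))


def cross_confusion(pair: LabelingPair, vocabulary: Sequence[str] | None = None,
                    normalize: str = "row") -> pd.DataFrame:
    """Confusion matrix with rows from the first labeling, columns from the
    second.  Row normalization makes rows sum to 1; zero-count rows are
    emitted as all-zero (flagged via the ``empty_rows`` attribute)."""
    if vocabulary is None:
        vocabulary = sorted(set(pair.a.tolist()) | set(pair.b.tolist()))
    vocab = list(vocabulary)
    pos = {v: i for i, v in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)))
    for x, y in zip(pair.a, pair.b):
        counts[pos[x], pos[y]] += 1
    mat = counts
    empty: list[str] = []
    if normalize == "row":
        sums = counts.sum(axis=1, keepdims=True)
        mat = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
        empty = [vocab[i] for i in np.flatnonzero(sums.ravel() == 0)]
    df = pd.DataFrame(mat, index=vocab, columns=vocab)
    df.attrs["empty_rows"] = empty
    return df


def _as_partitions(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("partitions must cover the same element set")
    if x.size < 2:
        raise ValueError("need at least two elements")
    return x, y


def adjusted_rand(x: Sequence, y: Sequence) -> float:
    """Adjusted Rand Index with the standard permutation-model expectation."""
    x, y = _as_partitions(x, y)
    return float(adjusted_rand_score(x, y))


def adjusted_mutual_info(x: Sequence, y: Sequence) -> float:
    """Adjusted Mutual Information with hypergeometric expected-MI correction,
    normalized by max(H(X), H(Y))."""
    x, y = _as_partitions(x, y)
    return float(adjusted_mutual_info_score(x, y, average_method="max"))
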