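"""Segmentation-agreement and detection metrics plus the QC filters.

The per-patch quality scores compare a label-derived mask with an independent
instance segmentation (e.g. a pretrained nucleus-segmentation model):

* Dice and Jaccard on the binary foreground;
* Panoptic Quality ``PQ = DQ x SQ`` with Hungarian instance matching on IoU
  (bPQ class-agnostic, mPQ averaged over categories);
* detection precision/recall/F1 and the matched-pair confusion matrix.

Instance matching pairs instances with ``IoU > threshold`` one-to-one while
maximizing summed IoU; at a threshold of 0.5 the matching is provably unique,
but the Hungarian solution is used for any threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "binary_overlap",
    "instance_iou_matrix",
    "match_instances",
    "brute_force_instance_match",
    "panoptic",
    "per_class_panoptic",
    "detection_prf",
    "matched_confusion",
    "patch_scores",
    "filter_patches",
    "cell_quality_scores",
]


@dataclass
class MatchResult:
    """True-positive pairs with IoUs plus unmatched instance lists."""

    tp: list[tuple[int, int, float]]    # (gt id, pred id, IoU)
    fp: list[int]                       # unmatched predicted ids
    fn: list[int]                       # unmatched ground-truth ids

    @property
    def n_tp(self) -> int:
        return len(self.tp)


def binary_overlap(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(dice, jaccard) of two binary masks; both-empty pairs score 1.0 by
    convention."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    inter = int(np.logical_and(a, b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0, 1.0
    union = sa + sb - inter
    dice = 2.0 * inter / (sa + sb)
    jac = inter / union if union else 1.0
    return dice, jac


def instance_iou_matrix(gt: np.ndarray, pred: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between positive-ID instances of two same-shape maps.

    Returns (gt_ids, pred_ids, iou) with iou shaped (len(gt_ids), len(pred_ids)).
    """
    if gt.shape != pred.shape:
        raise ValueError("instance maps must share a shape")
    g = gt.ravel()
    p = pred.ravel()
    gt_ids = np.unique(g[g > 0])
    pred_ids = np.unique(p[p > 0])
    if gt_ids.size == 0 or pred_ids.size == 0:
        return gt_ids, pred_ids, np.zeros((gt_ids.size, pred_ids.size))
    gi = np.searchsorted(gt_ids, g, side="left")
    pi = np.searchsorted(pred_ids, p, side="left")
    both = (g > 0) & (p > 0)
    inter = sparse.coo_matrix(
        (np.ones(int(both.sum())), (gi[both], pi[both])),
        shape=(gt_ids.size, pred_ids.size),
    ).toarray()
    ga = np.bincount(gi[g > 0], minlength=gt_ids.size).astype(float)
    pa = np.bincount(pi[p > 0], minlength=pred_ids.size).astype(float)
    union = ga[:, None] + pa[None, :] - inter
    return gt_ids, pred_ids, np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)


def match_instances(gt: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5) -> MatchResult:
    """Hungarian one-to-one matching of instances with IoU above threshold."""
    gt_ids, pred_ids, iou = instance_iou_matrix(gt, pred)
    admissible = iou > iou_threshold
    cost = np.where(admissible, iou, 0.0)
    tp: list[tuple[int, int, float]] = []
    if cost.size and admissible.any():
        rows, cols = linear_sum_assignment(cost, maximize=True)
        for i, j in zip(rows, cols):
            if admissible[i, j]:
                tp.append((int(gt_ids[i]), int(pred_ids[j]), float(iou[i, j])))
    matched_gt = {t[0] for t in tp}
    matched_pred = {t[1] for t in tp}
    fp = [int(i) for i in pred_ids if int(i) not in matched_pred]
    fn = [int(i) for i in gt_ids if int(i) not in matched_gt]
    return MatchResult(tp, fp, fn)


def brute_force_instance_match(gt: np.ndarray, pred: np.ndarray,
                               iou_threshold: float = 0.5) -> float:
    """Exhaustive-search oracle: best summed IoU over all one-to-one matchings
    restricted to pairs with IoU above threshold (tiny inputs only)."""
    gt_ids, pred_ids, iou = instance_iou_matrix(gt, pred)
    n, m = iou.shape
    best = 0.0
    k = min(n, m)
    for size in range(k + 1):
        for g_sub in itertools.permutations(range(n), size):
            for p_sub in itertools.combinations(range(m), size):
                total = 0.0
                ok = True
                for gi, pj in zip(g_sub, p_sub):
                    if iou[gi, pj] <= iou_threshold:
                        ok = False
                        break
                    total += iou[gi, pj]
                if ok:
                    best = max(best, total)
    return best


def panoptic(match: MatchResult) -> tuple[float, float, float]:
    """(dq, sq, pq) from a match result.

    dq = |TP| / (|TP| + |FP|/2 + |FN|/2); sq = mean IoU over TP (0 without TP);
    pq = dq * sq.  No instances on either side scores (1, 1, 1) by convention.
    """
    ntp, nfp, nfn = len(match.tp), len(match.fp), len(match.fn)
    if ntp == 0 and nfp == 0 and nfn == 0:
        return 1.0, 1.0, 1.0
    denom = ntp + 0.5 * nfp + 0.5 * nfn
    dq = ntp / denom if denom else 0.0
    sq = float(np.mean([t[2] for t in match.tp])) if ntp else 0.0
    return dq, sq, dq * sq


def _restrict(inst: np.ndarray, types: np.ndarray, cat: int) -> np.ndarray:
    return np.where(types == cat, inst, 0)


def per_class_panoptic(
    gt_inst: np.ndarray,
    gt_types: np.ndarray,
    pred_inst: np.ndarray,
    pred_types: np.ndarray,
    iou_threshold: float = 0.5,
) -> tuple[dict[int, tuple[float, float, float]], float]:
    """Per-category (dq, sq, pq) and their unweighted mean (mPQ).

    Categories are evaluated independently by masking both maps to that type;
    the mean runs over categories present in GT or prediction (absent
    categories are skipped, not zero-filled).
    """
    cats = sorted(set(np.unique(gt_types[gt_inst > 0]).tolist())
                  | set(np.unique(pred_types[pred_inst > 0]).tolist()))
    cats = [int(c) for c in cats if c > 0]
    per: dict[int, tuple[float, float, float]] = {}
    for c in cats:
        m = match_instances(_restrict(gt_inst, gt_types, c),
                            _restrict(pred_inst, pred_types, c), iou_threshold)
        per[c] = panoptic(m)
    mpq = float(np.mean([v[2] for v in per.values()])) if per else 1.0
    return per, mpq


def detection_prf(match: MatchResult) -> tuple[float, float, float]:
    """Detection precision, recall and F1 from a match result; 0/0 -> 0."""
    ntp, nfp, nfn = len(match.tp), len(match.fp), len(match.fn)
    precision = ntp / (ntp + nfp) if ntp + nfp else 0.0
    recall = ntp / (ntp + nfn) if ntp + nfn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def matched_confusion(
    gt_instance_types: Mapping[int, int],
    pred_instance_types: Mapping[int, int],
    match: MatchResult,
    n_categories: int,
) -> np.ndarray:
    """Row-normalized confusion over matched pairs, rows = true category,
    columns = predicted categories 1..C plus a trailing background column that
    absorbs unmatched (FN) ground-truth instances."""
    counts = np.zeros((n_categories, n_categories + 1))
    for g, p, _ in match.tp:
        counts[gt_instance_types[g] - 1, pred_instance_types[p] - 1] += 1
    for g in match.fn:
        counts[gt_instance_types[g] - 1, n_categories] += 1
    sums = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)


def patch_scores(gt_inst: np.ndarray, pred_inst: np.ndarray,
                 iou_threshold: float = 0.5) -> dict[str, float]:
    """Dice, Jaccard and binary PQ for one patch (class-agnostic)."""
    dice, jac = binary_overlap(gt_inst > 0, pred_inst > 0)
    dq, sq, pq = panoptic(match_instances(gt_inst, pred_inst, iou_threshold))
    return {"Dice": dice, "Jaccard": jac, "bPQ": pq, "bDQ": dq, "bSQ": sq}


def filter_patches(
    overview: pd.DataFrame,
    metric: str = "Jaccard",
    thresholds: Sequence[float] = (0.35, 0.45, 0.55),
    count_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Threshold-sensitivity summary of the patch-level QC filter.

    For each cutoff: retained patch count/fraction, retained patch-instance
    count (sum of the per-category count columns), and per-slide retention
    fractions.  Patches are retained when ``metric > threshold``.
    """
    if metric not in overview.columns:
        raise KeyError(f"metric column {metric!r} missing from overview table")
    if count_columns is None:
        reserved = {"slide_id", "file_name", "xmin", "ymin", "xmax", "ymax",
                    "Dice", "Jaccard", "bPQ", "tissue"}
        count_columns = [c for c in overview.columns if c not in reserved]
    rows = []
    total_inst = overview[list(count_columns)].to_numpy().sum() if count_columns else 0
    for thr in thresholds:
        kept = overview[overview[metric] > thr]
        row: dict[str, object] = {
            "threshold": thr,
            "retained_patches": int(len(kept)),
            "retained_fraction": len(kept) / len(overview) if len(overview) else 0.0,
            "retained_instances": int(kept[list(count_columns)].to_numpy().sum()) if count_columns else 0,
            "total_instances": int(total_inst),
        }
        if "slide_id" in overview.columns:
            per_slide = (kept.groupby("slide_id").size()
                         / overview.groupby("slide_id").size()).fillna(0.0)
            row["per_slide_retention"] = per_slide.to_dict()
        rows.append(row)
    return pd.DataFrame(rows)


def cell_quality_scores(cell_patches: Mapping[str, Sequence[int]],
                        patch_metric: Mapping[int, float]) -> pd.Series:
    """Per-cell segmentation/alignment score: the mean of the patch metric
    (typically Jaccard) over the patches the cell belongs to.  Used downstream
    with a 0.2 cutoff on Jaccard_mean."""
    out = {}
    for cid, patches in cell_patches.items():
        if not patches:
            raise ValueError(f"cell {cid} belongs to no patch")
        out[cid] = float(np.mean([patch_metric[k] for k in patches]))
    return pd.Series(out, name="jaccard_mean")
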