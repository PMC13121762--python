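"""Training-ready corpora: supervision tables, holdout splits and CV regimes.

Patch-level supervision counts *patch-level cell instances* (a cell counted
once per containing patch).  The holdout split is a 60/20/20 train/valid/test
partition performed independently within each slide, with largest-remainder
rounding so subset sizes deviate from exact fractions by less than one patch.
Cell-level cross-validation supports four regimes (cross-slide, leave-one-
tissue-out, within-tissue cross-slide, and within-slide cell-level splitting),
all applied after two global quality filters: within-slide RNA-depth quantile
>= 0.02 and per-cell mean patch Jaccard >= 0.2.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schemes import LabelScheme
from .tiling import PatchGrid, PatchMembership

__all__ = [
    "SplitSpec",
    "patch_supervision_tables",
    "make_holdout_split",
    "apply_quality_filters",
    "make_cv_splits",
]

REGIMES = ("within_slides", "cross_slides", "cross_tissues", "within_tissues")


@dataclass(frozen=True)
class SplitSpec:
    """Configuration for the cross-validation split generator."""

    regime: str
    outer_folds: int = 5
    val_folds: int = 5
    inner_val_frac: float = 0.2
    seed: int = 0
    min_rna_depth_quantile: float = 0.02
    min_cell_jaccard_mean: float = 0.2
    min_slides_per_tissue: int = 3

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if not 0.0 < self.inner_val_frac < 1.0:
            raise ValueError("inner_val_frac must lie in (0, 1)")


def patch_supervision_tables(
    membership: PatchMembership,
    labels: Mapping[str, str],
    scheme: LabelScheme,
    grid: PatchGrid,
    tissue: str = "synthetic",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cell_count, types) tables over retained patches.

    ``cell_count`` has one row per retained patch and one column per scheme
    category, counting patch-level instances in scheme category order;
    ``types`` records the tissue for each patch.
    """
    rows = []
    for k in membership.retained:
        counts = dict.fromkeys(scheme.categories, 0)
        for cid in membership.patch_cells[k]:
            counts[scheme.category(labels[cid])] += 1
        rows.append({"file_name": grid.patch_name(k), **counts})
    cell_count = pd.DataFrame(rows, columns=["file_name", *scheme.categories])
    types = pd.DataFrame({
        "file_name": [grid.patch_name(k) for k in membership.retained],
        "tissue": tissue,
    })
    return cell_count, types


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
    for i in order[:short]:
        base[int(i)] += 1
    return base


def make_holdout_split(
    patches: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    slide_column: str = "slide_id",
) -> pd.DataFrame:
    """Per-slide random 60/20/20 split; every slide with >= 3 patches
    contributes to all three subsets.  Deterministic given the seed."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    out = patches.copy()
    out["subset"] = ""
    for slide, idx in patches.groupby(slide_column).groups.items():
        idx = np.asarray(sorted(idx))
        n = len(idx)
        if n < 3:
            import warnings
            warnings.warn(f"slide {slide}: only {n} patches; degenerate split assigns all to train")
            out.loc[idx, "subset"] = "train"
            continue
        sizes = _largest_remainder(n, fractions)
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=object)
        labels[perm[: sizes[0]]] = "train"
        labels[perm[sizes[0]: sizes[0] + sizes[1]]] = "valid"
        labels[perm[sizes[0] + sizes[1]:]] = "test"
        out.loc[idx, "subset"] = labels
    return out


def apply_quality_filters(cells: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Drop low-RNA and low-segmentation-quality cells, identically for every
    fold and before any splitting."""
    required = {"rna_depth_quantile", "jaccard_mean"}
    missing = required - set(cells.columns)
    if missing:
        raise KeyError(f"missing columns for quality filtering: {sorted(missing)}")
    keep = (cells["rna_depth_quantile"] >= spec.min_rna_depth_quantile) & (
        cells["jaccard_mean"] >= spec.min_cell_jaccard_mean
    )
    return cells.loc[keep].reset_index(drop=True)


def _tissue_seed(global_seed: int, tissue: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{tissue}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _kfold_groups(groups: list, k: int, rng: np.random.Generator) -> list[list]:
    perm = list(rng.permutation(np.array(sorted(groups), dtype=object)))
    return [perm[i::k] for i in range(k)]


def _slide_level_folds(cells: pd.DataFrame, slides: list[str], outer_folds: int,
                       val_folds: int, rng: np.random.Generator, regime: str,
                       fold_prefix: str = "") -> list[pd.DataFrame]:
    folds = _kfold_groups(slides, outer_folds, rng)
    out = []
    for o, test_slides in enumerate(folds):
        pool = [s for s in slides if s not in test_slides]
        inner = _kfold_groups(pool, min(val_folds, len(pool)), rng)
        val_slides = inner[o % len(inner)]  # deterministic rotation
        role = np.where(
            cells["slide_id"].isin(test_slides), "test",
            np.where(cells["slide_id"].isin(val_slides), "valid", "train"),
        )
        df = cells[["slide_id", "cell_id"]].copy()
        df["regime"] = regime
        df["fold"] = f"{fold_prefix}{o}"
        df["role"] = role
        out.append(df)
    return out


def make_cv_splits(cells: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Fold assignments for the requested regime.

    Input table needs columns cell_id, slide_id, tissue, rna_depth_quantile,
    jaccard_mean.  Output has one row per (cell, fold) with a train/valid/test
    role; held-out units never leak into train+valid at the regime's unit of
    splitting (slide, tissue or cell).
    """
    cells = apply_quality_filters(cells, spec)
    rng = np.random.default_rng(spec.seed)
    slides = sorted(cells["slide_id"].unique())

    if spec.regime == "cross_slides":
        if len(slides) < spec.outer_folds:
            raise ValueError("fewer slides than outer folds")
        parts = _slide_level_folds(cells, slides, spec.outer_folds, spec.val_folds,
                                   rng, "cross_slides")

    elif spec.regime == "cross_tissues":
        tissues = sorted(cells["tissue"].unique())
        if len(tissues) < 3:
            raise ValueError("need at least 3 tissues for leave-one-tissue-out")
        parts = []
        order = list(rng.permutation(np.array(tissues, dtype=object)))
        for o, test_tissue in enumerate(tissues):
            pool = [t for t in order if t != test_tissue]
            val_tissue = pool[o % len(pool)]
            role = np.where(
                cells["tissue"] == test_tissue, "test",
                np.where(cells["tissue"] == val_tissue, "valid", "train"),
            )
            df = cells[["slide_id", "cell_id"]].copy()
            df["regime"] = "cross_tissues"
            df["fold"] = str(o)
            df["role"] = role
            parts.append(df)

    elif spec.regime == "within_tissues":
        parts = []
        for tissue, sub in cells.groupby("tissue"):
            t_slides = sorted(sub["slide_id"].unique())
            if len(t_slides) < spec.min_slides_per_tissue:
                continue
            t_rng = np.random.default_rng(_tissue_seed(spec.seed, str(tissue)))
            k = min(spec.outer_folds, len(t_slides))
            parts.extend(_slide_level_folds(sub, t_slides, k, spec.val_folds,
                                            t_rng, "within_tissues",
                                            fold_prefix=f"{tissue}:"))
        if not parts:
            raise ValueError("no tissue meets min_slides_per_tissue")

    else:  # within_slides: cell-level K-fold per slide
        parts = []
        for slide, sub in cells.groupby("slide_id"):
            ids = sorted(sub["cell_id"])
            if len(ids) < spec.outer_folds:
                raise ValueError(f"slide {slide}: fewer cells than folds")
            folds = _kfold_groups(ids, spec.outer_folds, rng)
            for o, test_ids in enumerate(folds):
                test_set = set(test_ids)
                rest = [c for c in ids if c not in test_set]
                n_val = max(1, int(round(spec.inner_val_frac * len(rest))))
                val_set = set(rng.permutation(np.array(rest, dtype=object))[:n_val])
                role = np.array([
                    "test" if c in test_set else ("valid" if c in val_set else "train")
                    for c in sub["cell_id"]
                ])
                df = sub[["slide_id", "cell_id"]].copy()
                df["regime"] = "within_slides"
                df["fold"] = f"{slide}:{o}"
                df["role"] = role
                parts.append(df)

    return pd.concat(parts, ignore_index=True)
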