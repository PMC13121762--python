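"""Shared coordinate frame, slide-level domain types, and nucleus-cell reconciliation.

All geometry lives in a single 0-based pixel coordinate frame at the highest
magnification level (level 0, 40x): x grows rightward, y grows downward, and
boxes are half-open ``[xmin, xmax) x [ymin, ymax)`` so that tiling partitions
are unambiguous.  Lower-resolution levels (e.g. level 1 at 20x) are derived by
dividing level-0 coordinates by the level downsample; rounding happens only at
rasterization time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import shapely
from scipy.optimize import linear_sum_assignment
from shapely.geometry import Polygon
from shapely.strtree import STRtree

from .schemes import RAW_LABEL_VOCABULARY

__all__ = [
    "SlideGeometry",
    "CellRecord",
    "SlideBundle",
    "NucleusCellMatch",
    "match_nuclei_to_cells",
    "validate_bundle",
]


@dataclass(frozen=True)
class SlideGeometry:
    """Pixel dimensions of a slide plus its resolution pyramid.

    ``width_px``/``height_px`` are level-0 (40x) dimensions.  Downsamples must
    start at 1.0 and increase strictly (level 1 = 2.0 corresponds to 20x).
    """

    slide_id: str
    width_px: int
    height_px: int
    level_downsamples: tuple[float, ...] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        ds = self.level_downsamples
        if not ds or ds[0] != 1.0 or any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError("level_downsamples must be strictly increasing starting at 1.0")

    def level_shape(self, level: int) -> tuple[int, int]:
        """(width, height) in pixels at the requested pyramid level."""
        d = self.level_downsamples[level]
        return int(self.width_px / d), int(self.height_px / d)


@dataclass
class CellRecord:
    """One segmented cell: nucleus polygon (required), cell polygon (optional),
    and its total transcript count ``c`` (the library size used by the RNA-depth
    confidence metrics)."""

    cell_id: str
    nucleus_polygon: Polygon
    cell_polygon: Polygon | None = None
    transcript_count: int = 0

    def __post_init__(self) -> None:
        if not self.nucleus_polygon.is_valid or self.nucleus_polygon.area <= 0:
            raise ValueError(f"cell {self.cell_id}: nucleus polygon must be simple with positive area")
        if self.transcript_count < 0:
            raise ValueError(f"cell {self.cell_id}: transcript_count must be non-negative")


@dataclass
class SlideBundle:
    """Everything known about one slide, in one pixel frame.

    ``labels`` maps cell_id to a raw final label from the 12-value vocabulary.
    ``image`` is an optional HxWx3 uint8 raster aligned to ``geometry``.
    ``knn_graph`` is an optional symmetric sparse connectivity matrix over
    ``cell order`` (see :mod:`histolink.confidence`).
    """

    geometry: SlideGeometry
    cells: dict[str, CellRecord]
    labels: dict[str, str] = field(default_factory=dict)
    image: np.ndarray | None = None
    knn_graph: object | None = None
    tissue: str = "synthetic"

    def cell_order(self) -> list[str]:
        """Deterministic cell ordering (ascending integer code where possible,
        else lexicographic)."""
        def key(cid: str):
            try:
                return (0, int(cid), cid)
            except ValueError:
                return (1, 0, cid)
        return sorted(self.cells, key=key)


@dataclass
class NucleusCellMatch:
    """Result of nucleus-to-cell identifier reconciliation."""

    mapping: dict[str, str]            # provisional nucleus id -> cell_id
    ious: dict[str, float]             # per matched nucleus id
    unmatched_nuclei: list[str]
    unmatched_cells: list[str]


def _check_degenerate(polys: Mapping[str, Polygon], side: str) -> None:
    bad = [k for k, p in polys.items() if p.is_empty or p.area <= 0 or not p.is_valid]
    if bad:
        raise ValueError(f"degenerate {side} polygons: {sorted(bad)}")


def polygon_iou(a: Polygon, b: Polygon) -> float:
    inter = a.intersection(b).area
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def match_nuclei_to_cells(
    nuclei: Mapping[str, Polygon],
    cells: Mapping[str, Polygon],
    iou_threshold: float = 0.5,
) -> NucleusCellMatch:
    """Reconcile nucleus identifiers with cell identifiers by shape similarity.

    Upstream format conversions do not always preserve identifiers, so nuclei
    are re-keyed to cells by maximizing total polygon IoU under a one-to-one
    assignment (Hungarian algorithm on ``1 - IoU`` cost).  Pairs whose IoU
    falls below ``iou_threshold`` are reported unmatched.
    """
    if not nuclei or not cells:
        raise ValueError("both polygon sets must be non-empty")
    _check_degenerate(nuclei, "nucleus")
    _check_degenerate(cells, "cell")

    nuc_ids = sorted(nuclei)
    cell_ids = sorted(cells)
    cell_geoms = [cells[c] for c in cell_ids]
    tree = STRtree(cell_geoms)

    iou = np.zeros((len(nuc_ids), len(cell_ids)))
    for i, nid in enumerate(nuc_ids):
        npoly = nuclei[nid]
        for j in tree.query(npoly):
            iou[i, int(j)] = polygon_iou(npoly, cell_geoms[int(j)])

    rows, cols = linear_sum_assignment(iou, maximize=True)
    mapping: dict[str, str] = {}
    ious: dict[str, float] = {}
    for i, j in zip(rows, cols):
        if iou[i, j] >= iou_threshold and iou[i, j] > 0:
            mapping[nuc_ids[i]] = cell_ids[j]
            ious[nuc_ids[i]] = float(iou[i, j])
    unmatched_nuclei = [n for n in nuc_ids if n not in mapping]
    matched_cells = set(mapping.values())
    unmatched_cells = [c for c in cell_ids if c not in matched_cells]
    return NucleusCellMatch(mapping, ious, unmatched_nuclei, unmatched_cells)


def brute_force_match(
    nuclei: Mapping[str, Polygon],
    cells: Mapping[str, Polygon],
) -> tuple[float, dict[str, str]]:
    """Exhaustive-enumeration oracle for :func:`match_nuclei_to_cells`.

    Enumerates every one-to-one assignment (feasible only for a handful of
    shapes) and returns the best summed IoU with one argmax assignment.
    """
    nuc_ids = sorted(nuclei)
    cell_ids = sorted(cells)
    k = min(len(nuc_ids), len(cell_ids))
    best, best_map = -1.0, {}
    for chosen in itertools.permutations(cell_ids, k):
        total = sum(polygon_iou(nuclei[n], cells[c]) for n, c in zip(nuc_ids, chosen))
        if total > best:
            best = total
            best_map = dict(zip(nuc_ids, chosen))
    return best, best_map


def validate_bundle(bundle: SlideBundle) -> list[dict]:
    """Report-only consistency checks; the bundle is never modified.

    Returns a list of issue records with keys ``kind``, ``cell_id`` and
    ``detail``.  An empty list means the bundle is well formed.
    """
    issues: list[dict] = []
    seen: set[str] = set()
    w, h = bundle.geometry.width_px, bundle.geometry.height_px
    for cid, rec in bundle.cells.items():
        if rec.cell_id != cid:
            issues.append({"kind": "id_mismatch", "cell_id": cid,
                           "detail": f"record carries id {rec.cell_id!r}"})
        if rec.cell_id in seen:
            issues.append({"kind": "duplicate_id", "cell_id": cid, "detail": "duplicate cell_id"})
        seen.add(rec.cell_id)
        minx, miny, maxx, maxy = rec.nucleus_polygon.bounds
        if minx < 0 or miny < 0 or maxx > w or maxy > h:
            issues.append({"kind": "out_of_bounds", "cell_id": cid,
                           "detail": f"nucleus bounds {rec.nucleus_polygon.bounds} exceed {w}x{h}"})
    for cid, lab in bundle.labels.items():
        if cid not in bundle.cells:
            issues.append({"kind": "orphan_label", "cell_id": cid, "detail": "label for unknown cell"})
        if lab not in RAW_LABEL_VOCABULARY:
            issues.append({"kind": "unknown_label", "cell_id": cid, "detail": f"label {lab!r} not in vocabulary"})
    return issues


def check_duplicate_ids(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    return dups
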