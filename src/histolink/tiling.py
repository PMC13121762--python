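"""Overlapping patch grid and the patch-cell membership relation.

A slide is tiled into square ``W x W`` patches on a regular grid with overlap
``O`` (stride ``s = W - O``), the convention used to extract 256 px patches
with 64 px overlap at 40x.  Because patches overlap and nuclei may straddle
patch borders, one biological cell can contribute several *patch-level
instances*; this module keeps the two counts distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import box as shp_box

from .core import SlideBundle, SlideGeometry

__all__ = ["Box", "PatchGrid", "PatchMembership", "make_grid", "assign_cells", "instance_accounting"]


@dataclass(frozen=True)
class Box:
    """Half-open patch box ``[xmin, xmax) x [ymin, ymax)`` in level-0 pixels."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    def shapely(self):
        return shp_box(self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class PatchGrid:
    """Row-major ordered patch boxes; patch ``k`` is named "{slide_id}_{k}"."""

    slide_id: str
    patch_size: int
    overlap: int
    boxes: tuple[Box, ...]

    @property
    def stride(self) -> int:
        return self.patch_size - self.overlap

    def patch_name(self, k: int) -> str:
        return f"{self.slide_id}_{k}"


@dataclass
class PatchMembership:
    """Bidirectional patch <-> cell relation by nucleus-box intersection."""

    patch_cells: dict[int, list[str]]          # patch index -> member cell_ids
    cell_patches: dict[str, list[int]]         # cell_id -> containing patches
    retained: list[int] = field(default_factory=list)


def _origins(extent: int, W: int, s: int) -> list[int]:
    # only boxes fully inside the image; no padding, no flush-to-edge box
    return [x for x in range(0, extent - W + 1, s)]


def make_grid(geometry: SlideGeometry, patch_size: int = 256, overlap: int = 64,
              level: int = 0) -> PatchGrid:
    """Regular overlapping grid of fully-inside patch boxes, row-major order.

    Origins are ``{0, s, 2s, ...}`` with ``origin + W <= extent`` on each axis.
    The grid is a pure function of (width, height, W, O).
    """
    if not (0 <= overlap < patch_size):
        raise ValueError("require 0 <= overlap < patch_size")
    width, height = geometry.level_shape(level)
    if patch_size > min(width, height):
        raise ValueError(f"patch size {patch_size} exceeds image dimension {width}x{height}")
    s = patch_size - overlap
    boxes = [
        Box(x, y, x + patch_size, y + patch_size)
        for y in _origins(height, patch_size, s)
        for x in _origins(width, patch_size, s)
    ]
    return PatchGrid(geometry.slide_id, patch_size, overlap, tuple(boxes))


def assign_cells(bundle: SlideBundle, grid: PatchGrid, min_cells: int = 1) -> PatchMembership:
    """Patch membership by polygon-box intersection with positive area.

    Touching a box boundary only (zero-area intersection) does not count,
    consistent with half-open boxes.  Patches with fewer than ``min_cells``
    member cells are dropped from the retained list, but their membership is
    still reported.
    """
    patch_cells: dict[int, list[str]] = {k: [] for k in range(len(grid.boxes))}
    cell_patches: dict[str, list[int]] = {}
    order = bundle.cell_order()
    # row-major grid: locate candidate patches arithmetically from bounds
    s = grid.stride
    W = grid.patch_size
    nx = len({b.xmin for b in grid.boxes})
    ny = len({b.ymin for b in grid.boxes})
    for cid in order:
        poly = bundle.cells[cid].nucleus_polygon
        minx, miny, maxx, maxy = poly.bounds
        ix0 = max(0, int((minx - W) // s) )
        iy0 = max(0, int((miny - W) // s) )
        ix1 = min(nx - 1, int(maxx // s))
        iy1 = min(ny - 1, int(maxy // s))
        hits: list[int] = []
        for iy in range(iy0, iy1 + 1):
            for ix in range(ix0, ix1 + 1):
                k = iy * nx + ix
                b = grid.boxes[k]
                if minx >= b.xmax or maxx <= b.xmin or miny >= b.ymax or maxy <= b.ymin:
                    continue
                if poly.intersection(b.shapely()).area > 0:
                    hits.append(k)
        if hits:
            cell_patches[cid] = hits
            for k in hits:
                patch_cells[k].append(cid)
    retained = [k for k in range(len(grid.boxes)) if len(patch_cells[k]) >= min_cells]
    return PatchMembership(patch_cells, cell_patches, retained)


def instance_accounting(membership: PatchMembership) -> tuple[int, int]:
    """(unique_cell_count, patch_instance_count).

    The instance count sums members over patches, so overlap-band cells are
    counted once per containing patch; it is always >= the unique count.
    """
    unique = len(membership.cell_patches)
    instances = sum(len(v) for v in membership.patch_cells.values())
    return unique, instances
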