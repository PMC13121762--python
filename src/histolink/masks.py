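"""Rasterization of nucleus polygons into the three per-patch mask dialects.

For a patch box ``B_k`` and a label scheme with ``C`` foreground categories the
primary representation is the PanNuke-style tensor ``M_k`` of shape
``W x W x (C+1)``: channels ``0..C-1`` hold per-category patch-local instance
IDs (0 = no instance) and the final channel holds the per-pixel type index
(0 = background).  Two derived dialects are supported losslessly:

* instance map + type map (the HoVer-Net/CellViT input convention), with a
  joint instance numbering over all categories;
* the cell-identity mask, where each nucleus pixel stores a stable per-slide
  integer cell ID so occurrences of the same cell in different patches can be
  joined back to per-cell metadata.

Pixel membership uses the pixel-center rule: the center ``(c + 0.5, r + 0.5)``
must lie inside the polygon, with boundary-center ties counting as inside.
When two polygons claim the same pixel (nuclei should not overlap), the lower
cell_id wins and a warning is logged - determinism over arbitration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .core import SlideBundle
from .schemes import LabelScheme
from .tiling import Box

__all__ = [
    "PanNukeMask",
    "InstanceTypeMask",
    "rasterize_patch",
    "rasterize_cell_ids",
    "to_instance_type",
    "from_instance_type",
    "integer_cell_code",
]

logger = logging.getLogger(__name__)

MASK_DTYPE = np.int32  # per-slide cell counts exceed 16-bit range on real slides


@dataclass
class PanNukeMask:
    """W x W x (C+1) integer tensor; ``tensor[..., :C]`` are per-category
    instance channels, ``tensor[..., C]`` is the type channel."""

    tensor: np.ndarray

    @property
    def n_categories(self) -> int:
        return self.tensor.shape[2] - 1

    @property
    def type_map(self) -> np.ndarray:
        return self.tensor[..., -1]

    def validate(self) -> None:
        C = self.n_categories
        claimed = (self.tensor[..., :C] > 0).sum(axis=2)
        if claimed.max(initial=0) > 1:
            raise ValueError("a pixel is claimed by more than one category channel")
        for c in range(C):
            ids = np.unique(self.tensor[..., c])
            ids = ids[ids > 0]
            if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
                raise ValueError(f"instance IDs in channel {c} are not contiguous from 1")
            if not np.all(self.type_map[self.tensor[..., c] > 0] == c + 1):
                raise ValueError(f"type channel disagrees with category channel {c}")
        if not np.array_equal(claimed > 0, self.type_map > 0):
            raise ValueError("type-channel support differs from instance-channel support")


@dataclass
class InstanceTypeMask:
    """Joint ``instance_map`` (patch-local IDs over all categories) plus
    ``type_map`` (per-pixel category indices, constant per instance)."""

    instance_map: np.ndarray
    type_map: np.ndarray


def polygon_pixels(poly: Polygon, box: Box) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of patch pixels whose centers fall in the polygon closure.

    Only in-box pixels are returned (nuclei are truncated at patch borders).
    """
    W = box.width
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx - box.xmin - 0.5)))
    c1 = min(W - 1, int(np.ceil(maxx - box.xmin)))
    r0 = max(0, int(np.floor(miny - box.ymin - 0.5)))
    r1 = min(W - 1, int(np.ceil(maxy - box.ymin)))
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    xs = box.xmin + cc + 0.5
    ys = box.ymin + rr + 0.5
    # point-in-closure: intersects == covers for point vs polygon, so
    # boundary-center ties count as inside
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel()).reshape(rr.shape)
    return rr[inside].ravel(), cc[inside].ravel()


def _scaled_polygon(poly: Polygon, downsample: float) -> Polygon:
    if downsample == 1.0:
        return poly
    return shapely.transform(poly, lambda a: a / downsample)


def _member_cells(bundle: SlideBundle, box: Box, downsample: float) -> list[str]:
    b = box.shapely()
    out = []
    for cid in bundle.cell_order():
        poly = _scaled_polygon(bundle.cells[cid].nucleus_polygon, downsample)
        if poly.intersection(b).area > 0:
            out.append(cid)
    return out


def rasterize_patch(
    bundle: SlideBundle,
    box: Box,
    scheme: LabelScheme,
    members: Sequence[str] | None = None,
    level_downsample: float = 1.0,
) -> PanNukeMask:
    """Fill every nucleus polygon intersecting ``box`` into a PanNuke tensor.

    Instance counters are per category and increment in ascending cell_id
    order starting at 1, making masks byte-reproducible across runs and
    platforms.  Lower-resolution masks are produced by scaling polygon
    coordinates by the level downsample before rasterizing (not by
    downsampling full-resolution masks).
    """
    W = box.width
    C = scheme.n_categories
    tensor = np.zeros((W, W, C + 1), dtype=MASK_DTYPE)
    if members is None:
        members = _member_cells(bundle, box, level_downsample)
    counters = np.zeros(C + 1, dtype=MASK_DTYPE)
    claimed = np.zeros((W, W), dtype=bool)
    for cid in members:
        label = bundle.labels[cid]
        cat = scheme.index(label)  # raises for labels outside the scheme
        poly = _scaled_polygon(bundle.cells[cid].nucleus_polygon, level_downsample)
        rows, cols = polygon_pixels(poly, box)
        if rows.size == 0:
            continue
        free = ~claimed[rows, cols]
        if not free.all():
            logger.warning("pixel conflict in patch at (%d,%d): cell %s loses %d px",
                           box.xmin, box.ymin, cid, int((~free).sum()))
            rows, cols = rows[free], cols[free]
            if rows.size == 0:
                continue
        counters[cat] += 1
        tensor[rows, cols, cat - 1] = counters[cat]
        tensor[rows, cols, C] = cat
        claimed[rows, cols] = True
    return PanNukeMask(tensor)


_TRAILING_INT = re.compile(r"(\d+)\s*$")


def integer_cell_code(cell_id: str) -> int:
    """Stable integer code for a cell_id (the id itself if numeric, else its
    trailing digits)."""
    try:
        return int(cell_id)
    except ValueError:
        m = _TRAILING_INT.search(cell_id)
        if not m:
            raise ValueError(f"cell_id {cell_id!r} is not integer-codable")
        return int(m.group(1))


def rasterize_cell_ids(
    bundle: SlideBundle,
    box: Box,
    members: Sequence[str] | None = None,
    level_downsample: float = 1.0,
) -> np.ndarray:
    """Cell-identity mask: each nucleus pixel stores the stable per-slide
    integer cell ID (0 = background), identical for the same cell across
    overlapping patches."""
    W = box.width
    if members is None:
        members = _member_cells(bundle, box, level_downsample)
    codes = {cid: integer_cell_code(cid) for cid in members}
    if len(set(codes.values())) != len(codes):
        raise ValueError("integer cell codes collide within this patch")
    if any(v <= 0 for v in codes.values()):
        raise ValueError("integer cell codes must be positive")
    mask = np.zeros((W, W), dtype=MASK_DTYPE)
    for cid in members:
        poly = _scaled_polygon(bundle.cells[cid].nucleus_polygon, level_downsample)
        rows, cols = polygon_pixels(poly, box)
        if rows.size == 0:
            continue
        free = mask[rows, cols] == 0
        mask[rows[free], cols[free]] = codes[cid]
    return mask


def to_instance_type(mask: PanNukeMask) -> InstanceTypeMask:
    """Convert to the joint instance/type dialect.

    Joint IDs run 1..N in (category index, per-category ID) lexicographic
    order, so the conversion is deterministic.
    """
    mask.validate()
    C = mask.n_categories
    W = mask.tensor.shape[0]
    inst = np.zeros((W, W), dtype=MASK_DTYPE)
    nxt = 1
    for c in range(C):
        chan = mask.tensor[..., c]
        n = int(chan.max(initial=0))
        for local in range(1, n + 1):
            inst[chan == local] = nxt
            nxt += 1
    return InstanceTypeMask(inst, mask.type_map.copy())


def from_instance_type(maps: InstanceTypeMask, n_categories: int) -> PanNukeMask:
    """Inverse of :func:`to_instance_type` up to instance renumbering within
    each category.  Raises if any instance spans more than one type."""
    W = maps.instance_map.shape[0]
    tensor = np.zeros((W, W, n_categories + 1), dtype=MASK_DTYPE)
    counters = np.zeros(n_categories + 1, dtype=MASK_DTYPE)
    ids = np.unique(maps.instance_map)
    for iid in ids[ids > 0]:
        sel = maps.instance_map == iid
        types = np.unique(maps.type_map[sel])
        if types.size != 1:
            raise ValueError(f"instance {iid} has mixed types {types.tolist()}")
        cat = int(types[0])
        if not 1 <= cat <= n_categories:
            raise ValueError(f"instance {iid} has type {cat} outside 1..{n_categories}")
        counters[cat] += 1
        tensor[sel, cat - 1] = counters[cat]
        tensor[sel, n_categories] = cat
    out = PanNukeMask(tensor)
    out.validate()
    return out
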