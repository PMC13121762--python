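"""End-to-end orchestration used by the CLI and the acceptance machinery."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as hio
from .assembly import patch_supervision_tables
from .core import SlideBundle
from .masks import PanNukeMask, rasterize_cell_ids, rasterize_patch, to_instance_type
from .metrics import patch_scores
from .schemes import LabelScheme, build_detailed_scheme
from .tiling import PatchGrid, PatchMembership, assign_cells, make_grid

__all__ = ["PipelineResult", "run_slide_pipeline"]


@dataclass
class PipelineResult:
    grid: PatchGrid
    membership: PatchMembership
    masks: dict[str, PanNukeMask]
    cell_id_masks: dict[str, np.ndarray]
    overview: pd.DataFrame
    cell_count: pd.DataFrame
    types: pd.DataFrame
    manifest: dict | None = None


def run_slide_pipeline(
    bundle: SlideBundle,
    scheme: LabelScheme | None = None,
    patch_size: int = 256,
    overlap: int = 64,
    min_cells: int = 1,
    pred_polygons: Mapping | None = None,
    outdir: str | Path | None = None,
    write_images: bool = True,
) -> PipelineResult:
    """Tile, rasterize all three mask dialects, score QC (when an alternative
    segmentation is supplied) and optionally write the patch dataset."""
    scheme = scheme or build_detailed_scheme()
    grid = make_grid(bundle.geometry, patch_size, overlap)
    membership = assign_cells(bundle, grid, min_cells=min_cells)

    pred_membership = None
    pred_bundle = None
    if pred_polygons is not None:
        from .core import CellRecord
        pred_cells = {pid: CellRecord(pid, poly) for pid, poly in pred_polygons.items()}
        pred_bundle = SlideBundle(bundle.geometry, pred_cells)
        pred_membership = assign_cells(pred_bundle, grid, min_cells=0)

    masks: dict[str, PanNukeMask] = {}
    cell_id_masks: dict[str, np.ndarray] = {}
    metrics: dict[int, dict[str, float]] = {}
    for k in membership.retained:
        box = grid.boxes[k]
        members = membership.patch_cells[k]
        name = grid.patch_name(k)
        mask = rasterize_patch(bundle, box, scheme, members=members)
        masks[name] = mask
        cell_id_masks[name] = rasterize_cell_ids(bundle, box, members=members)
        if pred_bundle is not None:
            gt_inst = to_instance_type(mask).instance_map
            pred_mask = rasterize_cell_ids(pred_bundle, box,
                                           members=pred_membership.patch_cells[k])
            metrics[k] = patch_scores(gt_inst, pred_mask)

    overview = hio.overview_table(grid, membership, bundle.labels, scheme,
                                  metrics if metrics else None)
    cell_count, types = patch_supervision_tables(membership, bundle.labels, scheme,
                                                 grid, tissue=bundle.tissue)
    manifest = None
    if outdir is not None:
        manifest = hio.write_patch_dataset(
            bundle, grid, membership, masks, overview,
            {"cell_count": cell_count, "types": types}, outdir,
            write_images=write_images)
    return PipelineResult(grid, membership, masks, cell_id_masks, overview,
                          cell_count, types, manifest)
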