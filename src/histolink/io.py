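"""Readers and writers for the release dialects.

A slide bundle round-trips through a plain directory layout:

    <dir>/geometry.json            slide id, dimensions, downsamples, tissue
    <dir>/nucleus_boundaries.geojson   one feature per cell, property "cell_id"
    <dir>/cell_boundaries.geojson      optional
    <dir>/cells.csv                cell_id, final_label, transcript_counts
    <dir>/image.png                optional H&E raster
    <dir>/knn_graph.npz            optional sparse connectivity triplets

Masks are archived as compressed NPZ keyed "{slide_id}_{k}" (PanNuke tensors),
instance/type pairs as NPZ with "_inst"/"_type" suffixes, and predicted
instance maps as HDF5 keyed containers.  Every writer has a reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
from PIL import Image
from scipy import sparse
from shapely import from_wkt, to_wkt
from shapely.geometry import Polygon, mapping as shp_mapping, shape as shp_shape

from .confidence import prepare_graph
from .core import CellRecord, SlideBundle, SlideGeometry
from .masks import InstanceTypeMask, PanNukeMask
from .schemes import LabelScheme
from .tiling import PatchGrid, PatchMembership

__all__ = [
    "write_polygons_geojson",
    "read_polygons_geojson",
    "write_polygons_wkt",
    "read_polygons_wkt",
    "write_bundle",
    "read_slide",
    "write_mask_archive",
    "read_mask_archive",
    "write_label_archive",
    "read_label_archive",
    "write_instance_map_h5",
    "read_instance_map_h5",
    "overview_table",
    "write_patch_dataset",
]

logger = logging.getLogger(__name__)


# --- polygon interchange -----------------------------------------------------

def write_polygons_geojson(polygons: Mapping[str, Polygon], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"cell_id": cid},
         "geometry": shp_mapping(poly)}
        for cid, poly in sorted(polygons.items())
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_polygons_geojson(path: str | Path) -> dict[str, Polygon]:
    doc = json.loads(Path(path).read_text())
    out: dict[str, Polygon] = {}
    for feat in doc["features"]:
        cid = str(feat["properties"]["cell_id"])
        out[cid] = shp_shape(feat["geometry"])
    return out


def write_polygons_wkt(polygons: Mapping[str, Polygon], path: str | Path) -> None:
    df = pd.DataFrame({
        "cell_id": sorted(polygons),
        "wkt": [to_wkt(polygons[c], rounding_precision=-1) for c in sorted(polygons)],
    })
    df.to_csv(path, index=False)


def read_polygons_wkt(path: str | Path) -> dict[str, Polygon]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    return {cid: from_wkt(w) for cid, w in zip(df["cell_id"], df["wkt"])}


# --- bundle directory dialect ------------------------------------------------

def write_bundle(bundle: SlideBundle, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = bundle.geometry
    (outdir / "geometry.json").write_text(json.dumps({
        "slide_id": geom.slide_id,
        "width_px": geom.width_px,
        "height_px": geom.height_px,
        "level_downsamples": list(geom.level_downsamples),
        "tissue": bundle.tissue,
    }, indent=2))
    write_polygons_geojson({c: r.nucleus_polygon for c, r in bundle.cells.items()},
                           outdir / "nucleus_boundaries.geojson")
    cell_polys = {c: r.cell_polygon for c, r in bundle.cells.items() if r.cell_polygon is not None}
    if cell_polys:
        write_polygons_geojson(cell_polys, outdir / "cell_boundaries.geojson")
    order = bundle.cell_order()
    pd.DataFrame({
        "cell_id": order,
        "final_label": [bundle.labels.get(c, "") for c in order],
        "transcript_counts": [bundle.cells[c].transcript_count for c in order],
    }).to_csv(outdir / "cells.csv", index=False)
    if bundle.image is not None:
        Image.fromarray(bundle.image).save(outdir / "image.png")
    if bundle.knn_graph is not None:
        g = bundle.knn_graph
        coo = g.weights.tocoo()
        _write_npz_deterministic(outdir / "knn_graph.npz",
                                 {"row": coo.row, "col": coo.col,
                                  "data": coo.data, "shape": np.array(coo.shape)})
    return outdir


def read_slide(path: str | Path, dialect: str = "dir") -> SlideBundle:
    """Read a slide bundle.  Dialects: "dir" (the directory layout written by
    :func:`write_bundle`).  A SpatialData-style Zarr store is not supported and
    raises with the missing-dialect name."""
    if dialect != "dir":
        raise NotImplementedError(f"dialect {dialect!r} not supported; use 'dir'")
    path = Path(path)
    missing = [f for f in ("geometry.json", "nucleus_boundaries.geojson", "cells.csv")
               if not (path / f).exists()]
    if missing:
        raise FileNotFoundError(f"bundle at {path} is missing components: {missing}")
    meta = json.loads((path / "geometry.json").read_text())
    geometry = SlideGeometry(meta["slide_id"], meta["width_px"], meta["height_px"],
                             tuple(meta["level_downsamples"]))
    nuclei = read_polygons_geojson(path / "nucleus_boundaries.geojson")
    cell_polys: dict[str, Polygon] = {}
    if (path / "cell_boundaries.geojson").exists():
        cell_polys = read_polygons_geojson(path / "cell_boundaries.geojson")
    table = pd.read_csv(path / "cells.csv", dtype={"cell_id": str})
    cells: dict[str, CellRecord] = {}
    labels: dict[str, str] = {}
    for _, row in table.iterrows():
        cid = row["cell_id"]
        if cid not in nuclei:
            raise ValueError(f"cell {cid} has no nucleus polygon")
        cells[cid] = CellRecord(cid, nuclei[cid], cell_polys.get(cid),
                                int(row["transcript_counts"]))
        if isinstance(row["final_label"], str) and row["final_label"]:
            labels[cid] = row["final_label"]
    image = None
    if (path / "image.png").exists():
        image = np.asarray(Image.open(path / "image.png"))
    knn = None
    if (path / "knn_graph.npz").exists():
        z = np.load(path / "knn_graph.npz")
        w = sparse.coo_matrix((z["data"], (z["row"], z["col"])),
                              shape=tuple(z["shape"])).tocsr()
        knn = prepare_graph(w, list(table["cell_id"]))
    bundle = SlideBundle(geometry, cells, labels, image, knn,
                         tissue=meta.get("tissue", "unknown"))
    return bundle


# --- mask archives -----------------------------------------------------------

def _write_npz_deterministic(path: str | Path, arrays: Mapping[str, np.ndarray]) -> None:
    """np.load-compatible compressed NPZ with fixed zip timestamps, so repeated
    runs produce byte-identical archives."""
    import io as _io
    import zipfile

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.save(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def write_mask_archive(masks: Mapping[str, PanNukeMask], path: str | Path) -> None:
    _write_npz_deterministic(path, {k: m.tensor for k, m in masks.items()})


def read_mask_archive(path: str | Path) -> dict[str, PanNukeMask]:
    with np.load(path) as z:
        return {k: PanNukeMask(z[k]) for k in z.files}


def write_label_archive(maps: Mapping[str, InstanceTypeMask], path: str | Path) -> None:
    payload = {}
    for k, m in maps.items():
        payload[f"{k}_inst"] = m.instance_map
        payload[f"{k}_type"] = m.type_map
    _write_npz_deterministic(path, payload)


def read_label_archive(path: str | Path) -> dict[str, InstanceTypeMask]:
    with np.load(path) as z:
        names = sorted({k[:-5] for k in z.files if k.endswith("_inst")})
        return {n: InstanceTypeMask(z[f"{n}_inst"], z[f"{n}_type"]) for n in names}


def write_instance_map_h5(maps: Mapping[str, np.ndarray], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for k, arr in maps.items():
            f.create_dataset(k, data=arr, compression="gzip", track_times=False)


def read_instance_map_h5(path: str | Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f[k][()] for k in f}


# --- patch dataset -----------------------------------------------------------

def overview_table(
    grid: PatchGrid,
    membership: PatchMembership,
    labels: Mapping[str, str],
    scheme: LabelScheme,
    metrics: Mapping[int, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """One row per retained patch: slide_id, file_name, box coordinates, the
    QC metrics (Dice/Jaccard/bPQ, NaN when no comparison segmentation was
    supplied) and per-category patch-instance counts in scheme order."""
    rows = []
    for k in membership.retained:
        b = grid.boxes[k]
        counts = dict.fromkeys(scheme.categories, 0)
        for cid in membership.patch_cells[k]:
            counts[scheme.category(labels[cid])] += 1
        m = metrics.get(k, {}) if metrics else {}
        rows.append({
            "slide_id": grid.slide_id,
            "file_name": grid.patch_name(k),
            "xmin": b.xmin, "ymin": b.ymin, "xmax": b.xmax, "ymax": b.ymax,
            "Dice": m.get("Dice", np.nan),
            "Jaccard": m.get("Jaccard", np.nan),
            "bPQ": m.get("bPQ", np.nan),
            **counts,
        })
    cols = ["slide_id", "file_name", "xmin", "ymin", "xmax", "ymax",
            "Dice", "Jaccard", "bPQ", *scheme.categories]
    return pd.DataFrame(rows, columns=cols)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_patch_dataset(
    bundle: SlideBundle,
    grid: PatchGrid,
    membership: PatchMembership,
    masks: Mapping[str, PanNukeMask],
    overview: pd.DataFrame,
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    write_images: bool = True,
) -> dict:
    """Write the per-slide patch dataset and return a checksum manifest.

    A partial write leaves ``manifest.json`` marked incomplete until the last
    artifact lands.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"slide_id": grid.slide_id, "complete": False, "files": {}}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    written: list[Path] = []
    mask_path = outdir / f"masks_{grid.slide_id}.npz"
    write_mask_archive(masks, mask_path)
    written.append(mask_path)

    ov_path = outdir / "patches_overview.csv"
    overview.to_csv(ov_path, index=False)
    written.append(ov_path)

    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)

    if write_images and bundle.image is not None:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for k in membership.retained:
            b = grid.boxes[k]
            patch = bundle.image[b.ymin:b.ymax, b.xmin:b.xmax]
            p = img_dir / f"{grid.patch_name(k)}.png"
            Image.fromarray(patch).save(p)
            written.append(p)

    manifest["files"] = {str(p.relative_to(outdir)): _sha256(p) for p in written}
    manifest["n_patches"] = len(membership.retained)
    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
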