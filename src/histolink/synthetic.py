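"""Fully synthetic slides with known ground truth.

The generator fabricates everything the real readers would supply: elliptical
nucleus polygons on a jittered grid (non-overlapping by construction),
categorical labels, Poisson transcript counts from label-separable expression
profiles, a flat-colored stand-in image, an expression kNN graph, and a
perturbed alternative segmentation whose true correspondence is recorded so
detection metrics have an oracle.  Ellipses keep pixel-count oracles cheap
(closed-form areas); everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import shapely
from scipy import sparse
from shapely.geometry import Polygon
from sklearn.neighbors import NearestNeighbors

from .core import CellRecord, SlideBundle, SlideGeometry
from .confidence import KnnGraph, prepare_graph

__all__ = [
    "SyntheticSlideSpec",
    "generate_slide",
    "perturb_segmentation",
    "build_knn_fixture",
    "ellipse_polygon",
]

# realistic tumor-microenvironment proportions over the detailed categories
DEFAULT_LABEL_PROBS: dict[str, float] = {
    "Epithelial": 0.40,
    "Fibroblast_Myofibroblast": 0.20,
    "T_NK": 0.15,
    "Myeloid": 0.15,
    "Blood_vessel": 0.10,
}


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide."""

    slide_id: str = "synthetic_s0"
    width: int = 1024
    height: int = 1024
    n_cells: int = 600
    radius_range: tuple[float, float] = (4.0, 8.0)
    label_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LABEL_PROBS))
    n_genes: int = 40
    profile_scale: float = 8.0      # mean counts per marker gene
    overdispersion: float = 0.0     # gamma-poisson mixing; 0 = pure Poisson
    jitter_frac: float = 0.25       # center jitter as a fraction of free spacing
    tissue: str = "synthetic"
    seed: int = 0


def ellipse_polygon(cx: float, cy: float, a: float, b: float, angle: float,
                    n_vertices: int = 48) -> Polygon:
    """Closed simple polygon approximating an ellipse."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    xs = cx + ca * x - sa * y
    ys = cy + sa * x + ca * y
    return Polygon(np.column_stack([xs, ys]))


def _category_profiles(categories: list[str], n_genes: int, scale: float,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Well-separated mean expression profiles: each category gets an exclusive
    marker block at high mean plus a small shared baseline."""
    K = len(categories)
    block = max(1, n_genes // K)
    profiles = {}
    for k, cat in enumerate(categories):
        mu = np.full(n_genes, 0.2)
        lo = k * block
        mu[lo: min(n_genes, lo + block)] = scale
        profiles[cat] = mu
    return profiles


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideBundle, dict]:
    """Generate a :class:`SlideBundle` plus a ground-truth record.

    Nuclei are ellipses centered on a jittered grid whose spacing guarantees
    pairwise non-overlap; labels are drawn from ``label_probs``; per-cell
    counts are Poisson draws from the category profile so a label-separable
    expression space exists.  The image is a flat background with darker
    nucleus interiors, sufficient for patch-extraction plumbing.
    """
    rng = np.random.default_rng(spec.seed)
    rmin, rmax = spec.radius_range
    if not 0 < rmin <= rmax:
        raise ValueError("invalid radius range")

    # grid spacing 2*rmax + margin; per-axis jitter < margin/2 keeps every
    # center pair farther apart than 2*rmax, so nuclei cannot overlap
    margin = 4.0
    spacing = 2.0 * rmax + margin
    jitter = min(spec.jitter_frac * margin, margin / 2.0) * 0.98
    xs = np.arange(spacing / 2 + rmax, spec.width - spacing / 2 - rmax, spacing)
    ys = np.arange(spacing / 2 + rmax, spec.height - spacing / 2 - rmax, spacing)
    sites = [(x, y) for y in ys for x in xs]
    if spec.n_cells > len(sites):
        raise ValueError(f"infeasible density: {spec.n_cells} cells but only {len(sites)} sites")
    chosen = rng.choice(len(sites), size=spec.n_cells, replace=False)
    chosen.sort()

    categories = list(spec.label_probs)
    probs = np.array([spec.label_probs[c] for c in categories], dtype=float)
    probs = probs / probs.sum()
    profiles = _category_profiles(categories, spec.n_genes, spec.profile_scale, rng)

    cells: dict[str, CellRecord] = {}
    labels: dict[str, str] = {}
    counts = np.zeros((spec.n_cells, spec.n_genes), dtype=np.int64)
    truth_rows = []
    for i, si in enumerate(chosen):
        cx, cy = sites[si]
        cx += rng.uniform(-jitter, jitter)
        cy += rng.uniform(-jitter, jitter)
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, a)
        angle = rng.uniform(0, np.pi)
        label = categories[rng.choice(len(categories), p=probs)]
        mu = profiles[label]
        if spec.overdispersion > 0:
            lam = mu * rng.gamma(1.0 / spec.overdispersion, spec.overdispersion, size=mu.shape)
        else:
            lam = mu
        row = rng.poisson(lam)
        cid = str(i + 1)
        cells[cid] = CellRecord(
            cell_id=cid,
            nucleus_polygon=ellipse_polygon(cx, cy, a, b, angle),
            transcript_count=int(row.sum()),
        )
        labels[cid] = label
        counts[i] = row
        truth_rows.append({"cell_id": cid, "cx": cx, "cy": cy, "a": a, "b": b,
                           "angle": angle, "label": label})

    image = np.full((spec.height, spec.width, 3), 235, dtype=np.uint8)
    for rec in cells.values():
        minx, miny, maxx, maxy = rec.nucleus_polygon.bounds
        c0, c1 = int(np.floor(minx)), int(np.ceil(maxx))
        r0, r1 = int(np.floor(miny)), int(np.ceil(maxy))
        cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = shapely.intersects_xy(rec.nucleus_polygon, cc.ravel() + 0.5, rr.ravel() + 0.5)
        image[rr.ravel()[inside], cc.ravel()[inside]] = (90, 60, 140)

    bundle = SlideBundle(
        geometry=SlideGeometry(spec.slide_id, spec.width, spec.height),
        cells=cells,
        labels=labels,
        image=image,
        tissue=spec.tissue,
    )
    truth = {
        "spec": spec,
        "cells": truth_rows,
        "counts": counts,
        "gene_names": [f"g{j}" for j in range(spec.n_genes)],
    }
    return bundle, truth


def perturb_segmentation(
    bundle: SlideBundle,
    dropout_rate: float = 0.0,
    jitter_px: float = 0.0,
    dilate_px: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, Polygon], dict[str, str | None]]:
    """Alternative segmentation with known correspondence.

    Each nucleus is independently dropped with probability ``dropout_rate``;
    retained nuclei are shifted by ``jitter_px`` in a random direction and
    dilated by ``dilate_px``.  Returns (perturbed polygons keyed by new ids,
    correspondence original cell_id -> new id or None when dropped).
    """
    if min(dropout_rate, jitter_px, dilate_px) < 0:
        raise ValueError("perturbation parameters must be >= 0")
    rng = np.random.default_rng(seed)
    polygons: dict[str, Polygon] = {}
    correspondence: dict[str, str | None] = {}
    nxt = 1
    for cid in bundle.cell_order():
        if rng.uniform() < dropout_rate:
            correspondence[cid] = None
            continue
        poly = bundle.cells[cid].nucleus_polygon
        if jitter_px > 0:
            theta = rng.uniform(0, 2 * np.pi)
            poly = shapely.transform(
                poly, lambda a: a + np.array([jitter_px * np.cos(theta),
                                              jitter_px * np.sin(theta)]))
        if dilate_px > 0:
            poly = poly.buffer(dilate_px)
        pid = str(nxt)
        nxt += 1
        polygons[pid] = poly
        correspondence[cid] = pid
    return polygons, correspondence


def build_knn_fixture(bundle: SlideBundle, truth: dict, k: int = 10) -> KnnGraph:
    """Symmetric positive-weight kNN graph on log-normalized counts.

    Emulates the expression connectivity graph the confidence formulas consume:
    library-size normalization to the median depth, log1p, Euclidean kNN,
    weights ``1 / (1 + distance)`` symmetrized by maximum, zero diagonal.
    """
    counts = np.asarray(truth["counts"], dtype=float)
    n = counts.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    depth = counts.sum(axis=1)
    target = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    norm = np.log1p(counts / np.maximum(depth, 1.0)[:, None] * target)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(norm)
    dist, idx = nn.kneighbors(norm)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()          # skip self
    weights = 1.0 / (1.0 + dist[:, 1:].ravel())
    w = sparse.coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()
    w = w.maximum(w.T)
    cell_ids = [row["cell_id"] for row in truth["cells"]]
    return prepare_graph(w, cell_ids)
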