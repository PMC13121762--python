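import numpy as np
import pytest
from shapely.geometry import Polygon

from histolink.core import CellRecord, SlideBundle, SlideGeometry
from histolink.masks import polygon_pixels
from histolink.synthetic import SyntheticSlideSpec, build_knn_fixture, generate_slide
from histolink.tiling import Box


def square(cx: float, cy: float, half: float) -> Polygon:
    return Polygon([(cx - half, cy - half), (cx + half, cy - half),
                    (cx + half, cy + half), (cx - half, cy + half)])


def slide_instance_map(polygons: dict, size: int) -> np.ndarray:
    """Rasterize polygons into a slide-level instance map with IDs 1..n in
    sorted-key order (independent pixel-center oracle path)."""
    box = Box(0, 0, size, size)
    out = np.zeros((size, size), dtype=np.int32)
    for i, key in enumerate(sorted(polygons, key=lambda k: (len(k), k)), start=1):
        rows, cols = polygon_pixels(polygons[key], box)
        free = out[rows, cols] == 0
        out[rows[free], cols[free]] = i
    return out


@pytest.fixture()
def toy_bundle() -> SlideBundle:
    """Three labelled square nuclei in a 128x128 slide."""
    cells = {
        "1": CellRecord("1", square(20, 20, 5), transcript_count=12),
        "2": CellRecord("2", square(60, 60, 6), transcript_count=40),
        "3": CellRecord("3", square(100, 30, 4), transcript_count=3),
    }
    labels = {"1": "Epithelial", "2": "T_NK", "3": "Myeloid"}
    return SlideBundle(SlideGeometry("toy_s0", 128, 128), cells, labels)


@pytest.fixture(scope="session")
def synthetic_slide():
    spec = SyntheticSlideSpec(n_cells=520, width=1024, height=1024, seed=7)
    bundle, truth = generate_slide(spec)
    return bundle, truth


@pytest.fixture(scope="session")
def synthetic_graph(synthetic_slide):
    bundle, truth = synthetic_slide
    return build_knn_fixture(bundle, truth, k=10)
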