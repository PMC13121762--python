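"""Label vocabularies, harmonization/grouping maps and loss class weights.

Cell-type annotation produces one of 12 raw "final" labels per cell.  Masks and
training corpora use coarser schemes obtained through a deterministic mapping
``g: final_label -> {1..C}`` with index 0 reserved for background:

* ``harmonized10`` - the 10 curated categories (Unknown, Stem_like and Less10
  collapsed into Other);
* ``detailed9`` - the 9 foreground mask categories (Glioblastoma slides are
  excluded before patching, so the label is inadmissible here);
* ``grouped5`` - 5 broad classes for easier morphology-only prediction
  (Immune = T_NK + B_Plasma + Myeloid; Stromal = Blood_vessel +
  Fibroblast_Myofibroblast; Other additionally absorbs Specialized).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "RAW_LABEL_VOCABULARY",
    "CONFIDENCE_LABELS",
    "LabelScheme",
    "ClassWeights",
    "harmonize",
    "build_harmonized_scheme",
    "build_detailed_scheme",
    "build_grouped_scheme",
    "class_weights",
]

RAW_LABEL_VOCABULARY: tuple[str, ...] = (
    "Epithelial",
    "Blood_vessel",
    "Fibroblast_Myofibroblast",
    "Myeloid",
    "B_Plasma",
    "T_NK",
    "Melanocyte",
    "Glioblastoma",
    "Specialized",
    "Stem_like",
    "Unknown",
    "Less10",
)

# Cells with fewer than 10 transcripts (Less10) are filtered out before the
# expression kNN graph is built, so the confidence module works over an
# 11-label alphabet.
CONFIDENCE_LABELS: tuple[str, ...] = tuple(l for l in RAW_LABEL_VOCABULARY if l != "Less10")

_OTHER_SOURCES = ("Unknown", "Stem_like", "Less10")

_DEFAULT_COLORS = {
    "Epithelial": "#d62728",
    "Blood_vessel": "#1f77b4",
    "Fibroblast_Myofibroblast": "#2ca02c",
    "Myeloid": "#ff7f0e",
    "B_Plasma": "#9467bd",
    "T_NK": "#e377c2",
    "Melanocyte": "#8c564b",
    "Glioblastoma": "#17becf",
    "Specialized": "#bcbd22",
    "Immune": "#ff7f0e",
    "Stromal": "#2ca02c",
    "Other": "#7f7f7f",
}


@dataclass(frozen=True)
class LabelScheme:
    """Ordered mapping from raw final labels to mask category indices.

    Index 0 is background; foreground categories are 1..C in ``categories``
    order.  ``mapping`` is total over its admissible raw labels and raises
    (never silently drops) for anything else.
    """

    name: str
    categories: tuple[str, ...]           # foreground, index 1..C
    mapping: Mapping[str, str]            # raw label -> category name
    colors: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def index(self, raw_label: str) -> int:
        """Category index ``g(raw_label)`` in 1..C."""
        return self.categories.index(self.category(raw_label)) + 1

    def category(self, raw_label: str) -> str:
        if raw_label not in RAW_LABEL_VOCABULARY:
            raise KeyError(f"label {raw_label!r} is not in the raw vocabulary")
        try:
            return self.mapping[raw_label]
        except KeyError:
            raise KeyError(f"label {raw_label!r} is not admissible under scheme {self.name!r}") from None

    # --- release side files -------------------------------------------------
    def label2cat(self) -> dict[str, str]:
        return dict(self.mapping)

    def cat2idx(self) -> dict[str, int]:
        return {c: i + 1 for i, c in enumerate(self.categories)}

    def cat2color(self) -> dict[str, str]:
        return {c: self.colors.get(c, "#000000") for c in self.categories}

    def write_side_files(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, payload in (
            ("label2cat.json", self.label2cat()),
            ("cat2idx.json", self.cat2idx()),
            ("cat2color.json", self.cat2color()),
        ):
            p = outdir / name
            p.write_text(json.dumps(payload, indent=2))
            written.append(p)
        return written


def harmonize(raw_label: str) -> str:
    """Collapse the low-information labels (Unknown, Stem_like, Less10) into
    Other; every other raw label maps to itself."""
    if raw_label not in RAW_LABEL_VOCABULARY:
        raise KeyError(f"label {raw_label!r} is not in the raw vocabulary")
    return "Other" if raw_label in _OTHER_SOURCES else raw_label


def build_harmonized_scheme() -> LabelScheme:
    """The 10-category harmonized scheme used for slide-level annotation."""
    cats = tuple(l for l in RAW_LABEL_VOCABULARY if l not in _OTHER_SOURCES) + ("Other",)
    mapping = {l: harmonize(l) for l in RAW_LABEL_VOCABULARY}
    return LabelScheme("harmonized10", cats, mapping, _DEFAULT_COLORS)


def build_detailed_scheme() -> LabelScheme:
    """The C = 9 foreground mask scheme.

    Glioblastoma is absent: slides carrying it are excluded before patch
    extraction, so the label is inadmissible and raises.
    """
    cats = (
        "Epithelial",
        "Blood_vessel",
        "Fibroblast_Myofibroblast",
        "Myeloid",
        "B_Plasma",
        "T_NK",
        "Melanocyte",
        "Specialized",
        "Other",
    )
    mapping = {l: harmonize(l) for l in RAW_LABEL_VOCABULARY if l != "Glioblastoma"}
    return LabelScheme("detailed9", cats, mapping, _DEFAULT_COLORS)


_GROUPS = {
    "T_NK": "Immune",
    "B_Plasma": "Immune",
    "Myeloid": "Immune",
    "Blood_vessel": "Stromal",
    "Fibroblast_Myofibroblast": "Stromal",
    "Epithelial": "Epithelial",
    "Melanocyte": "Melanocyte",
    "Specialized": "Other",
    "Other": "Other",
}


def build_grouped_scheme() -> LabelScheme:
    """The C = 5 broad-class scheme used for the easier prediction target."""
    cats = ("Immune", "Stromal", "Epithelial", "Melanocyte", "Other")
    mapping = {l: _GROUPS[harmonize(l)]
               for l in RAW_LABEL_VOCABULARY if l != "Glioblastoma"}
    return LabelScheme("grouped5", cats, mapping, _DEFAULT_COLORS)


def group_detailed_category(category: str) -> str:
    """Map a detailed9 category name to its grouped5 category (composes with
    :func:`harmonize`)."""
    return _GROUPS[category]


@dataclass(frozen=True)
class ClassWeights:
    """Per-category loss weights ``w_c = ln(1 + 1/freq_c)``.

    ``background`` equals the weight of the most frequent category.  The Other
    category is additionally downweighted: 0.1 absolute in BCE/Dice contexts,
    and 0.1 times the most-prevalent class's weight in the focal-Tversky
    context.
    """

    frequencies: Mapping[str, float]
    weights: Mapping[str, float]
    background: float
    other_bce_dice: float
    other_focal_tversky: float


def class_weights(counts: Mapping[str, int], scheme: LabelScheme) -> ClassWeights:
    """Compute loss class weights from per-category training-corpus counts.

    Frequencies are taken over foreground categories only; natural log is used
    (any fixed base rescales all weights uniformly).
    """
    arr = {c: int(counts.get(c, 0)) for c in scheme.categories}
    if any(v < 0 for v in arr.values()):
        raise ValueError("counts must be non-negative")
    total = sum(arr.values())
    if total == 0:
        raise ValueError("at least one category count must be positive")
    freq = {c: v / total for c, v in arr.items()}
    weights = {c: math.log1p(1.0 / f) if f > 0 else math.inf for c, f in freq.items()}
    most_common = max(freq, key=lambda c: freq[c])
    return ClassWeights(
        frequencies=freq,
        weights=weights,
        background=weights[most_common],
        other_bce_dice=0.1,
        other_focal_tversky=0.1 * weights[most_common],
    )
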