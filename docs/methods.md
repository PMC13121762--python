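# Methods

This note records the conventions, defaults and open design choices behind
`histolink`. It documents what the code computes and why; every number quoted
here is produced by the test suite or `scripts/acceptance.py` at run time.

## Coordinate frame and tiling

All geometry lives in 0-based level-0 (40×) pixel coordinates, x rightward,
y downward. Patch boxes are half-open `[xmin, xmax) × [ymin, ymax)`; half-open
boxes make tiling partitions unambiguous and pair naturally with the
pixel-center rasterization rule. The grid uses origins `{0, s, 2s, …}` with
stride `s = W − O` and keeps only boxes fully inside the image — no padding
and no flush-to-edge box, so every patch has the same size and no resampling
is needed. A thin margin at the right/bottom edge (width `< W` beyond the last
origin) is therefore never patched; on real slides that margin is background
far more often than tissue. Lower pyramid levels (level 1 = 20×) are produced
by dividing polygon coordinates by the level downsample *before* rasterizing,
never by downsampling full-resolution masks, which would alias thin nuclei.

Patch membership is polygon–box intersection with strictly positive area;
touching a boundary line only does not count, consistent with half-open
boxes. Patches with fewer than `min_cells = 1` member cells are dropped from
the retained list (configurable); this is a stand-in for the tissue-detection
step that excludes background-only regions on real slides.

## Rasterization and mask dialects

A pixel belongs to a nucleus when its center `(c + 0.5, r + 0.5)` lies in the
polygon closure (boundary-center ties count as inside). Instance counters are
per category and increment in ascending `cell_id` order starting at 1, so
masks are byte-reproducible across platforms. Nuclei should not overlap; if
two polygons claim a pixel after upstream alignment, the lower `cell_id` wins
and a warning is logged — determinism was preferred over any area- or
distance-based arbitration. The three dialects conserve foreground exactly:
the union of instance-channel support equals the type-channel support equals
the cell-ID-mask support, a property asserted per patch in the tests.
Mask arrays are 32-bit integers because per-slide cell counts on real slides
exceed the 16-bit range. Conversion to the joint instance/type dialect
numbers instances 1..N in (category, per-category ID) lexicographic order and
is inverted exactly up to within-category renumbering.

## Nucleus–cell reconciliation

Upstream format conversions do not always preserve identifiers, so nuclei are
re-keyed to cells by shape similarity: polygon IoU, one-to-one assignment by
the Hungarian algorithm on `1 − IoU` cost, acceptance threshold IoU ≥ 0.5.
The similarity measure and threshold are this package's choice; the upstream
procedure is described only as shape-based. Degenerate (zero-area or invalid)
polygons are rejected with an itemized error. For ≤ 6 shapes per side the
assignment is verified against exhaustive enumeration of all one-to-one
assignments.

## Label schemes and class weights

The raw vocabulary has 12 final labels. Harmonization collapses Unknown,
Stem_like and Less10 (cells with fewer than 10 transcripts) into Other,
giving the 10-category scheme. The 9-category detailed mask scheme
additionally excludes Glioblastoma, whose slides are removed before patch
extraction, so that label raises rather than mapping silently. The 5-category
grouped scheme merges T_NK + B_Plasma + Myeloid into Immune and Blood_vessel
+ Fibroblast_Myofibroblast into Stromal, with Other absorbing Specialized;
grouping commutes with harmonization by construction. Loss class weights are
`w_c = ln(1 + 1/freq_c)` over foreground frequencies; natural log is fixed
because any base change rescales all weights uniformly. The background weight
equals the most frequent category's weight. Other is additionally
downweighted: 0.1 absolute in BCE/Dice contexts and 0.1 × the most prevalent
class's weight in the focal-Tversky context. The losses themselves are out of
scope; only their weight inputs are computed.

## Segmentation agreement

Dice and Jaccard are computed on binary foreground; both-empty pairs score
1.0 by convention (the comparison provides no evidence of disagreement).
Instance matching pairs instances with IoU strictly above the threshold,
one-to-one, maximizing summed IoU via the Hungarian algorithm; at threshold
0.5 the matching is provably unique, and IoU (rather than centroid distance)
was chosen as the cost for consistency with PQ. PQ follows the standard
decomposition PQ = DQ·SQ with SQ = 0 when there are no true positives, and
the no-instances-on-either-side case scores (1, 1, 1). Per-class PQ averages
over categories present in ground truth or prediction for the evaluation
unit; absent categories are skipped, not zero-filled. The matched-pair
confusion matrix is computed within class-agnostic matches, rows = true
category, with a trailing background column absorbing unmatched ground-truth
instances; rows are normalized to 1. Patch QC uses Jaccard cutoffs with
strict inequality; the per-cell quality score is the mean Jaccard over the
patches containing the cell, used downstream with a 0.2 cutoff.

## Confidence scores

The neighborhood label distribution is row-normalized connectivity mass; the
diagonal is zeroed before any computation so a cell never reinforces its own
label. Entropy uses natural log with ε = 1e−12 added inside the logarithm
only (not to the multiplier), exactly as defined; the normalizer is ln L with
L = 11 — the raw vocabulary minus Less10, because low-RNA cells are filtered
out before the expression graph is built and therefore never appear as graph
nodes. Confidence is 1 − H̃ and support is p at the assigned label; both are
invariant under uniform scaling of the weights. Alternatives are the top-3
labels excluding the assigned one, ties broken by ascending fixed label
order. Rows with zero connectivity are NaN everywhere and exposed through
`knn_row_sum` for filtering. The RNA-depth quantile is the min–max of average
fractional ranks, `(rank − 1)/(n − 1)`, ties sharing the mean rank and a
single cell scoring 0.5; the rank convention is this package's choice among
the standard ones.

## Agreement analytics

Concordance is the strict percentage of exact per-cell matches over shared
cell ids; cells present in only one labeling are dropped with a logged count.
Two exclusion variants are exposed because different comparisons exclude
different label sets (Less10 only, or Less10 + Unknown). ARI uses the
permutation-model expectation; AMI uses the hypergeometric expected-MI
correction normalized by max(H(X), H(Y)). Both are delegated to
scikit-learn and cross-checked in the tests against an explicit
pair-counting oracle and a direct evaluation of the expected-MI sum.

## Dataset assembly

Supervision tables count patch-level instances (a cell once per containing
patch), in scheme category order. The holdout split is per-slide, unstratified
uniform sampling with largest-remainder rounding, so each subset size differs
from the exact 60/20/20 fractions by less than one patch; slides with fewer
than three patches degenerate to train-only with a warning. Quality filters
(RNA-depth quantile ≥ 0.02, Jaccard mean ≥ 0.2) are applied identically
before any splitting. The four CV regimes split at the slide, tissue, or cell
level; the inner validation fold rotates deterministically across outer
folds, leave-one-tissue-out chooses a whole validation tissue by seeded
permutation, and within-tissue CV uses a tissue-specific seed derived by
stable hashing of (global seed, tissue name). No identifier leaks across test
and train+valid at the regime's unit of splitting, asserted per fold.

## Synthetic slides

The generator emulates the slide primitives the real readers would supply.
Defaults, chosen once as a realistic desk-scale stand-in: a 1024×1024 px
slide with 600 cells; five detailed categories at tumor-microenvironment-like
proportions (Epithelial 0.40, Fibroblast_Myofibroblast 0.20, T_NK 0.15,
Myeloid 0.15, Blood_vessel 0.10); nucleus radii 4–8 px; 40 genes with
block-separable mean profiles and Poisson counts (an overdispersion knob
exists but is off — Poisson keeps the parameter count minimal and suffices
for a label-separable expression space). Nuclei are ellipses (closed-form
areas make pixel-count oracles cheap) on a jittered grid whose spacing
guarantees pairwise non-overlap by construction. The image is a flat-colored
stand-in adequate for patch-extraction plumbing; it has no H&E texture,
staining variation, or artifacts. The kNN fixture normalizes counts to the
median library size, applies log1p, and builds a symmetric graph with weights
`1/(1 + distance)` over 10 Euclidean nearest neighbors.

What passing tests on this generator do show: the tiling, rasterization,
metric, confidence, agreement and splitting machinery is correct against
independent oracles, deterministic, and self-consistent across dialects.
What they do not show: robustness to real-data pathologies — misregistration
between modalities, segmentation errors, overlapping or non-convex nuclei,
batch effects across gene panels, or morphology/label mismatch. The
perturbation module (dropout, jitter, dilation with known correspondence)
probes the metric machinery's response to such errors but does not emulate
their real-world structure.

## Numerical conventions and edge cases

Empty-vs-empty comparisons score 1.0 (Dice/Jaccard) and (1,1,1) (PQ);
detection ratios return 0 on 0/0. Problem sizes in the tests and the
acceptance script (slides of 150–600 cells, 512–1024 px, 20 perturbation
seeds, 50 null-agreement draws, 200 matching toys) were chosen as the
smallest sizes at which the binomial and Monte-Carlo assertions have
comfortable margins. Mask archives are written with fixed zip timestamps and
HDF5 datasets with `track_times=False`, so repeated runs are byte-identical —
the property the determinism check asserts via checksum manifests. A
SpatialData-Zarr reader is not included; bundles round-trip through a plain
directory dialect (GeoJSON/WKT polygons, CSV tables, PNG image, NPZ graph).

## Known limitations

* The nucleus↔cell matching threshold (IoU ≥ 0.5) and the AMI normalization
  are package choices where upstream conventions are unspecified.
* `min_cells` patch retention is a proxy for image-based tissue detection.
* The generator's flat image means image-dependent QC (blur, staining) is
  untestable here by design.
* Within-slide 60/20/20 splitting is unstratified; on very small slides the
  largest-remainder rounding can leave a subset with a single patch.
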