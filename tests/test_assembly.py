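import numpy as np
import pandas as pd
import pytest

from histolink.assembly import (
    SplitSpec,
    apply_quality_filters,
    make_cv_splits,
    make_holdout_split,
    patch_supervision_tables,
)
from histolink.schemes import build_detailed_scheme
from histolink.tiling import assign_cells, make_grid


def cells_table(n_slides=5, cells_per_slide=40, tissues=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_slides):
        tissue = (tissues or [f"tissue{s % 3}"] * n_slides)[s]
        for c in range(cells_per_slide):
            rows.append({
                "cell_id": f"s{s}_c{c}",
                "slide_id": f"slide{s}",
                "tissue": tissue,
                "rna_depth_quantile": rng.uniform(),
                "jaccard_mean": rng.uniform(),
            })
    return pd.DataFrame(rows)


class TestSupervisionTables:
    def test_counts_equal_brute_force(self, synthetic_slide):
        bundle, _ = synthetic_slide
        scheme = build_detailed_scheme()
        grid = make_grid(bundle.geometry, 256, 64)
        m = assign_cells(bundle, grid)
        cell_count, types = patch_supervision_tables(m, bundle.labels, scheme, grid,
                                                     tissue=bundle.tissue)
        assert list(cell_count.columns) == ["file_name", *scheme.categories]
        # brute-force recount over all (cell, patch) pairs
        total = cell_count[list(scheme.categories)].to_numpy().sum()
        brute = sum(len(v) for k, v in m.patch_cells.items() if k in set(m.retained))
        assert total == brute
        assert (types["tissue"] == bundle.tissue).all()

    def test_overlap_cell_counted_once_per_patch(self, synthetic_slide):
        bundle, _ = synthetic_slide
        scheme = build_detailed_scheme()
        grid = make_grid(bundle.geometry, 256, 64)
        m = assign_cells(bundle, grid)
        cell_count, _ = patch_supervision_tables(m, bundle.labels, scheme, grid)
        multi = [c for c, ps in m.cell_patches.items() if len(ps) > 1]
        assert multi, "fixture should have overlap-band cells"
        cid = multi[0]
        cat = scheme.category(bundle.labels[cid])
        names = {f"{grid.slide_id}_{k}" for k in m.cell_patches[cid]}
        sub = cell_count[cell_count["file_name"].isin(names)]
        assert (sub[cat] >= 1).all()


class TestHoldoutSplit:
    def test_ten_patches_split_six_two_two(self):
        df = pd.DataFrame({"slide_id": ["s"] * 10, "file_name": [f"s_{i}" for i in range(10)]})
        out = make_holdout_split(df, seed=1)
        sizes = out["subset"].value_counts()
        assert sizes["train"] == 6 and sizes["valid"] == 2 and sizes["test"] == 2

    def test_deterministic_and_partition(self):
        df = pd.DataFrame({"slide_id": np.repeat(["a", "b"], 17),
                           "file_name": [f"p{i}" for i in range(34)]})
        o1 = make_holdout_split(df, seed=5)
        o2 = make_holdout_split(df, seed=5)
        pd.testing.assert_frame_equal(o1, o2)
        assert set(o1["subset"]) == {"train", "valid", "test"}
        # every slide contributes to all three subsets
        for _, grp in o1.groupby("slide_id"):
            assert set(grp["subset"]) == {"train", "valid", "test"}

    def test_largest_remainder_within_one_patch(self):
        df = pd.DataFrame({"slide_id": ["s"] * 13, "file_name": [f"p{i}" for i in range(13)]})
        out = make_holdout_split(df, seed=0)
        sizes = out["subset"].value_counts()
        for frac, name in [(0.6, "train"), (0.2, "valid"), (0.2, "test")]:
            assert abs(sizes[name] - 13 * frac) < 1.0

    def test_tiny_slide_warns_and_degenerates(self):
        df = pd.DataFrame({"slide_id": ["s"] * 2, "file_name": ["a", "b"]})
        with pytest.warns(UserWarning):
            out = make_holdout_split(df, seed=0)
        assert (out["subset"] == "train").all()


class TestQualityFilters:
    def test_filters_match_brute_force(self):
        df = cells_table(seed=3)
        spec = SplitSpec("cross_slides", seed=0)
        kept = apply_quality_filters(df, spec)
        brute = df[(df["rna_depth_quantile"] >= 0.02) & (df["jaccard_mean"] >= 0.2)]
        assert len(kept) == len(brute)
        assert set(kept["cell_id"]) == set(brute["cell_id"])

    def test_missing_column_rejected(self):
        df = cells_table().drop(columns=["jaccard_mean"])
        with pytest.raises(KeyError):
            apply_quality_filters(df, SplitSpec("cross_slides"))


class TestCvSplits:
    def test_cross_slides_each_slide_tested_once(self):
        df = cells_table(n_slides=5)
        folds = make_cv_splits(df, SplitSpec("cross_slides", outer_folds=5, seed=1))
        test_slides = folds[folds["role"] == "test"].groupby("fold")["slide_id"].unique()
        seen = sorted(np.concatenate(test_slides.to_list()))
        assert seen == sorted(df["slide_id"].unique())
        for fold, grp in folds.groupby("fold"):
            test = set(grp.loc[grp["role"] == "test", "slide_id"])
            trainval = set(grp.loc[grp["role"] != "test", "slide_id"])
            assert not test & trainval

    def test_cross_tissues_leave_one_out(self):
        df = cells_table(n_slides=6, tissues=["t0", "t0", "t1", "t1", "t2", "t2"])
        folds = make_cv_splits(df, SplitSpec("cross_tissues", seed=2))
        assert folds["fold"].nunique() == 3
        slide_tissue = dict(zip(df["slide_id"], df["tissue"]))
        for _, grp in folds.groupby("fold"):
            test_t = {slide_tissue[s] for s in grp.loc[grp["role"] == "test", "slide_id"]}
            other_t = {slide_tissue[s] for s in grp.loc[grp["role"] != "test", "slide_id"]}
            assert len(test_t) == 1 and not test_t & other_t

    def test_within_tissues_gate_and_seeding(self):
        tissues = ["rich"] * 4 + ["poor"] * 2
        df = cells_table(n_slides=6, tissues=tissues)
        spec = SplitSpec("within_tissues", outer_folds=4, val_folds=3, seed=9)
        folds = make_cv_splits(df, spec)
        assert set(f.split(":")[0] for f in folds["fold"]) == {"rich"}
        again = make_cv_splits(df, spec)
        pd.testing.assert_frame_equal(folds, again)

    def test_within_slides_cell_level_no_leak(self):
        df = cells_table(n_slides=2, cells_per_slide=30)
        folds = make_cv_splits(df, SplitSpec("within_slides", outer_folds=5,
                                             inner_val_frac=0.2, seed=4))
        for _, grp in folds.groupby("fold"):
            test = set(grp.loc[grp["role"] == "test", "cell_id"])
            rest = set(grp.loc[grp["role"] != "test", "cell_id"])
            assert not test & rest
            assert (grp["role"] == "valid").sum() >= 1

    def test_filters_applied_before_splitting(self):
        df = cells_table(n_slides=5, seed=7)
        spec = SplitSpec("cross_slides", seed=0)
        folds = make_cv_splits(df, spec)
        kept = apply_quality_filters(df, spec)
        assert set(folds["cell_id"]) == set(kept["cell_id"])

    def test_infeasible_regime_rejected(self):
        df = cells_table(n_slides=3)
        with pytest.raises(ValueError):
            make_cv_splits(df, SplitSpec("cross_slides", outer_folds=5))

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec("bootstrap")
        with pytest.raises(ValueError):
            SplitSpec("cross_slides", outer_folds=1)
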