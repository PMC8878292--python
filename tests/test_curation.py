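import numpy as np
import pandas as pd
import pytest

from pnaqsar import curation
from pnaqsar.chem import canonicalize_desalt, ecfp4
from pnaqsar.curation import (
    assign_task_labels,
    dedupe_within_source,
    iqr_outlier_filter,
    merge_sources,
    normalize_records,
    remove_activity_cliff_generators,
    stratified_kfold,
    stratified_split,
    to_pic50,
)


class TestToPic50:
    @pytest.mark.parametrize("ic50,expected", [
        (1e-6, 6.0), (1e-9, 9.0), (5e-8, 7.30103),
    ])
    def test_hand_values(self, ic50, expected):
        assert to_pic50(ic50) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            to_pic50(0.0)
        with pytest.raises(ValueError):
            to_pic50(-1e-9)


def _rec(smiles, target, pic50, source="A", assay="x", **kw):
    return {"smiles": smiles, "target": target, "pic50": pic50,
            "source": source, "assay": assay,
            "canonical_smiles": canonicalize_desalt(smiles).smiles, **kw}


class TestDedupe:
    def test_exact_duplicates_collapse(self):
        df = pd.DataFrame([_rec("CCO", "T1", 6.0), _rec("CCO", "T1", 6.0)])
        assert len(dedupe_within_source(df)) == 1

    def test_conflict_keeps_lowest_ic50(self):
        # 100 nM vs 10 nM: keep 10 nM, i.e. pIC50 8
        df = pd.DataFrame([_rec("CCO", "T1", 7.0, assay="a"),
                           _rec("CCO", "T1", 8.0, assay="b")])
        out = dedupe_within_source(df)
        assert len(out) == 1 and out.iloc[0]["pic50"] == 8.0

    def test_distinct_targets_never_merge(self):
        df = pd.DataFrame([_rec("CCO", "T1", 6.0), _rec("CCO", "T2", 7.0)])
        assert len(dedupe_within_source(df)) == 2


class TestIqrFilter:
    def test_hand_computed_outlier(self):
        # values 1..10 plus 1000: IQR bounds comfortably contain 1..10 and
        # exclude 1000 under the linear-interpolation quartile convention
        vals = list(range(1, 11)) + [1000]
        df = pd.DataFrame([_rec("CCO", "T1", 6.0, mw=v) for v in vals])
        kept, removed = iqr_outlier_filter(df, ["mw"])
        assert list(removed["mw"]) == [1000]
        assert len(kept) == 10

    def test_identical_values_keep_all(self):
        df = pd.DataFrame([_rec("CCO", "T1", 6.0, mw=100.0)] * 5)
        kept, removed = iqr_outlier_filter(df, ["mw"])
        assert len(removed) == 0

    def test_empty_property_list_is_identity(self):
        df = pd.DataFrame([_rec("CCO", "T1", 6.0, mw=1e9)])
        kept, removed = iqr_outlier_filter(df, [])
        assert len(kept) == 1 and len(removed) == 0

    def test_bounds_are_per_target(self):
        rows = [_rec("CCO", "T1", 6.0, mw=v) for v in [100] * 8 + [100000]]
        rows += [_rec("CCO", "T2", 6.0, mw=100000.0)] * 8  # normal for T2
        kept, removed = iqr_outlier_filter(pd.DataFrame(rows), ["mw"])
        assert len(removed) == 1 and removed.iloc[0]["target"] == "T1"


class TestMergeSources:
    def test_higher_pic50_wins_across_sources(self):
        a = pd.DataFrame([_rec("CCO", "EGFR", 6.2, source="A")])
        b = pd.DataFrame([_rec("CCO", "EGFR", 6.8, source="B")])
        out = merge_sources([a, b], targets=("EGFR", "MET"))
        assert len(out) == 1 and out.iloc[0]["EGFR"] == 6.8

    def test_single_source_passthrough_and_keyed_union(self):
        a = pd.DataFrame([_rec("CCO", "EGFR", 6.0, source="A")])
        b = pd.DataFrame([_rec("CCO", "MET", 7.5, source="B"),
                          _rec("CCN", "MET", 5.5, source="B")])
        out = merge_sources([a, b], targets=("EGFR", "MET"))
        row = out[out["smiles"] == "CCO"].iloc[0]
        assert row["EGFR"] == 6.0 and row["MET"] == 7.5
        assert len(out) == 2

    def test_exactly_one_value_per_compound_target(self, small_library):
        _, records, _ = small_library
        kept, _ = normalize_records(records, targets=("T1", "T2"))
        kept, _ = curation.canonicalize_records(kept)
        merged = merge_sources(
            [dedupe_within_source(s) for _, s in kept.groupby("source")],
            targets=("T1", "T2"))
        assert merged["smiles"].is_unique


class TestActivityCliffs:
    def test_threshold_pair_detected_and_removed(self):
        # twin compounds with Tanimoto ~1 and a 3-unit activity gap
        a = "c1c(-c2ccc(F)cc2)cc(-c2ccc(F)cc2)cc1-c2ccc(Cl)cc2"
        b = "c1c(-c2ccc(F)cc2)cc(-c2ccc(Cl)cc2)cc1-c2ccc(Cl)cc2"
        comp = pd.DataFrame({
            "smiles": [canonicalize_desalt(a).smiles, canonicalize_desalt(b).smiles,
                       "CCO"],
            "T1": [5.0, 8.0, 6.0],
        })
        kept, log = remove_activity_cliff_generators(comp, "T1")
        assert len(log) == 2  # both members are generators
        assert kept["T1"].notna().sum() == 1

    def test_identical_activities_never_a_pair(self):
        a = "c1c(-c2ccc(F)cc2)cc(-c2ccc(F)cc2)cc1-c2ccc(Cl)cc2"
        b = "c1c(-c2ccc(F)cc2)cc(-c2ccc(Cl)cc2)cc1-c2ccc(Cl)cc2"
        comp = pd.DataFrame({"smiles": [a, b], "T1": [6.0, 6.0]})
        kept, log = remove_activity_cliff_generators(comp, "T1")
        assert len(log) == 0

    def test_dissimilar_compounds_never_paired(self):
        comp = pd.DataFrame({"smiles": ["CCO", "c1ccc2ncncc2c1"],
                             "T1": [4.0, 9.0]})
        kept, log = remove_activity_cliff_generators(comp, "T1")
        assert len(log) == 0

    def test_engineered_cliffs_recovered(self, small_library):
        """The generator's engineered cliff pairs are found by the detector
        at its default thresholds."""
        spec, records, _ = small_library
        kept, _ = normalize_records(records, targets=("T1", "T2"))
        kept, _ = curation.canonicalize_records(kept)
        merged = merge_sources(
            [dedupe_within_source(s) for _, s in kept.groupby("source")],
            targets=("T1", "T2"))
        n_pairs = int(round(spec.cliff_fraction * spec.n_compounds))
        total_removed = 0
        for t in ("T1", "T2"):
            _, log = remove_activity_cliff_generators(merged, t)
            total_removed += len(log)
        assert total_removed >= n_pairs  # each pair yields >= 1 generator


class TestTaskLabels:
    def test_rarest_target_wins(self):
        comp = pd.DataFrame({"smiles": ["a", "b"],
                             "EGFR": [6.0, 6.5], "ROS1": [7.0, np.nan]})
        out = assign_task_labels(comp, targets=("EGFR", "ROS1"))
        assert out.iloc[0]["task_label"] == "ROS1"   # ROS1 rarer (1 < 2)
        assert out.iloc[1]["task_label"] == "EGFR"   # single-target compound

    def test_count_tie_breaks_by_target_order(self):
        comp = pd.DataFrame({"smiles": ["a"], "MET": [6.0], "ALK": [7.0]})
        out = assign_task_labels(comp, targets=("ALK", "MET"))
        assert out.iloc[0]["task_label"] == "ALK"


class TestSplits:
    def _compounds(self, n, label="T1"):
        return pd.DataFrame({"smiles": [f"C{'C' * (i % 9)}" for i in range(n)],
                             "T1": np.linspace(5, 8, n), "task_label": label})

    def test_single_label_split_arithmetic(self):
        out = stratified_split(self._compounds(1000), seed=0)
        counts = out["split"].value_counts()
        assert counts["external_test"] == 100
        assert counts["validation"] == 90
        assert counts["train"] == 810

    def test_deterministic_under_seed(self):
        c = self._compounds(200)
        a = stratified_split(c, seed=3)["split"]
        b = stratified_split(c, seed=3)["split"]
        assert a.equals(b)

    def test_per_label_proportions(self):
        frames = []
        for i, (label, n) in enumerate([("A", 300), ("B", 120), ("C", 60)]):
            f = self._compounds(n, label)
            f["smiles"] = f["smiles"] + "N" * i
            frames.append(f)
        out = stratified_split(pd.concat(frames, ignore_index=True), seed=1)
        for label, n in [("A", 300), ("B", 120), ("C", 60)]:
            sub = out[out["task_label"] == label]
            assert abs((sub["split"] == "external_test").sum() - 0.1 * n) <= 1

    def test_tiny_label_all_train(self):
        out = stratified_split(self._compounds(2), seed=0)
        assert (out["split"] == "train").all()

    def test_kfold_partitions(self):
        labels = ["A"] * 40 + ["B"] * 25
        folds = stratified_kfold(labels, k=5, seed=0)
        all_holdouts = np.concatenate([h for _, h in folds])
        assert sorted(all_holdouts) == list(range(65))  # disjoint cover
        sizes = [len(h) for _, h in folds]
        assert max(sizes) - min(sizes) <= len(set(labels))
        assert folds[0][1].tolist() == stratified_kfold(labels, 5, 0)[0][1].tolist()

    def test_kfold_small_label_degrades_gracefully(self):
        labels = ["A"] * 30 + ["B"] * 2
        folds = stratified_kfold(labels, k=5, seed=0)
        assert sum(len(h) for _, h in folds) == 32


class TestPipeline:
    def test_order_insensitive(self, clean_library):
        _, records, _ = clean_library
        res1 = curation.curate(records, targets=("T1", "T2"), seed=1)
        shuffled = records.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = curation.curate(shuffled, targets=("T1", "T2"), seed=1)
        a = res1.compounds.sort_values("smiles").reset_index(drop=True)
        b = res2.compounds.sort_values("smiles").reset_index(drop=True)
        pd.testing.assert_frame_equal(a[["smiles", "T1", "T2", "task_label"]],
                                      b[["smiles", "T1", "T2", "task_label"]])

    def test_external_test_excluded_from_cliff_removal(self, small_library):
        _, records, _ = small_library
        res = curation.curate(records, targets=("T1", "T2"), seed=1)
        removed = set(res.cliff_log["smiles"])
        ext = set(res.compounds[res.compounds["split"] == "external_test"]["smiles"])
        assert not removed & ext
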