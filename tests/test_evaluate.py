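"""Metric definitions and the hierarchical / local-pool / novel-species
protocols, checked against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from pitfallid.classify import ModelSpec, PredictionMatrix
from pitfallid.dataprep import SplitSet, filter_rare, make_splits, standardize
from pitfallid.evaluate import (
    EvaluateError,
    confusion_matrix_avg,
    hierarchical_evaluate,
    local_filter,
    macro_prf,
    novel_species_evaluate,
    single_level_evaluate,
    topk_accuracy,
)
from pitfallid.manifest import feature_names


def matrix(rows, classes, freq=None):
    classes = np.array(classes, dtype=object)
    freq = freq or {c: 1 for c in classes}
    return PredictionMatrix(np.array(rows, float), classes, freq)


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)


def brute_macro_prf(pred, truth, classes):
    ps, rs, fs = [], [], []
    for c in classes:
        tp = sum(1 for p, t in zip(pred, truth) if p == c and t == c)
        fp = sum(1 for p, t in zip(pred, truth) if p == c and t != c)
        fn = sum(1 for p, t in zip(pred, truth) if p != c and t == c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        ps.append(prec)
        rs.append(rec)
        fs.append(f1)
    return np.mean(ps), np.mean(rs), np.mean(fs)


def brute_topk(proba, classes, freq, truth, k):
    hits = 0
    name_order = {c: i for i, c in enumerate(sorted(classes))}
    for row, t in zip(proba, truth):
        scored = sorted(
            zip(row, classes),
            key=lambda pc: (-pc[0], -freq[pc[1]], name_order[pc[1]]),
        )
        hits += t in [c for _, c in scored[:k]]
    return hits / len(truth)


class TestTopK:
    def test_hand_ranked_toy(self):
        # truth sits at rank 1, 2 and 4 of the three rows
        pm = matrix(
            [
                [0.7, 0.2, 0.05, 0.05],
                [0.4, 0.5, 0.05, 0.05],
                [0.4, 0.3, 0.2, 0.1],
            ],
            ["a", "b", "c", "d"],
        )
        truth = ["a", "a", "d"]
        assert topk_accuracy(pm, truth, 1) == pytest.approx(1 / 3)
        assert topk_accuracy(pm, truth, 3) == pytest.approx(2 / 3)

    def test_k_equal_to_class_count_is_perfect(self):
        pm = matrix([[0.9, 0.1], [0.2, 0.8]], ["a", "b"])
        assert topk_accuracy(pm, ["b", "a"], 2) == 1.0

    def test_k_beyond_classes_clamps_with_warning(self):
        pm = matrix([[0.9, 0.1]], ["a", "b"])
        with pytest.warns(UserWarning, match="clamp"):
            assert topk_accuracy(pm, ["b"], 5) == 1.0

    def test_topk_matches_brute_force_and_top3_ge_top1(self, rng):
        classes = list("abcde")
        for _ in range(100):
            n = int(rng.integers(5, 40))
            proba = rng.dirichlet(np.ones(5), size=n)
            truth = rng.choice(classes, size=n)
            freq = {c: int(rng.integers(1, 50)) for c in classes}
            pm = PredictionMatrix(proba, np.array(classes, object), freq)
            t1 = topk_accuracy(pm, truth, 1)
            t3 = topk_accuracy(pm, truth, 3)
            assert t1 == pytest.approx(brute_topk(proba, classes, freq, truth, 1))
            assert t3 == pytest.approx(brute_topk(proba, classes, freq, truth, 3))
            assert t3 >= t1


class TestMacroPRF:
    def test_perfect_predictions(self):
        p, r, f = macro_prf(["a", "b", "a"], ["a", "b", "a"])
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_two_class_hand_computation(self):
        # confusion [[8,2],[3,7]]: 8 a-as-a, 2 b-as-a, 3 a-as-b, 7 b-as-b
        pred = ["a"] * 8 + ["a"] * 2 + ["b"] * 3 + ["b"] * 7
        truth = ["a"] * 8 + ["b"] * 2 + ["a"] * 3 + ["b"] * 7
        p, r, f = macro_prf(pred, truth)
        prec_a, prec_b = 8 / 10, 7 / 10
        rec_a, rec_b = 8 / 11, 7 / 9
        f_a = 2 * prec_a * rec_a / (prec_a + rec_a)
        f_b = 2 * prec_b * rec_b / (prec_b + rec_b)
        assert p == pytest.approx((prec_a + prec_b) / 2)
        assert r == pytest.approx((rec_a + rec_b) / 2)
        assert f == pytest.approx((f_a + f_b) / 2)

    def test_never_predicted_class_has_zero_precision(self):
        p, r, f = macro_prf(["a", "a"], ["a", "b"], classes=["a", "b"])
        assert p == pytest.approx((0.5 + 0.0) / 2)

    def test_matches_brute_force_oracle_100_seeds(self):
        classes = list("abcde")
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 50))
            pred = rng.choice(classes, size=n)
            truth = rng.choice(classes, size=n)
            got = macro_prf(pred, truth, classes=classes)
            want = brute_macro_prf(pred, truth, classes)
            assert got == pytest.approx(want, abs=1e-12)


class TestHierarchical:
    def test_congener_confusion_right_at_genus(self, carabid_taxonomy):
        classes = [
            "Pasimachus strenuus",
            "Pasimachus californicus",
            "Scarites subterraneus",
            "Cyclotrachelus torvus",
        ]
        pm = matrix([[0.1, 0.8, 0.05, 0.05]], classes)
        res = hierarchical_evaluate(pm, ["Pasimachus strenuus"], carabid_taxonomy)
        assert res.loc["species", "top1"] == 0.0
        assert res.loc["genus", "top1"] == 1.0
        assert res.loc["subfamily", "top1"] == 1.0

    def test_cross_subfamily_confusion_wrong_everywhere(self, carabid_taxonomy):
        classes = [
            "Pasimachus strenuus",
            "Pasimachus californicus",
            "Scarites subterraneus",
            "Cyclotrachelus torvus",
        ]
        pm = matrix([[0.05, 0.05, 0.1, 0.8]], classes)
        res = hierarchical_evaluate(pm, ["Scarites subterraneus"], carabid_taxonomy)
        assert (res["top1"] == 0.0).all()

    def test_top1_monotone_nondecreasing_with_rank(self, reduced_report):
        s = reduced_report.summary()
        order = ["species", "group", "genus", "subtribe", "tribe", "subfamily"]
        top1 = s[(s["metric"] == "top1") & (s["mode"] == "hierarchical")]
        for alg, grp in top1.groupby("algorithm"):
            vals = grp.set_index("rank").loc[order, "value"].to_numpy()
            assert (np.diff(vals) >= -1e-12).all(), alg

    def test_top3_ge_top1_at_every_rank(self, reduced_report):
        s = reduced_report.summary()
        h = s[s["mode"] == "hierarchical"].pivot_table(
            index=["algorithm", "rank"], columns="metric", values="value"
        )
        assert (h["top3"] >= h["top1"] - 1e-12).all()


class TestSingleLevel:
    @pytest.fixture()
    def toy_splits(self, reduced_dataset):
        _, table, _ = reduced_dataset
        common, _ = filter_rare(table)
        return [standardize(s) for s in make_splits(common, n_repeats=2, seed=3)]

    def test_species_rank_equals_hierarchical(self, reduced_dataset, toy_splits, carabid_taxonomy):
        tax, _, _ = reduced_dataset
        spec = ModelSpec("LDA")
        df = single_level_evaluate(spec, toy_splits, tax, "species")
        for split, (_, row) in zip(toy_splits, df.iterrows()):
            from pitfallid.classify import train

            feats = feature_names()
            model = train(spec, split.train[feats].to_numpy(), split.train["species"].to_numpy(object))
            pm = model.prediction_matrix(split.test[feats].to_numpy())
            hier = hierarchical_evaluate(pm, split.test["species"], tax, ["species"])
            assert row["top1"] == pytest.approx(hier.loc["species", "top1"])

    def test_class_count_matches_distinct_taxa(self, reduced_dataset, toy_splits):
        tax, _, _ = reduced_dataset
        from pitfallid.classify import train

        split = toy_splits[0]
        genera = set(tax.lift(list(split.train["species"]), "genus"))
        feats = feature_names()
        model = train(
            ModelSpec("LDA"),
            split.train[feats].to_numpy(),
            np.array(tax.lift(list(split.train["species"]), "genus"), object),
        )
        assert set(model.classes_) == genera

    def test_single_class_rank_flagged_degenerate(self, reduced_dataset, toy_splits):
        tax, _, _ = reduced_dataset
        if tax.n_taxa("subfamily") > 1:
            # force degeneracy with a one-subfamily sub-table
            fam = tax.table["subfamily"].iloc[0]
            keep = set(tax.table[tax.table["subfamily"] == fam]["species"])
            splits = []
            for s in toy_splits:
                tr = s.train[s.train["species"].isin(keep)]
                te = s.test[s.test["species"].isin(keep)]
                splits.append(SplitSet(s.repeat_index, tr, te, s.standardizer))
        else:
            splits = toy_splits
        df = single_level_evaluate(ModelSpec("LDA"), splits, tax, "subfamily")
        assert df["degenerate"].all()
        assert (df["top1"] == 1.0).all()


class TestLocalFilter:
    def test_predictions_restricted_to_pool(self, carabid_taxonomy):
        classes = ["Chlaenius aestivus", "Cyclotrachelus furtivus", "Scarites subterraneus"]
        pm = matrix(
            [[0.1, 0.2, 0.7], [0.5, 0.3, 0.2]],
            classes,
            freq={c: 10 for c in classes},
        )
        pools = {"s1": ["Chlaenius aestivus", "Cyclotrachelus furtivus"]}
        res = local_filter(pm, ["s1", "s1"], pools, ["Cyclotrachelus furtivus", "Chlaenius aestivus"])
        # row 1's top class (Scarites) is outside the pool; Cyclotrachelus wins
        assert res.pooled_accuracy == 1.0
        assert res.unrestricted_accuracy == 0.5

    def test_singleton_pool_scores_one_and_is_excluded(self):
        classes = ["a", "b"]
        pm = matrix([[0.9, 0.1], [0.2, 0.8]], classes, freq={"a": 5, "b": 5})
        pools = {"solo": ["a"], "both": ["a", "b"]}
        res = local_filter(pm, ["solo", "both"], pools, ["a", "a"])
        per_site = res.per_site.set_index("site")
        assert per_site.loc["solo", "singleton"]
        assert per_site.loc["solo", "accuracy"] == 1.0
        # pooled accuracy covers only the non-singleton site (row 2, wrong)
        assert res.pooled_accuracy == 0.0

    def test_no_degradation_when_truth_in_pool(self, rng):
        classes = list("abcd")
        for _ in range(20):
            n = int(rng.integers(5, 30))
            proba = rng.dirichlet(np.ones(4), size=n)
            truth = rng.choice(classes, size=n)
            pools = {"s": classes[:3]}
            keep = np.isin(truth, pools["s"])
            if not keep.any():
                continue
            pm = PredictionMatrix(
                proba[keep], np.array(classes, object), {c: 1 for c in classes}
            )
            res = local_filter(pm, ["s"] * int(keep.sum()), pools, truth[keep])
            assert res.pooled_accuracy >= res.unrestricted_accuracy - 1e-12

    def test_unknown_site_is_an_error(self):
        pm = matrix([[1.0, 0.0]], ["a", "b"])
        with pytest.raises(EvaluateError, match="absent"):
            local_filter(pm, ["nowhere"], {"s": ["a"]}, ["a"])


class TestNovelSpecies:
    class _Stub:
        """Fixed-output model: always predicts Cyclotrachelus furtivus."""

        def __init__(self, classes):
            self.classes_ = np.array(classes, dtype=object)

        def prediction_matrix(self, X):
            proba = np.zeros((len(X), len(self.classes_)))
            proba[:, list(self.classes_).index("Cyclotrachelus furtivus")] = 1.0
            return PredictionMatrix(proba, self.classes_, {c: 1 for c in self.classes_})

    def test_worked_example_unmeasured_then_genus_then_subtribe(self, carabid_taxonomy):
        """A novel Pterostichus forced to a species call: not measurable at
        species/group, wrong at genus, right from subtribe upward."""
        training = [
            "Pasimachus strenuus",
            "Scarites subterraneus",
            "Cyclotrachelus furtivus",
            "Pterostichus melanarius",
        ]
        model = self._Stub(training)
        rare = pd.DataFrame(
            [[0.0] * 68], columns=feature_names()
        )
        rare["species"] = ["Pterostichus trinarius"]
        res = novel_species_evaluate(model, rare, carabid_taxonomy).set_index("rank")
        assert res.loc["species", "n_measurable"] == 0
        assert res.loc["group", "n_measurable"] == 0
        assert res.loc["genus", "n_measurable"] == 1
        assert res.loc["genus", "accuracy"] == 0.0
        assert res.loc["subtribe", "accuracy"] == 1.0
        assert res.loc["tribe", "accuracy"] == 1.0
        assert res.loc["subfamily", "accuracy"] == 1.0

    def test_rare_species_missing_from_taxonomy_errors(self, carabid_taxonomy):
        model = self._Stub(["Cyclotrachelus furtivus", "Pasimachus strenuus"])
        rare = pd.DataFrame([[0.0] * 68], columns=feature_names())
        rare["species"] = ["Agonum muelleri"]
        with pytest.raises(EvaluateError, match="missing from taxonomy"):
            novel_species_evaluate(model, rare, carabid_taxonomy)

    def test_genus_measurable_iff_shared_with_training(self, carabid_taxonomy):
        model = self._Stub(["Cyclotrachelus furtivus", "Pasimachus strenuus"])
        rare = pd.DataFrame([[0.0] * 68] * 2, columns=feature_names())
        rare["species"] = ["Cyclotrachelus torvus", "Chlaenius aestivus"]
        res = novel_species_evaluate(model, rare, carabid_taxonomy).set_index("rank")
        assert res.loc["genus", "n_measurable"] == 1  # only the Cyclotrachelus


class TestConfusionMatrix:
    def test_perfect_predictor_is_diagonal(self):
        truth = np.array(["a", "a", "b"], dtype=object)
        out = confusion_matrix_avg([(truth, truth)])
        assert out.loc["a", "a"] == 2 and out.loc["b", "b"] == 1
        assert out.loc["a", "b"] == 0
        assert out.loc["Actual", "a"] == 2

    def test_cellwise_average_of_two_repeats(self):
        p1 = np.array(["a", "a", "b", "b"], dtype=object)
        t1 = np.array(["a", "b", "b", "b"], dtype=object)
        p2 = np.array(["a", "b", "b", "b"], dtype=object)
        t2 = np.array(["a", "a", "b", "b"], dtype=object)
        out = confusion_matrix_avg([(p1, t1), (p2, t2)])
        # cell (a,a): repeat1 has 1, repeat2 has 1 -> 1.0
        assert out.loc["a", "a"] == 1.0
        # cell (b,b): repeat1 has 2, repeat2 has 2 -> 2.0
        assert out.loc["b", "b"] == 2.0
        # cell (a,b): repeat1 1, repeat2 0 -> 0.5
        assert out.loc["a", "b"] == 0.5

    def test_column_sums_equal_average_test_counts(self, rng):
        pairs = []
        for _ in range(3):
            t = rng.choice(list("abc"), size=20)
            p = rng.choice(list("abc"), size=20)
            pairs.append((p, t))
        out = confusion_matrix_avg(pairs)
        for c in "abc":
            want = np.mean([(t == c).sum() for _, t in pairs])
            assert out.loc["Actual", c] == pytest.approx(want)
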