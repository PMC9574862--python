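import json

import numpy as np
import pytest

import protacsol as ps
from protacsol.datatypes import GskClass, Moiety
from protacsol.errors import DegenerateDesignError, DomainError, InsufficientDataError
from protacsol.models import (
    LogS,
    classify_solubility_rule,
    compare_pair,
    confusion_matrix,
    cross_validate,
    fit_linear,
    learn_tree,
    reference_rule_tree,
    tree_from_json,
    tree_to_json,
)
from tests.conftest import ols_oracle


class TestFitLinear:
    def test_exact_line(self):
        x = [0, 1, 2, 3, 4]
        lm = fit_linear(x, [2 * v + 1 for v in x])
        assert (lm.slope, lm.intercept, lm.r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_y(self):
        lm = fit_linear([0, 1, 2, 3], [5, 5, 5, 5])
        assert lm.slope == pytest.approx(0.0, abs=1e-12)
        assert lm.r2 == 0.0

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear([2, 2, 2], [1, 2, 3])

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 40)
        y = -1.3 * x + 2 + rng.normal(0, 1, 40)
        lm = fit_linear(x, y)
        slope, intercept, r2 = ols_oracle(x, y)
        assert lm.slope == pytest.approx(slope, abs=1e-10)
        assert lm.intercept == pytest.approx(intercept, abs=1e-10)
        assert lm.r2 == pytest.approx(r2, abs=1e-12)

    def test_duplicate_point_exchange_invariance(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.1, 2.3, 1.9, 3.2]
        a = fit_linear(x, y)
        b = fit_linear([1.0, 2.0, 2.0, 3.0], [1.1, 1.9, 2.3, 3.2])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_affine_x_rescaling_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 20)
        y = 0.7 * x + rng.normal(0, 0.2, 20)
        base = fit_linear(x, y)
        scaled = fit_linear(3.0 * x + 1.0, y)
        assert scaled.slope == pytest.approx(base.slope / 3.0, abs=1e-10)
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-12)


class TestSolubilityRule:
    @pytest.mark.parametrize(
        "tpsa,brlogd,expected",
        [
            (300.0, 5.0, GskClass.HIGH),
            (200.0, 3.0, GskClass.LOW),
            (200.0, 2.0, GskClass.INTERMEDIATE),
            (289.31, 0.0, GskClass.HIGH),       # threshold inclusive
            (289.30, 2.58, GskClass.LOW),       # threshold inclusive
        ],
    )
    def test_rule(self, tpsa, brlogd, expected):
        assert classify_solubility_rule(tpsa, brlogd) == expected

    def test_rule_agrees_with_two_split_tree(self):
        tree = reference_rule_tree()
        rng = np.random.default_rng(17)
        tpsa = rng.uniform(100, 400, 10_000)
        brlogd = rng.uniform(-1, 7, 10_000)
        preds = tree.predict(np.column_stack([tpsa, brlogd]))
        assert all(p == classify_solubility_rule(t, b)
                   for p, t, b in zip(preds, tpsa, brlogd))


class TestLearnTree:
    def test_one_dimensional_midpoint_split(self):
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = [GskClass.LOW] * 3 + [GskClass.HIGH] * 3
        tree = learn_tree(X, y, ["x"])
        assert tree.splits() == [("x", 5.0)]

    def test_pure_node_single_leaf(self):
        X = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single-class"):
            tree = learn_tree(X, [GskClass.LOW, GskClass.LOW], ["x"])
        assert tree.root.is_leaf()
        assert tree.predict(X) == [GskClass.LOW, GskClass.LOW]

    def test_xor_with_depth_one_is_chance(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = [GskClass.LOW, GskClass.LOW, GskClass.HIGH, GskClass.HIGH]
        tree = learn_tree(X, y, ["a", "b"], max_depth=1)
        acc = np.mean([p == t for p, t in zip(tree.predict(X), y)])
        assert acc == 0.5

    def test_training_accuracy_beats_majority_baseline(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(30, 2))
        y = [GskClass.LOW if a + b < 0.9 else GskClass.HIGH for a, b in X]
        tree = learn_tree(X, y, ["a", "b"])
        acc = np.mean([p == t for p, t in zip(tree.predict(X), y)])
        counts = np.unique([c.value for c in y], return_counts=True)[1]
        assert acc >= counts.max() / counts.sum()

    def test_root_split_matches_sklearn_cart(self):
        """Depth-1 split agrees with an independent CART implementation."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(12)
        for _ in range(5):
            X = rng.uniform(0, 10, size=(40, 1))
            y = np.where(X[:, 0] + rng.normal(0, 1.5, 40) > 5, "high", "low")
            mine = learn_tree(X, [GskClass(v) for v in y], ["x"], max_depth=1)
            ref = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
            # sklearn stores features as float32; midpoints differ in the 7th digit
            assert mine.splits()[0][1] == pytest.approx(ref.tree_.threshold[0], abs=1e-5)

    def test_json_round_trip(self, tmp_path):
        tree = reference_rule_tree()
        payload = tree_to_json(tree)
        restored = tree_from_json(payload)
        assert restored.splits() == tree.splits()
        assert restored.provenance == "fixed_rule"
        path = tmp_path / "tree.json"
        tree_to_json(tree, path)
        assert tree_from_json(path).splits() == tree.splits()

    def test_synthetic_rule_data_recovers_thresholds(self):
        """A tree refit on noiseless rule-labelled points recovers both
        published split features in order."""
        rng = np.random.default_rng(21)
        tpsa = rng.uniform(150, 400, 300)
        brlogd = rng.uniform(0, 6, 300)
        y = [classify_solubility_rule(t, b) for t, b in zip(tpsa, brlogd)]
        tree = learn_tree(np.column_stack([tpsa, brlogd]), y, ["tpsa", "brlogd"])
        feats = [f for f, _ in tree.splits()]
        assert set(feats) == {"tpsa", "brlogd"}
        for feature, threshold in tree.splits():
            target = 289.31 if feature == "tpsa" else 2.58
            assert threshold == pytest.approx(target, abs=2.0 if feature == "tpsa" else 0.1)


class TestCrossValidation:
    def test_separable_data_perfect_accuracy(self):
        X = np.vstack([np.full((10, 1), 0.0), np.full((10, 1), 10.0)])
        y = [GskClass.LOW] * 10 + [GskClass.HIGH] * 10
        for seed in (0, 1, 2):
            acc, _ = cross_validate(X, y, ["x"], k=5, seed=seed)
            assert acc == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        n = 300
        X = rng.uniform(0, 1, size=(n, 2))
        y = [GskClass(v) for v in rng.permutation(
            ["low", "intermediate", "high"] * (n // 3))]
        acc, _ = cross_validate(X, y, ["a", "b"], k=10, seed=1, max_depth=3)
        assert abs(acc - 1 / 3) < 0.12

    def test_pooled_counts_conserve_class_totals(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(30, 2))
        y = [GskClass.LOW] * 12 + [GskClass.INTERMEDIATE] * 10 + [GskClass.HIGH] * 8
        acc, cm = cross_validate(X, y, ["a", "b"], k=5, seed=0)
        assert cm.total == 30
        assert list(cm.counts.sum(axis=1)) == [12, 10, 8]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            cross_validate(np.zeros((3, 1)), [GskClass.LOW] * 3, ["x"], k=10)

    def test_small_class_falls_back_to_plain_folds(self):
        X = np.arange(12, dtype=float).reshape(-1, 1)
        y = [GskClass.LOW] * 10 + [GskClass.HIGH] * 2
        with pytest.warns(UserWarning, match="unstratified"):
            cross_validate(X, y, ["x"], k=4, seed=0)


class TestConfusionMatrix:
    def test_accuracy_and_recall(self):
        true = [GskClass.LOW, GskClass.LOW, GskClass.HIGH, GskClass.INTERMEDIATE]
        pred = [GskClass.LOW, GskClass.HIGH, GskClass.HIGH, GskClass.INTERMEDIATE]
        cm = confusion_matrix(true, pred)
        assert cm.accuracy == 0.75
        assert cm.recall(GskClass.LOW) == 0.5
        assert cm.recall(GskClass.HIGH) == 1.0


class TestChemicalSpaceExport:
    def test_complete_rows_exported(self, synthetic_panel):
        df = ps.chemical_space_export(synthetic_panel, axes=("nc", "phi", "tpsa"))
        assert len(df) == 21
        assert set(df.columns) == {"id", "nc", "phi", "tpsa", "gsk_class", "censored"}

    def test_missing_axis_drops_row_with_warning(self, synthetic_panel):
        synthetic_panel.descriptors["SYN-001"].tpsa = None
        with pytest.warns(UserWarning, match="SYN-001"):
            df = ps.chemical_space_export(synthetic_panel, axes=("nc", "phi", "tpsa"))
        assert len(df) == 20

    def test_round_trip_through_writer(self, synthetic_panel, tmp_path):
        import pandas as pd

        df = ps.chemical_space_export(synthetic_panel)
        path = tmp_path / "space.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["tpsa"], df["tpsa"])


class TestComparePair:
    def test_warhead_pair_concordant(self):
        # more-soluble warhead (censored above -2.6) -> more-soluble degrader
        report = compare_pair(
            ("MZ1", LogS(-4.42)), ("MZP-54", LogS(-6.29)), Moiety.WARHEAD,
            ("JQ1 carboxylic acid", LogS(-2.6, censor="above")),
            ("I-BET726", LogS(-4.42)))
        assert report.delta_log_s == pytest.approx(1.87)
        assert report.concordance == "concordant"

    def test_e3_pair_discordant(self):
        report = compare_pair(
            ("BI-3663", LogS(-5.16)), ("BI-0319", LogS(-5.58)), Moiety.E3_LIGAND,
            ("pomalidomide", LogS(-4.44)), ("S,R,S-AHPC HCl", LogS(-2.68)))
        assert report.delta_log_s == pytest.approx(0.42)
        assert report.concordance == "discordant"

    def test_missing_block_indeterminate(self):
        report = compare_pair(("dBET57", LogS(-4.52)), ("ZXH-3-26", LogS(-5.53)),
                              Moiety.LINKER)
        assert report.concordance == "indeterminate"

    def test_identical_compound_indeterminate_zero_delta(self):
        report = compare_pair(("A", LogS(-5.0)), ("A", LogS(-5.0)), Moiety.WARHEAD,
                              ("w", LogS(-3.0)), ("w", LogS(-3.0)))
        assert report.delta_log_s == 0.0
        assert report.concordance == "indeterminate"

    def test_overlapping_censored_intervals_indeterminate(self):
        report = compare_pair(
            ("A", LogS(-4.0)), ("B", LogS(-5.0)), Moiety.WARHEAD,
            ("wa", LogS(-4.0, censor="above")), ("wb", LogS(-3.0)))
        assert report.concordance == "indeterminate"

    def test_block_property_deltas(self):
        report = compare_pair(
            ("A", LogS(-4.0)), ("B", LogS(-5.0)), Moiety.WARHEAD,
            ("wa", LogS(-2.0)), ("wb", LogS(-3.0)),
            block_properties={"brlogd": (1.5, 2.5), "tpsa": (120.0, None)})
        assert report.block_deltas == {"brlogd": -1.0}
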