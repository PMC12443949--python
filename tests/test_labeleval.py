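import io
import random
import zipfile

import numpy as np
import pandas as pd
import pytest

import clinext as cx
from clinext import labeleval
from clinext.errors import ConfigurationError, EvaluationError, IngestionWarning


@pytest.fixture
def bool_schema():
    return cx.validate_schema([cx.LabelSpec("cough", "boolean")])


def gt(tmp_path, rows, columns):
    p = tmp_path / "truth.csv"
    pd.DataFrame(rows, columns=columns).to_csv(p, index=False)
    return p


class TestLoadGroundTruth:
    def test_loads_id_plus_label_columns(self, tmp_path, tnm_small):
        schema = tnm_small["schema"]
        p = gt(
            tmp_path,
            [["d1"] + ["T1", "N0", "M0", "10", "0", "true", "false"]],
            ["id", *schema.names],
        )
        truth = cx.load_ground_truth(p, schema)
        assert truth.rows["d1"]["t_stage"] == "T1"
        assert truth.declared_kinds["nodes_examined"] == "number"

    def test_missing_label_column_rejected(self, tmp_path, bool_schema):
        p = gt(tmp_path, [["d1"]], ["id"])
        with pytest.raises(EvaluationError, match="cough"):
            cx.load_ground_truth(p, bool_schema)

    def test_duplicate_ids_rejected(self, tmp_path, bool_schema):
        p = gt(tmp_path, [["d1", "true"], ["d1", "false"]], ["id", "cough"])
        with pytest.raises(EvaluationError, match="duplicate"):
            cx.load_ground_truth(p, bool_schema)

    def test_unconfirmed_kinds_refuse_metrics(self, tmp_path, bool_schema):
        p = gt(tmp_path, [["d1", "true"]], ["id", "cough"])
        truth = cx.load_ground_truth(p, bool_schema)
        results = [cx.DocumentResult("d1", {"cough": True})]
        with pytest.raises(ConfigurationError, match="confirm"):
            cx.evaluate_labels(results, truth, bool_schema)
        truth.confirm_kinds()
        summary = cx.evaluate_labels(results, truth, bool_schema)
        assert summary.overall_accuracy == 1.0

    def test_unmatched_result_ids_reported_and_excluded(self, tmp_path, bool_schema):
        p = gt(tmp_path, [["d1", "true"]], ["id", "cough"])
        truth = cx.load_ground_truth(p, bool_schema).confirm_kinds()
        results = [
            cx.DocumentResult("d1", {"cough": True}),
            cx.DocumentResult("ghost", {"cough": True}),
        ]
        summary = cx.evaluate_labels(results, truth, bool_schema)
        assert summary.n_compared == 1
        assert summary.unmatched_ids == ["ghost"]


class TestCoercion:
    @pytest.mark.parametrize(
        "raw,kind,expected",
        [
            ("True ", "boolean", True),
            ("no", "boolean", False),
            ("1", "boolean", True),
            (" T3", "categorical", "t3"),
            ("t3", "categorical", "t3"),
            ("a  b\tc", "string", "a b c"),
            ("017", "number", 17),
            (" 2.50 ", "number", 2.5),
        ],
    )
    def test_normalization(self, raw, kind, expected):
        assert cx.coerce_value(raw, kind) == expected

    def test_unparseable_becomes_missing_with_warning(self):
        with pytest.warns(IngestionWarning):
            assert cx.coerce_value("maybe", "boolean") is cx.MISSING
        with pytest.warns(IngestionWarning):
            assert cx.coerce_value("n/a", "number") is cx.MISSING


class TestCompareDocument:
    KINDS = {"cough": "boolean", "side": "categorical", "nodes": "number"}
    GOLD = {"cough": "true", "side": "left", "nodes": "12"}

    def cmp(self, pred):
        return cx.compare_document(pred, self.GOLD, self.KINDS)

    def test_true_positive(self):
        out = self.cmp({"cough": True, "side": "left", "nodes": 12})
        assert out == {"cough": "TP", "side": ("left", "left"), "nodes": True}

    def test_number_mismatch(self):
        assert self.cmp({"cough": True, "side": "left", "nodes": 13})["nodes"] is False

    def test_missing_prediction_is_fn_for_gold_true(self):
        out = self.cmp({"cough": cx.MISSING, "side": cx.MISSING, "nodes": cx.MISSING})
        assert out["cough"] == "FN"
        assert out["side"] == ("left", "MISSING")
        assert out["nodes"] is False

    def test_missing_prediction_is_tn_for_gold_false(self):
        out = cx.compare_document(
            {"cough": cx.MISSING}, {"cough": "false"}, {"cough": "boolean"}
        )
        assert out["cough"] == "TN"

    def test_label_absent_from_gold_row_rejected(self):
        with pytest.raises(EvaluationError):
            cx.compare_document({"x": True}, {}, {"x": "boolean"})


class TestPerLabelMetrics:
    def test_boolean_block_matches_arithmetic(self):
        outcomes = ["TP"] * 10 + ["TN"] * 12 + ["FN"] * 3
        block = cx.per_label_metrics(outcomes, "boolean")
        assert block["recall"] == pytest.approx(10 / 13)
        assert block["accuracy"] == pytest.approx(22 / 25)
        assert block["precision"] == 1.0
        assert block["fnr"] == pytest.approx(3 / 13)

    def test_perfect_categorical_identity_confusion(self):
        pairs = [("T1", "T1"), ("T2", "T2"), ("T1", "T1")]
        block = cx.per_label_metrics(pairs, "categorical")
        assert block["accuracy"] == 1.0
        conf = block["confusion"]
        assert np.trace(conf.counts) == 3

    def test_three_class_macro_ovr_matches_per_class_counting(self):
        rng = random.Random(21)
        classes = ["A", "B", "C"]
        pairs = [(rng.choice(classes), rng.choice(classes)) for _ in range(200)]
        block = cx.per_label_metrics(pairs, "categorical")
        # brute-force one-vs-rest per class present in gold
        precisions, recalls = [], []
        for cls in classes:
            tp = sum(1 for g, p in pairs if g == cls and p == cls)
            fp = sum(1 for g, p in pairs if g != cls and p == cls)
            fn = sum(1 for g, p in pairs if g == cls and p != cls)
            if tp + fp:
                precisions.append(tp / (tp + fp))
            if tp + fn:
                recalls.append(tp / (tp + fn))
        assert block["precision"] == pytest.approx(sum(precisions) / len(precisions))
        assert block["recall"] == pytest.approx(sum(recalls) / len(recalls))

    def test_macro_cross_checked_against_sklearn(self):
        from sklearn.metrics import precision_score, recall_score

        rng = random.Random(4)
        classes = ["A", "B", "C"]
        # every class predicted and present so no undefined entries
        pairs = [(c, c) for c in classes] + [
            (rng.choice(classes), rng.choice(classes)) for _ in range(100)
        ]
        block = cx.per_label_metrics(pairs, "categorical")
        gold = [g for g, _ in pairs]
        pred = [p for _, p in pairs]
        assert block["precision"] == pytest.approx(
            precision_score(gold, pred, average="macro", zero_division=np.nan)
        )
        assert block["recall"] == pytest.approx(
            recall_score(gold, pred, average="macro", zero_division=np.nan)
        )

    def test_string_and_number_accuracy_is_match_fraction(self):
        assert cx.per_label_metrics([True, True, False], "number")["accuracy"] == (
            pytest.approx(2 / 3)
        )


class TestOverallAccuracy:
    def test_micro_average_counts_pairs(self):
        kinds = {f"l{i}": "number" for i in range(7)}
        outcomes = {}
        correct = 0
        rng = random.Random(2)
        for d in range(100):
            row = {}
            for l in kinds:
                ok = rng.random() < 0.87
                row[l] = ok
                correct += ok
            outcomes[f"d{d}"] = row
        acc = cx.overall_accuracy(outcomes, kinds)
        assert acc == pytest.approx(correct / 700)

    def test_invariant_to_ordering(self):
        kinds = {"a": "boolean", "b": "number"}
        out1 = {"d1": {"a": "TP", "b": True}, "d2": {"a": "FN", "b": False}}
        out2 = {k: out1[k] for k in reversed(list(out1))}
        assert cx.overall_accuracy(out1, kinds) == cx.overall_accuracy(out2, kinds)


class TestMetricsReport:
    def test_bundle_round_trips_and_margins_sum(self, tmp_path, tnm_small):
        summary = tnm_small["summary"]
        out = tmp_path / "metrics.zip"
        cx.build_metrics_report(
            summary, tnm_small["results"], tnm_small["truth"],
            tnm_small["schema"], tnm_small["docs"], out,
        )
        with zipfile.ZipFile(out) as zf:
            names = set(zf.namelist())
            metrics = pd.read_csv(io.BytesIO(zf.read("metrics.csv")))
            conf = pd.read_csv(
                io.BytesIO(zf.read("confusion_t_stage.csv")), index_col=0
            )
            per_doc = pd.read_csv(io.BytesIO(zf.read("per_document_comparison.csv")))
        assert "confusion_t_stage.png" in names
        assert "documents/tnm-0001.txt" in names
        overall = metrics[metrics.label == "__overall__"].accuracy.iloc[0]
        assert overall == pytest.approx(summary.overall_accuracy)
        assert conf.values.sum() == summary.n_compared  # marginal sums
        # per-document file lists gold and prediction side by side
        row = per_doc[(per_doc.id == "tnm-0001") & (per_doc.label == "t_stage")]
        assert not row.empty and {"gold", "predicted"} <= set(per_doc.columns)


class TestParameterRecoveryProperty:
    def test_per_label_accuracy_converges_to_one_minus_p(self):
        from conftest import run_tnm_pipeline

        p = 0.1
        out = run_tnm_pipeline(n=300, seed=5, error_rate=p)
        se = (p * (1 - p) / 300) ** 0.5
        for label, block in out["summary"].per_label.items():
            assert abs(block["accuracy"] - (1 - p)) < 3 * se, label
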