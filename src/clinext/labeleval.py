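"""Label-wise evaluation of extraction results against a ground-truth table.

Predictions and gold values are normalized per kind before comparison
(booleans accept yes/no/1/0 spellings, categorical and string values are
trimmed, case-folded and whitespace-collapsed, numbers are compared as
decimals so "017" equals 17).  Boolean labels yield a pooled TP/FP/TN/FN
block with the full metric set; categorical labels yield a gold-by-predicted
confusion matrix with trace accuracy and macro one-vs-rest
precision/recall/F1; number and string labels yield a match fraction.

A MISSING prediction counts as predicted-negative for booleans and as a
plain mismatch for every other kind; "skip" mode excludes such documents
instead.  Overall accuracy is the micro average over all (document, label)
comparisons.
"""

from __future__ import annotations

import io
import json
import re
import warnings
import zipfile
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .anonymize import LabelMetrics, METRIC_NAMES, _ratio
from .corpus import Document
from .engine import MISSING, DocumentResult
from .errors import ConfigurationError, EvaluationError, IngestionWarning
from .schema import ExtractionSchema

_TRUE_WORDS = {"true", "yes", "1"}
_FALSE_WORDS = {"false", "no", "0"}
_WS_RE = re.compile(r"\s+")

MISSING_CLASS = "MISSING"  # how MISSING appears in categorical confusions


@dataclass
class GroundTruthTable:
    rows: dict[str, dict[str, str]]  # id -> label -> gold value (as string)
    declared_kinds: dict[str, str]  # label -> kind
    kinds_confirmed: bool = False

    def confirm_kinds(self) -> "GroundTruthTable":
        """Explicitly confirm the declared data types before metrics run."""
        self.kinds_confirmed = True
        return self


def load_ground_truth(path: str | Path, schema: ExtractionSchema) -> GroundTruthTable:
    """Read a ground-truth CSV/XLSX with an id column plus one per label.

    The returned table carries the schema's kinds but starts unconfirmed:
    evaluation refuses to run until :meth:`GroundTruthTable.confirm_kinds`
    is called, so a silently wrong type declaration cannot skew metrics.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif path.suffix.lower() == ".xlsx":
        df = pd.read_excel(path, dtype=str, keep_default_na=False)
    else:
        raise EvaluationError(f"unsupported ground-truth format: {path.suffix!r}")
    if "id" not in df.columns:
        raise EvaluationError(f"{path}: ground truth needs an 'id' column")
    missing_cols = [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise EvaluationError(f"{path}: missing label columns {missing_cols}")
    ids = [str(v) for v in df["id"]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise EvaluationError(f"{path}: duplicate ids {dupes}")
    rows = {
        str(row["id"]): {n: str(row[n]) for n in schema.names}
        for _, row in df.iterrows()
    }
    kinds = {spec.name: spec.kind for spec in schema.labels}
    return GroundTruthTable(rows=rows, declared_kinds=kinds)


def coerce_value(raw: Any, kind: str) -> Any:
    """Normalize a raw value per kind; unparseable values become MISSING."""
    if raw is MISSING:
        return MISSING
    if isinstance(raw, bool):
        return raw if kind == "boolean" else _normalize_text(str(raw))
    s = str(raw).strip()
    if kind == "boolean":
        low = s.lower()
        if low in _TRUE_WORDS:
            return True
        if low in _FALSE_WORDS:
            return False
        warnings.warn(f"unparseable boolean {raw!r}", IngestionWarning)
        return MISSING
    if kind == "number":
        try:
            d = Decimal(s)
        except InvalidOperation:
            warnings.warn(f"unparseable number {raw!r}", IngestionWarning)
            return MISSING
        return int(d) if d == d.to_integral_value() else float(d)
    return _normalize_text(s)


def _normalize_text(s: str) -> str:
    return _WS_RE.sub(" ", s.strip().casefold())


def compare_document(
    pred: DocumentResult | Mapping[str, Any],
    gold_row: Mapping[str, str],
    kinds: Mapping[str, str],
) -> dict[str, Any]:
    """Compare one document's predictions to its gold row, label by label.

    Outcomes: booleans map to "TP"/"FP"/"TN"/"FN" (gold true is the
    positive class; MISSING predicts negative); categoricals map to a
    (gold, predicted) class pair; numbers and strings map to True/False.
    """
    values = pred.values if isinstance(pred, DocumentResult) else pred
    outcomes: dict[str, Any] = {}
    for label, kind in kinds.items():
        if label not in gold_row:
            raise EvaluationError(f"label {label!r} absent from ground-truth row")
        g = coerce_value(gold_row[label], kind)
        p = coerce_value(values.get(label, MISSING), kind)
        if kind == "boolean":
            pred_pos = p is True  # MISSING counts as predicted-negative
            if g is True:
                outcomes[label] = "TP" if pred_pos else "FN"
            else:
                outcomes[label] = "FP" if pred_pos else "TN"
        elif kind == "categorical":
            outcomes[label] = (
                MISSING_CLASS if g is MISSING else str(g),
                MISSING_CLASS if p is MISSING else str(p),
            )
        else:  # number, string: exact match after normalization
            outcomes[label] = (p is not MISSING and g is not MISSING and p == g)
    return outcomes


@dataclass
class CategoricalConfusion:
    classes: list[str]
    counts: np.ndarray  # rows = gold, columns = predicted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


def categorical_confusion(pairs: Sequence[tuple[str, str]]) -> CategoricalConfusion:
    """Gold-by-predicted count matrix over the union of observed classes."""
    classes = sorted({g for g, _ in pairs} | {p for _, p in pairs})
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for g, p in pairs:
        counts[index[g], index[p]] += 1
    return CategoricalConfusion(classes, counts)


def _macro_one_vs_rest(conf: CategoricalConfusion) -> dict[str, float | None]:
    """Macro precision/recall/F1 over classes present in gold."""
    precisions, recalls, f1s = [], [], []
    for i, cls in enumerate(conf.classes):
        gold_count = conf.counts[i, :].sum()
        if gold_count == 0:
            continue  # class never appears in gold
        tp = conf.counts[i, i]
        fp = conf.counts[:, i].sum() - tp
        fn = gold_count - tp
        prec = _ratio(int(tp), int(tp + fp))
        rec = _ratio(int(tp), int(tp + fn))
        if prec is not None:
            precisions.append(prec)
        if rec is not None:
            recalls.append(rec)
        if prec is not None and rec is not None and prec + rec > 0:
            f1s.append(2 * prec * rec / (prec + rec))
        elif prec is not None and rec is not None:
            f1s.append(0.0)
    return {
        "precision": sum(precisions) / len(precisions) if precisions else None,
        "recall": sum(recalls) / len(recalls) if recalls else None,
        "f1": sum(f1s) / len(f1s) if f1s else None,
    }


def per_label_metrics(outcomes: Sequence[Any], kind: str) -> dict[str, Any]:
    """Aggregate one label's per-document outcomes into a metrics block."""
    if not outcomes:
        raise EvaluationError("no compared documents for label")
    if kind == "boolean":
        tp = sum(1 for o in outcomes if o == "TP")
        fp = sum(1 for o in outcomes if o == "FP")
        tn = sum(1 for o in outcomes if o == "TN")
        fn = sum(1 for o in outcomes if o == "FN")
        total = tp + fp + tn + fn
        precision = _ratio(tp, tp + fp)
        recall = _ratio(tp, tp + fn)
        f1 = (
            None
            if precision is None or recall is None or precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
        return {
            "kind": kind, "n": total,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "accuracy": (tp + tn) / total,
            "precision": precision, "recall": recall,
            "specificity": _ratio(tn, tn + fp), "f1": f1,
            "fpr": _ratio(fp, fp + tn), "fnr": _ratio(fn, fn + tp),
        }
    if kind == "categorical":
        conf = categorical_confusion(list(outcomes))
        block: dict[str, Any] = {
            "kind": kind, "n": conf.total,
            "accuracy": conf.accuracy, "confusion": conf,
        }
        block.update(_macro_one_vs_rest(conf))
        return block
    matches = sum(1 for o in outcomes if o is True)
    return {
        "kind": kind, "n": len(outcomes),
        "accuracy": matches / len(outcomes),
    }


def _outcome_correct(outcome: Any, kind: str) -> bool:
    if kind == "boolean":
        return outcome in ("TP", "TN")
    if kind == "categorical":
        return outcome[0] == outcome[1]
    return outcome is True


def overall_accuracy(
    all_outcomes: Mapping[str, dict[str, Any]], kinds: Mapping[str, str]
) -> float:
    """Micro accuracy: correct (document, label) pairs / all pairs."""
    correct = total = 0
    for outcomes in all_outcomes.values():
        for label, o in outcomes.items():
            total += 1
            correct += _outcome_correct(o, kinds[label])
    if total == 0:
        raise EvaluationError("no outcomes to aggregate")
    return correct / total


@dataclass
class MetricsSummary:
    per_label: dict[str, dict[str, Any]]
    overall_accuracy: float
    n_compared: int
    n_unmatched: int
    unmatched_ids: list[str] = field(default_factory=list)
    outcomes: dict[str, dict[str, Any]] = field(default_factory=dict)


def evaluate_labels(
    results: Sequence[DocumentResult],
    truth: GroundTruthTable,
    schema: ExtractionSchema,
    missing_policy: str = "penalize",
) -> MetricsSummary:
    """Compare every result to its gold row and aggregate metrics.

    Refuses to run until the ground-truth kinds have been confirmed.
    Result ids absent from the ground truth are reported as unmatched and
    excluded; with ``missing_policy="skip"``, documents whose prediction
    for a label is MISSING are dropped from that label's comparison instead
    of being penalized.
    """
    if not truth.kinds_confirmed:
        raise ConfigurationError(
            "ground-truth data types are unconfirmed; call "
            "GroundTruthTable.confirm_kinds() (or pass --kinds confirmed) "
            "before computing metrics"
        )
    if missing_policy not in ("penalize", "skip"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    kinds = truth.declared_kinds
    all_outcomes: dict[str, dict[str, Any]] = {}
    unmatched = []
    for r in results:
        if r.doc_id not in truth.rows:
            unmatched.append(r.doc_id)
            continue
        outcomes = compare_document(r, truth.rows[r.doc_id], kinds)
        if missing_policy == "skip":
            values = r.values
            outcomes = {
                k: v for k, v in outcomes.items()
                if values.get(k, MISSING) is not MISSING
            }
        all_outcomes[r.doc_id] = outcomes
    if not all_outcomes:
        raise EvaluationError("no result ids matched the ground truth")
    per_label = {}
    for spec in schema.labels:
        label_outcomes = [
            o[spec.name] for o in all_outcomes.values() if spec.name in o
        ]
        if label_outcomes:
            per_label[spec.name] = per_label_metrics(label_outcomes, spec.kind)
    flat_kinds = {k: v for k, v in kinds.items()}
    return MetricsSummary(
        per_label=per_label,
        overall_accuracy=overall_accuracy(all_outcomes, flat_kinds),
        n_compared=len(all_outcomes),
        n_unmatched=len(unmatched),
        unmatched_ids=sorted(unmatched),
        outcomes=all_outcomes,
    )


def build_metrics_report(
    summary: MetricsSummary,
    results: Sequence[DocumentResult],
    truth: GroundTruthTable,
    schema: ExtractionSchema,
    docs: Sequence[Document],
    out_path: str | Path,
) -> Path:
    """Write the metrics bundle ZIP: metrics CSV, confusion tables and
    figures, a per-document gold-vs-predicted comparison, and the documents.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    metric_rows = []
    for label, block in summary.per_label.items():
        row = {"label": label, "kind": block["kind"], "n": block["n"]}
        for m in ("accuracy", *METRIC_NAMES[1:]):
            if m in block:
                row[m] = block[m]
        metric_rows.append(row)
    metric_rows.append(
        {"label": "__overall__", "kind": "micro", "n": summary.n_compared,
         "accuracy": summary.overall_accuracy}
    )
    metrics_csv = pd.DataFrame(metric_rows).to_csv(index=False)

    comparison_rows = []
    for r in results:
        if r.doc_id not in truth.rows:
            continue
        for name in schema.names:
            v = r.values.get(name, MISSING)
            comparison_rows.append(
                {"id": r.doc_id, "label": name,
                 "gold": truth.rows[r.doc_id][name],
                 "predicted": "" if v is MISSING else str(v),
                 "missing": v is MISSING}
            )
    comparison_csv = pd.DataFrame(comparison_rows).to_csv(index=False)

    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("metrics.csv", metrics_csv)
        zf.writestr("per_document_comparison.csv", comparison_csv)
        zf.writestr(
            "summary.json",
            json.dumps(
                {
                    "overall_accuracy": summary.overall_accuracy,
                    "n_compared": summary.n_compared,
                    "n_unmatched": summary.n_unmatched,
                    "unmatched_ids": summary.unmatched_ids,
                },
                indent=2,
            ),
        )
        for label, block in summary.per_label.items():
            if block["kind"] != "categorical":
                continue
            conf: CategoricalConfusion = block["confusion"]
            frame = conf.to_frame()
            zf.writestr(f"confusion_{label}.csv", frame.to_csv())
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(conf.counts, cmap="Blues")
            ax.set_xticks(range(len(conf.classes)), conf.classes, rotation=45)
            ax.set_yticks(range(len(conf.classes)), conf.classes)
            ax.set_xlabel("predicted")
            ax.set_ylabel("gold")
            ax.set_title(label)
            for i in range(len(conf.classes)):
                for j in range(len(conf.classes)):
                    ax.text(j, i, str(conf.counts[i, j]), ha="center", va="center")
            buf = io.BytesIO()
            fig.tight_layout()
            fig.savefig(buf, format="png", dpi=100)
            plt.close(fig)
            zf.writestr(f"confusion_{label}.png", buf.getvalue())
        for d in docs:
            zf.writestr(f"documents/{d.id}.txt", d.text)
    return out_path
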