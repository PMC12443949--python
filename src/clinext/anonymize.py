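"""Exact-string redaction of personal identifiers and its character-wise
evaluation.

De-identification here is deliberately simple and auditable: the values the
model extracted for identifier labels (names, date of birth, patient id,
age, sex) are matched as exact substrings — case-insensitively by default —
and every matched character is replaced by a mask glyph.  Masking is 1:1
per character so document length and all other offsets are preserved.

Evaluation treats every character as a redaction decision: a character is a
true positive when it is masked and lies inside a gold identifier span,
a false positive when masked outside all gold spans, and so on.  Metrics
are the usual confusion-matrix derivatives; zero-denominator cases are
UNDEFINED (None) and are skipped — with a reported count — when macro
averaging over documents.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Document
from .engine import MISSING, DocumentResult
from .errors import ConfigurationError, EvaluationError

DEFAULT_MASK_CHAR = "■"  # ■
DEFAULT_SENTINELS = frozenset({"", "not mentioned"})
ALL_LABELS = "ALL"


@dataclass(frozen=True)
class AnnotatedSpan:
    """A gold identifier occurrence: ``[start, end)`` offsets into a document."""

    doc_id: str
    label: str
    start: int
    end: int
    covered_text: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise EvaluationError(
                f"span {self.doc_id}/{self.label}: invalid offsets "
                f"[{self.start},{self.end})"
            )


@dataclass
class RedactionMask:
    doc_id: str
    mask: np.ndarray  # boolean, one entry per character


@dataclass(frozen=True)
class CharConfusion:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "CharConfusion") -> "CharConfusion":
        return CharConfusion(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class LabelMetrics:
    """Confusion-derived metrics; None marks an UNDEFINED (0/0) metric."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    fpr: float | None
    fnr: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "fpr": self.fpr, "fnr": self.fnr,
        }


METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1", "fpr", "fnr")


def collect_identifiers(
    result: DocumentResult | Mapping[str, Any],
    identifier_labels: Iterable[str],
    min_length: int = 2,
    sentinels: frozenset[str] = DEFAULT_SENTINELS,
) -> set[str]:
    """Gather the identifier strings to redact from an extraction result.

    Values shorter than ``min_length`` are excluded (a one-letter sex code
    would mask arbitrary text), as are sentinel answers like "not mentioned".
    """
    values = result.values if isinstance(result, DocumentResult) else result
    out: set[str] = set()
    for label in identifier_labels:
        if label not in values:
            raise ConfigurationError(f"unknown identifier label {label!r}")
        v = values[label]
        if v is MISSING:
            continue
        s = str(v).strip()
        if len(s) < min_length or s.lower() in sentinels:
            continue
        out.add(s)
    return out


def redact_text(
    doc: Document,
    identifiers: Iterable[str],
    case_sensitive: bool = False,
    mask_char: str = DEFAULT_MASK_CHAR,
) -> tuple[RedactionMask, str]:
    """Mask every occurrence of every identifier string in the document.

    Overlapping occurrences union; the redacted text replaces each masked
    character by one mask glyph, preserving length and all offsets.
    """
    text = doc.text
    haystack = text if case_sensitive else text.lower()
    mask = np.zeros(len(text), dtype=bool)
    for ident in identifiers:
        needle = ident if case_sensitive else ident.lower()
        if not needle:
            continue
        start = 0
        while True:
            i = haystack.find(needle, start)
            if i < 0:
                break
            mask[i : i + len(needle)] = True
            start = i + 1  # overlapping occurrences count too
    redacted = "".join(mask_char if m else c for m, c in zip(mask, text))
    return RedactionMask(doc.id, mask), redacted


def spans_from_annotation_export(
    zip_path: str | Path, documents: Sequence[Document] | None = None
) -> list[AnnotatedSpan]:
    """Load gold spans from a ZIP of per-document JSON files.

    Each member is ``<doc_id>.json`` holding a list of objects with fields
    ``label``, ``begin``, ``end``, ``covered_text``.  When documents are
    supplied, offsets and covered text are validated against them.
    """
    docs_by_id = {d.id: d for d in documents} if documents is not None else None
    spans: list[AnnotatedSpan] = []
    orphans = []
    with zipfile.ZipFile(zip_path) as zf:
        for name in sorted(zf.namelist()):
            if not name.endswith(".json"):
                continue
            doc_id = Path(name).stem
            if docs_by_id is not None and doc_id not in docs_by_id:
                orphans.append(doc_id)
                continue
            entries = json.loads(zf.read(name).decode("utf-8"))
            for e in entries:
                span = AnnotatedSpan(
                    doc_id=doc_id,
                    label=str(e["label"]),
                    start=int(e["begin"]),
                    end=int(e["end"]),
                    covered_text=str(e["covered_text"]),
                )
                if docs_by_id is not None:
                    text = docs_by_id[doc_id].text
                    if span.end > len(text):
                        raise EvaluationError(
                            f"span {doc_id}/{span.label} [{span.start},{span.end}) "
                            f"exceeds document length {len(text)}"
                        )
                    if text[span.start : span.end] != span.covered_text:
                        raise EvaluationError(
                            f"span {doc_id}/{span.label} covered_text does not "
                            f"match document slice [{span.start},{span.end})"
                        )
                spans.append(span)
    if orphans:
        raise EvaluationError(f"annotation files match no document: {orphans}")
    return spans


def _gold_vector(length: int, spans: Iterable[AnnotatedSpan]) -> np.ndarray:
    g = np.zeros(length, dtype=bool)
    for s in spans:
        if s.end > length:
            raise EvaluationError(
                f"span {s.doc_id}/{s.label} exceeds document length {length}"
            )
        g[s.start : s.end] = True
    return g


def char_confusion(
    mask: RedactionMask,
    gold: Sequence[AnnotatedSpan],
    restrict_label: str = ALL_LABELS,
) -> CharConfusion:
    """Per-character confusion of a redaction mask against gold spans.

    With ``restrict_label`` set, TP/FN consider only that label's spans,
    while FP counts only masked characters outside *every* gold label —
    redacting a first name must not count as a last-name error.
    """
    m = mask.mask
    n = len(m)
    doc_spans = [s for s in gold if s.doc_id == mask.doc_id]
    g_all = _gold_vector(n, doc_spans)
    if restrict_label == ALL_LABELS:
        g = g_all
    else:
        g = _gold_vector(n, [s for s in doc_spans if s.label == restrict_label])
    tp = int(np.sum(m & g))
    fn = int(np.sum(~m & g))
    fp = int(np.sum(m & ~g_all))
    tn = n - tp - fn - fp
    return CharConfusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_to_metrics(c: CharConfusion) -> LabelMetrics:
    """Accuracy/precision/recall/specificity/F1/FPR/FNR from raw counts."""
    if c.total == 0:
        raise EvaluationError("empty confusion: total count is zero")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = (
        None
        if precision is None or recall is None or precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return LabelMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
        fpr=_ratio(c.fp, c.fp + c.tn),
        fnr=_ratio(c.fn, c.fn + c.tp),
    )


def macro_average_metrics(
    per_document: Sequence[LabelMetrics],
) -> tuple[LabelMetrics, dict[str, int]]:
    """Unweighted mean of each metric over documents, skipping UNDEFINED.

    Returns the macro metrics plus, per metric, how many documents were
    skipped because the metric was undefined there.
    """
    if not per_document:
        raise EvaluationError("macro average of an empty list")
    means: dict[str, float | None] = {}
    skipped: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = [
            getattr(m, name) for m in per_document if getattr(m, name) is not None
        ]
        skipped[name] = len(per_document) - len(vals)
        means[name] = sum(vals) / len(vals) if vals else None
    return LabelMetrics(**means), skipped


def evaluate_anonymization(
    docs: Sequence[Document],
    masks: Mapping[str, RedactionMask],
    gold: Sequence[AnnotatedSpan],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full anonymizer evaluation: per-document x per-label + pooled rows.

    Returns a tidy frame with one row per (doc, label) and per (doc, ALL),
    plus pooled rows (doc_id="__pooled__") summing counts over documents,
    and macro rows (doc_id="__macro__") averaging per-document metrics.
    """
    if labels is None:
        labels = sorted({s.label for s in gold})
    rows = []
    pooled: dict[str, CharConfusion] = {}
    per_doc_metrics: dict[str, list[LabelMetrics]] = {}
    for doc in docs:
        mask = masks[doc.id]
        for label in [ALL_LABELS, *labels]:
            c = char_confusion(mask, gold, restrict_label=label)
            metrics = confusion_to_metrics(c)
            pooled[label] = pooled.get(label, CharConfusion()) + c
            per_doc_metrics.setdefault(label, []).append(metrics)
            rows.append(
                {"doc_id": doc.id, "label": label,
                 "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                 **metrics.as_dict()}
            )
    for label, c in pooled.items():
        rows.append(
            {"doc_id": "__pooled__", "label": label,
             "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
             **confusion_to_metrics(c).as_dict()}
        )
    for label, ms in per_doc_metrics.items():
        macro, _ = macro_average_metrics(ms)
        rows.append(
            {"doc_id": "__macro__", "label": label,
             "tp": None, "fp": None, "tn": None, "fn": None,
             **macro.as_dict()}
        )
    return pd.DataFrame(rows)
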