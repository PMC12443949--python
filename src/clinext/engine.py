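"""Extraction orchestration: prompts, per-chunk runs, merging, baselines.

The engine renders the user's prompt template around each chunk, requests a
grammar-constrained completion, parses the output, and reconciles chunk
records into one row per document.  Failures (unparseable output, backend
errors, truncation) are recorded per document and never abort a run.

MISSING is a first-class sentinel distinct from the empty string: it means
the pipeline produced no value for a label, which evaluation must treat
differently from a model answering "".
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from .backend import CompletionRequest, CompletionResult, GenerationConfig
from .corpus import Chunk, Document
from .errors import BackendError, OutputParseError, TemplateError
from .schema import ExtractionSchema, parse_and_validate_output, schema_to_gbnf


class _Missing:
    """Singleton sentinel for 'no value produced'."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()
#: wire form of MISSING in results CSVs (distinct from the empty string)
MISSING_TOKEN = "__missing__"


@dataclass(frozen=True)
class PromptTemplate:
    """Prompt text containing exactly one ``{report}`` placeholder."""

    text: str

    def __post_init__(self) -> None:
        n = self.text.count("{report}")
        if n != 1:
            raise TemplateError(
                f"template must contain exactly one {{report}} placeholder, found {n}"
            )


def render_prompt(template: PromptTemplate, chunk: Chunk) -> str:
    """Insert the chunk text at the placeholder; everything else unchanged."""
    return template.text.replace("{report}", chunk.text)


@dataclass
class ExtractionRecord:
    doc_id: str
    chunk_index: int
    values: dict[str, Any]
    raw_output: str
    status: str  # ok | parse_error | backend_error | truncated
    prompt_used: str = ""
    config_used: GenerationConfig | None = None


@dataclass
class DocumentResult:
    doc_id: str
    values: dict[str, Any]
    provenance: dict[str, int] = field(default_factory=dict)  # label -> chunk index
    conflict_flags: set[str] = field(default_factory=set)
    status: str = "ok"


def extract_chunk(
    chunk: Chunk,
    schema: ExtractionSchema,
    template: PromptTemplate,
    backend,
    config: GenerationConfig | None = None,
) -> ExtractionRecord:
    """Run one chunk through the backend and parse the constrained output."""
    config = config or GenerationConfig()
    prompt = render_prompt(template, chunk)
    grammar = schema_to_gbnf(schema)
    request = CompletionRequest(prompt=prompt, grammar=grammar, config=config)
    missing_all = {name: MISSING for name in schema.names}
    try:
        result: CompletionResult = backend.complete(
            request, context={"doc_id": chunk.doc_id, "chunk_index": chunk.index}
        )
    except BackendError:
        return ExtractionRecord(
            chunk.doc_id, chunk.index, dict(missing_all), "", "backend_error",
            prompt, config,
        )
    if result.finish_reason == "length":
        # truncation means the token budget was too small; never trust the text
        return ExtractionRecord(
            chunk.doc_id, chunk.index, dict(missing_all), result.text, "truncated",
            prompt, config,
        )
    try:
        values = parse_and_validate_output(result.text, schema)
    except OutputParseError:
        return ExtractionRecord(
            chunk.doc_id, chunk.index, dict(missing_all), result.text, "parse_error",
            prompt, config,
        )
    return ExtractionRecord(
        chunk.doc_id, chunk.index, values, result.text, "ok", prompt, config
    )


MERGE_POLICIES = ("first_answer", "majority", "any_positive")


def merge_chunk_records(
    records: Sequence[ExtractionRecord],
    schema: ExtractionSchema,
    policy: str = "first_answer",
) -> DocumentResult:
    """Reconcile chunk-level records into one per-document result.

    ``first_answer`` takes the first non-MISSING value per label;
    ``majority`` the modal value (ties broken by earliest chunk);
    ``any_positive`` makes booleans true iff any chunk says true and falls
    back to first_answer otherwise.  Disagreements between chunks are
    always flagged, whatever the policy resolves them to.
    """
    if not records:
        raise ValueError("cannot merge an empty record list")
    if policy not in MERGE_POLICIES:
        raise ValueError(f"unknown merge policy {policy!r}")
    doc_ids = {r.doc_id for r in records}
    if len(doc_ids) != 1:
        raise ValueError(f"records span multiple documents: {sorted(doc_ids)}")
    records = sorted(records, key=lambda r: r.chunk_index)
    out = DocumentResult(doc_id=records[0].doc_id, values={})
    for spec in schema.labels:
        candidates = [
            (r.chunk_index, r.values[spec.name])
            for r in records
            if r.values.get(spec.name, MISSING) is not MISSING
        ]
        if not candidates:
            out.values[spec.name] = MISSING
            out.provenance[spec.name] = -1
            continue
        distinct = {v for _, v in candidates}
        if len(distinct) > 1:
            out.conflict_flags.add(spec.name)
        if policy == "majority":
            counts = Counter(v for _, v in candidates)
            best = max(counts.values())
            chosen_idx, chosen = next(
                (i, v) for i, v in candidates if counts[v] == best
            )
        elif policy == "any_positive" and spec.kind == "boolean":
            chosen_idx, chosen = next(
                ((i, v) for i, v in candidates if v is True), candidates[0]
            )
        else:  # first_answer (and any_positive fallback)
            chosen_idx, chosen = candidates[0]
        out.values[spec.name] = chosen
        out.provenance[spec.name] = chosen_idx
    statuses = [r.status for r in records]
    for bad in ("backend_error", "parse_error", "truncated"):
        if bad in statuses:
            out.status = bad
            break
    return out


def results_to_frame(
    results: Sequence[DocumentResult], schema: ExtractionSchema
) -> pd.DataFrame:
    """Serialize document results to the results table (one row per document)."""
    rows = []
    for r in results:
        row: dict[str, Any] = {"id": r.doc_id}
        for name in schema.names:
            v = r.values.get(name, MISSING)
            row[name] = MISSING_TOKEN if v is MISSING else (
                ("true" if v else "false") if isinstance(v, bool) else str(v)
            )
        row["status"] = r.status
        row["conflicts"] = ";".join(sorted(r.conflict_flags))
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", *schema.names, "status", "conflicts"])


def frame_to_results(df: pd.DataFrame, schema: ExtractionSchema) -> list[DocumentResult]:
    """Inverse of :func:`results_to_frame` (typed values re-coerced)."""
    out = []
    for _, row in df.iterrows():
        values: dict[str, Any] = {}
        for spec in schema.labels:
            cell = str(row[spec.name])
            if cell == MISSING_TOKEN:
                values[spec.name] = MISSING
            elif spec.kind == "boolean":
                values[spec.name] = cell == "true"
            elif spec.kind == "number":
                values[spec.name] = (
                    float(cell) if "." in cell else int(cell)
                )
            else:
                values[spec.name] = cell
        out.append(
            DocumentResult(
                doc_id=str(row["id"]),
                values=values,
                conflict_flags=set(filter(None, str(row["conflicts"]).split(";"))),
                status=str(row["status"]),
            )
        )
    return out


def run_extraction(
    docs: Sequence[Document],
    chunks: Sequence[Chunk],
    schema: ExtractionSchema,
    template: PromptTemplate,
    backend,
    config: GenerationConfig | None = None,
    policy: str = "first_answer",
) -> tuple[pd.DataFrame, dict, list[DocumentResult]]:
    """Extract every document and return (results table, run manifest, results).

    Per-document failures are isolated: a parse error in one document never
    changes any other document's row.
    """
    config = config or GenerationConfig()
    by_doc: dict[str, list[Chunk]] = {}
    for c in chunks:
        by_doc.setdefault(c.doc_id, []).append(c)
    results: list[DocumentResult] = []
    status_counts: Counter[str] = Counter()
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    for doc in docs:
        doc_chunks = sorted(by_doc.get(doc.id, []), key=lambda c: c.index)
        if not doc_chunks:
            doc_chunks = [Chunk(doc.id, 0, 0, len(doc.text), doc.text)]
        records = [
            extract_chunk(c, schema, template, backend, config) for c in doc_chunks
        ]
        merged = merge_chunk_records(records, schema, policy)
        status_counts[merged.status] += 1
        results.append(merged)
    finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest = {
        "prompt": template.text,
        "grammar": schema_to_gbnf(schema).text,
        "config": {
            "model_id": config.model_id,
            "temperature": config.temperature,
            "n_predict": config.n_predict,
            "seed": config.seed,
        },
        "backend": getattr(backend, "name", type(backend).__name__),
        "merge_policy": policy,
        "started": started,
        "finished": finished,
        "n_documents": len(docs),
        "status_counts": {
            k: status_counts.get(k, 0)
            for k in ("ok", "parse_error", "backend_error", "truncated")
        },
    }
    return results_to_frame(results, schema), manifest, results


# --- keyword baseline -------------------------------------------------------

_T_RE = re.compile(r"\b(?:y?p)?(T(?:[0-4]|is|x|X))([a-c])?\b")
_N_RE = re.compile(r"\b(?:y?p)?(N[0-3xX])\b")
_M_RE = re.compile(r"\b(?:y?p)?(M[01xX])\b")


def keyword_baseline_tnm(text: str) -> dict[str, Any]:
    """Regex keyword search for explicit TNM stage tokens.

    Matches optional ``p``/``yp`` pathological-staging prefixes (stripped
    from the reported value) and optional ``a``–``c`` substage suffixes;
    the first match per axis wins.  A sanity baseline only: it cannot read
    stages that are implied rather than stated, which is exactly where
    LLM-based extraction earns its keep.
    """
    out: dict[str, Any] = {}
    for axis, rx in (("T", _T_RE), ("N", _N_RE), ("M", _M_RE)):
        m = rx.search(text)
        if m is None:
            out[axis] = MISSING
        else:
            value = m.group(1)
            suffix = m.group(2) if rx is _T_RE else None
            value = value[0] + value[1:].replace("X", "x")
            out[axis] = value + (suffix or "")
    return out


def save_run_manifest(manifest: Mapping[str, Any], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dict(manifest), fh, indent=2, ensure_ascii=False)
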