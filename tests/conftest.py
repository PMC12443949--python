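from __future__ import annotations

import pytest

import clinext as cx
from clinext.fixtures import IDENTIFIER_LABELS

PE_PROMPT = cx.PromptTemplate(
    "You are a helpful medical assistant. Extract the patient identifiers, "
    "the leading symptoms and the embolism side. This is the report: {report}"
)
TNM_PROMPT = cx.PromptTemplate(
    "Extract the TNM stage, lymph node counts, resection margin and "
    "lymphatic invasion. This is the report: {report}"
)


def run_pe_pipeline(n=8, seed=1, collision_rate=0.0, error_rate=0.0):
    """Generate PE letters, extract with the mock backend, and redact."""
    schema = cx.pe_schema()
    cases = cx.generate_pe_letters(n, seed=seed, collision_rate=collision_rate)
    docs = [c.document for c in cases]
    chunks = [ch for d in docs for ch in cx.split_document(d)]
    backend = cx.MockBackend(
        schema, cx.truth_mapping(cases), error_rate=error_rate, seed=seed
    )
    frame, manifest, results = cx.run_extraction(
        docs, chunks, schema, PE_PROMPT, backend
    )
    spans = [s for c in cases for s in c.gold_spans]
    masks = {}
    for d, r in zip(docs, results):
        idents = cx.collect_identifiers(r, IDENTIFIER_LABELS)
        masks[d.id], _ = cx.redact_text(d, idents)
    return {
        "schema": schema, "cases": cases, "docs": docs, "chunks": chunks,
        "frame": frame, "manifest": manifest, "results": results,
        "spans": spans, "masks": masks,
    }


def run_tnm_pipeline(n=100, seed=3, error_rate=0.0, mock_seed=None,
                     corrupt_doc_ids=()):
    """Generate TNM reports, extract with the mock backend, evaluate labels."""
    schema = cx.tnm_schema()
    cases = cx.generate_tnm_reports(n, seed=seed)
    docs = [c.document for c in cases]
    chunks = [ch for d in docs for ch in cx.split_document(d)]
    backend = cx.MockBackend(
        schema, cx.truth_mapping(cases), error_rate=error_rate,
        seed=seed if mock_seed is None else mock_seed,
        corrupt_doc_ids=set(corrupt_doc_ids),
    )
    frame, manifest, results = cx.run_extraction(
        docs, chunks, schema, TNM_PROMPT, backend
    )
    truth = cx.GroundTruthTable(
        rows={
            c.document.id: {
                k: ("true" if v is True else "false" if v is False else str(v))
                for k, v in c.truth.items()
            }
            for c in cases
        },
        declared_kinds={s.name: s.kind for s in schema.labels},
    ).confirm_kinds()
    summary = cx.evaluate_labels(results, truth, schema)
    return {
        "schema": schema, "cases": cases, "docs": docs, "frame": frame,
        "manifest": manifest, "results": results, "truth": truth,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def pe_clean():
    return run_pe_pipeline(n=8, seed=1, collision_rate=0.0, error_rate=0.0)


@pytest.fixture(scope="session")
def pe_collision():
    return run_pe_pipeline(n=8, seed=1, collision_rate=1.0, error_rate=0.0)


@pytest.fixture(scope="session")
def tnm_small():
    return run_tnm_pipeline(n=30, seed=3, error_rate=0.0)
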