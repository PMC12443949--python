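"""Run schema-constrained extraction end to end with the mock backend.

The mock backend is a deterministic stand-in for a local model server: it
serializes the known truth in the grammar's language and injects seeded
per-label errors, so pipeline behavior can be studied without a GPU.
Swap in ``HttpBackend("http://localhost:8080/completion")`` to talk to a
real llama.cpp server with the same code.
"""

import clinext as cx

schema = cx.tnm_schema()
cases = cx.generate_tnm_reports(n=20, seed=3)
docs = [c.document for c in cases]
chunks = [ch for d in docs for ch in cx.split_document(d)]

backend = cx.MockBackend(
    schema, cx.truth_mapping(cases), error_rate=0.1, seed=7
)
template = cx.PromptTemplate(
    "Extract the TNM stage, the lymph node counts, the resection margin "
    "status and lymphatic invasion. This is the report: {report}"
)

frame, manifest, results = cx.run_extraction(
    docs, chunks, schema, template, backend
)
print(frame.head(5).to_string(index=False))
print("status counts:", manifest["status_counts"])
# One row per document; a 10% per-label error rate means roughly one value
# in ten differs from the planted truth, and the run manifest records the
# prompt, grammar, sampling settings and backend so the run is auditable.
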