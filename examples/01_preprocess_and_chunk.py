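"""Ingest a small tabular corpus and split it into context-window chunks.

Documents arrive as an id/report table; long reports are split into
contiguous character chunks (default 14,000 characters, cut at whitespace)
whose concatenation reproduces the original text exactly.
"""

import tempfile
from pathlib import Path

import clinext as cx

with tempfile.TemporaryDirectory() as td:
    corpus_csv = Path(td) / "corpus.csv"
    corpus_csv.write_text(
        "id,report\n"
        "r1,Short pathology note. pT2 pN0 M0.\n"
        f"r2,\"{'History of present illness. ' * 40}\"\n"
    )
    docs = cx.load_tabular_corpus(corpus_csv)
    print(f"loaded {len(docs)} documents: {[d.id for d in docs]}")

    for doc in docs:
        chunks = cx.split_document(doc, split_size=300)
        rebuilt = "".join(c.text for c in chunks)
        print(
            f"{doc.id}: {len(doc.text)} chars -> {len(chunks)} chunk(s), "
            f"round trip exact: {rebuilt == doc.text}"
        )

    # the preprocessed bundle is the hand-off artifact to extraction
    all_chunks = [c for d in docs for c in cx.split_document(d, 300)]
    bundle = Path(td) / "bundle.zip"
    cx.build_preprocessed_bundle(docs, all_chunks, bundle, split_size=300)
    rdocs, rchunks = cx.read_preprocessed_bundle(bundle)
    print(
        f"bundle round trip: {len(rdocs)} documents, {len(rchunks)} chunks, "
        f"identical: {rchunks == all_chunks}"
    )

# Each chunk records 0-based [start, end) offsets into its document, so
# downstream annotation spans and redaction masks stay aligned.
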