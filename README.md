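# clinext

Schema-constrained information extraction and de-identification for
clinical free text, with character-wise and label-wise evaluation.

## The problem

Clinical documents — discharge letters, pathology reports — carry
structured facts (TNM stage, symptom presence, lymph-node counts) and
protected identifiers (names, dates of birth, patient ids) buried in free
text. Extracting the facts with a local large language model is attractive
for privacy, but raw LLM output is not reliably parseable, and both the
extraction and any redaction built on it need quantitative evaluation
before anyone should trust them.

`clinext` implements that pipeline as a library:

1. **Corpus ingestion and chunking** — CSV/XLSX tables (`id`, `report`
   columns), TXT files, or PDFs through a pluggable OCR adapter; documents
   are split into contiguous character chunks (default 14,000 characters,
   cut at whitespace) whose concatenation reproduces the input exactly.
2. **Declarative schemas compiled to grammars** — each label has a kind
   (`string`, `boolean`, `categorical`, `number`) and constraints; a schema
   compiles to a JSON schema and to a GBNF grammar (llama.cpp dialect)
   whose language is exactly the set of single-line JSON objects the
   schema permits. Constrained decoding against that grammar guarantees
   parseable output; a built-in recognizer decides language membership for
   testing and auditing.
3. **Pluggable completion backends** — an HTTP client for the llama.cpp
   server wire format, and a deterministic seeded mock that emits
   grammar-valid records with controlled per-label error injection, so the
   whole pipeline is testable at desk scale without a model.
4. **Anonymization** — extracted identifier values are redacted by exact
   substring matching (case-insensitive by default), one mask glyph per
   character so offsets are preserved; evaluation classifies every
   character as TP/FP/TN/FN against gold annotation spans and reports
   accuracy, precision, recall (sensitivity), specificity, F1, FPR and FNR,
   per label, pooled, and macro-averaged over documents.
5. **Label evaluation** — extraction results are compared to a
   ground-truth table; booleans get pooled confusion metrics, categoricals
   a gold-by-predicted confusion matrix with macro one-vs-rest F1,
   numbers/strings an exact-match fraction after normalization; the
   overall accuracy is the micro average over (document, label) pairs.
6. **Synthetic fixtures** — seeded generators for fictitious
   pulmonary-embolism letters (planted identifier spans, symptom booleans,
   embolism side, optional provider/patient surname collisions) and
   TCGA-style colorectal pathology reports (explicit TNM, node counts,
   margins, optional conflicting statements and OCR lookalike noise),
   plus a regex TNM keyword baseline for comparison.

## Worked example

```python
import clinext as cx
from clinext.fixtures import IDENTIFIER_LABELS

schema = cx.pe_schema()
cases = cx.generate_pe_letters(n=8, seed=1)
docs = [c.document for c in cases]
chunks = [ch for d in docs for ch in cx.split_document(d)]
backend = cx.MockBackend(schema, cx.truth_mapping(cases), error_rate=0.0)
template = cx.PromptTemplate("Extract identifiers. Report: {report}")
_, _, results = cx.run_extraction(docs, chunks, schema, template, backend)

masks = {}
for doc, result in zip(docs, results):
    identifiers = cx.collect_identifiers(result, IDENTIFIER_LABELS)
    masks[doc.id], redacted = cx.redact_text(doc, identifiers)
spans = [s for c in cases for s in c.gold_spans]
table = cx.evaluate_anonymization(docs, masks, spans, list(IDENTIFIER_LABELS))
pooled = table[(table.doc_id == "__pooled__") & (table.label == "ALL")].iloc[0]
print(f"recall={pooled.recall:.4f} specificity={pooled.specificity:.4f} "
      f"precision={pooled.precision:.4f}")
```

prints

```
recall=1.0000 specificity=1.0000 precision=1.0000
```

meaning every planted identifier character was redacted (recall 1.0), no
non-identifier character was touched (specificity and precision 1.0).
Re-running with `collision_rate=1.0` — every letter signed by a provider
who shares the patient's surname — prints

```
recall=1.0000 specificity=0.9901 precision=0.8977
```

recall holds (exact matching cannot miss a planted occurrence) but
precision pays exactly the provider-surname characters, the structural
failure mode of exact-string redaction. The `examples/` directory walks
through each capability the same way: chunking (`01`), grammars (`02`),
mock extraction (`03`), anonymization (`04`), label metrics (`05`) and the
keyword baseline under OCR noise (`06`).

A thin CLI wraps the same functions:

```bash
clinext fixtures tnm --n 100 --seed 3 --out fx
clinext preprocess --input fx/corpus.csv --out bundle.zip
clinext extract --bundle bundle.zip --schema fx/schema.csv \
    --prompt prompt.txt --backend mock --truth fx/ground_truth.csv \
    --seed 1 --out results.csv
clinext eval-labels --results results.csv --gold fx/ground_truth.csv \
    --schema fx/schema.csv --kinds confirmed --out metrics.zip
```

## Documentation

`docs/methods.md` describes the models and conventions in detail: the
grammar language and recognizer, the mock backend's error model, the
character-wise evaluation definitions, the synthetic-data generators and
what passing tests do and do not establish about real clinical data.
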