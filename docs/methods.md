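# Methods

This note documents the models, conventions and design choices behind
`clinext`, in the order the pipeline runs.

## Documents, offsets and chunking

A `Document` is a unique id plus Unicode text. Ingestion performs no
normalization beyond unifying newlines to `"\n"`: character-wise
evaluation and annotation spans require stable offsets, so anything more
aggressive (whitespace collapsing, Unicode normalization) would corrupt
gold alignments. All offsets throughout the package are 0-based half-open
and count Unicode code points, not bytes.

`split_document` cuts a document into contiguous chunks of at most
`split_size` characters (default 14,000, sized for common local-LLM
context windows and adjustable per run). With the default `whitespace`
boundary policy each cut is placed just after the last whitespace inside
the window when one exists, so words are not bisected; a window with no
whitespace falls back to a hard cut. Because chunks store exact offsets
and their texts concatenate to the original, the policy affects extraction
quality only, never fidelity: the split/concatenate round trip is exact
for arbitrary input and any `split_size ≥ 1`, which the suite verifies
property-style.

The preprocessed bundle (ZIP with one text file per document plus
`manifest.csv`) is validated on load: chunk contiguity, offset/text
agreement and full coverage are all checked, so a corrupted manifest fails
loudly rather than silently shifting every downstream offset.

PDF ingestion accepts any callable OCR adapter (`bytes -> text`); without
one, a minimal reader extracts the text layer of simple (uncompressed or
Flate-compressed) PDFs and raises an explicit "OCR required" error for
image-only files. The adapter name is recorded in provenance so runs with
different OCR engines remain distinguishable.

## Extraction schemas and the output grammar

A schema is an ordered list of labels with kinds `string`, `boolean`,
`categorical` or `number`. Order matters: it fixes the key order of output
objects and the column order of result tables, which keeps outputs
diff-stable across runs.

The compiled GBNF grammar describes exactly the single-line JSON objects
with the schema's keys in schema order:

* booleans are `true|false`;
* categoricals are one of the quoted category literals, with `"` and `\`
  escaped (escaping is involutive: category → literal → parsed value is
  the identity for printable strings);
* strings are 0..`max_length` characters excluding raw control characters
  and unescaped quotes, with only `\"` and `\\` as escapes — keeping
  outputs single-line and CSV-safe;
* numbers are **quoted digit strings** of length ≤ `max_length` with at
  most one decimal point. The constraint the schema expresses is a
  character budget, not numeric range; parsed values are normalized by
  stripping leading zeros (`"017"` → 17). This deliberately excludes
  scientific notation and signs, which have no place in counts and stages.

Exactly zero or one space is permitted after each `:` and `,`; no other
whitespace is in the language. The bounded language keeps the recognizer
total and fast. Key-order permutations are excluded by construction — a
permutation-tolerant grammar would be exponentially larger and the decoder
gains nothing from the freedom.

The recognizer parses the GBNF dialect (literals with escapes, character
classes and ranges, negation, grouping, alternation, `? * +` and bounded
repetition, non-recursive rule references) and decides membership by a
descent over sets of input positions memoized on (rule, position). For the
non-recursive grammars the compiler emits this is polynomial and total;
recursive or otherwise unsupported grammars raise an explicit error rather
than risking unsoundness. The test suite checks language equivalence
against an independent oracle (JSON parse + direct constraint checks +
a surface scan for padding/escape rules) on randomized schemas, valid
records, single-character mutants and garbage strings.

Model output parsing is deliberately more lenient than the grammar (it
accepts any JSON key order and padding): the grammar governs generation,
the parser accepts anything semantically valid, and all parse failures are
recoverable per-chunk records rather than aborts.

## Backends

`HttpBackend` speaks the llama.cpp server completion wire format — POST of
`{prompt, grammar, temperature, n_predict, seed}` — with configurable
retries and exponential backoff; a response flagged as stopped at the
token limit maps to `finish_reason="length"`, which the engine records as
a truncated (failed) chunk rather than trusting a cut-off record.
Temperature defaults to 0: extraction wants determinism; it is a plain
config field for anyone who disagrees.

`MockBackend` is the desk-scale stand-in for the model. Given per-document
truth it serializes each record in the grammar's own language, then with
probability `error_rate` per label perturbs the value kind-preservingly:
boolean flip, categorical resample among the other categories, number ±1
(reflected at zero and at the length budget), string character drop. The
decision and the perturbation derive from a SHA-256 hash of
`(seed, doc_id, label)`, so outputs are byte-identical across runs and
platforms and independent of document processing order. Because
perturbations preserve kind, every mock output — corrupted or not — stays
inside the grammar's language; dedicated switches produce non-JSON or
truncated outputs for failure-path testing.

## Extraction engine

Prompts are plain text with exactly one `{report}` placeholder replaced by
the chunk text, everything else byte-identical. Per-chunk records carry
status `ok | parse_error | backend_error | truncated`; a failure in one
document never affects another (verified by a corruption test that diffs
whole result tables).

`MISSING` is a first-class sentinel distinct from the empty string:
"the pipeline produced no value" and "the model answered an empty string"
are different facts and evaluation treats them differently. In results
CSVs it serializes as `__missing__`.

Multi-chunk documents are reconciled by a merge policy: `first_answer`
(default — most reports fit one chunk, and headers carry the staging),
`majority` (modal value, ties to the earliest chunk) or `any_positive`
(booleans true iff any chunk says true). Disagreeing chunks are always
flagged in the `conflicts` column regardless of policy, and the run
manifest records which policy was used along with prompt, grammar,
sampling settings, backend identity and status counts.

The TNM keyword baseline matches explicit stage tokens (`T0–T4/Tis/Tx`
with optional `a–c` substage, `N0–N3/Nx`, `M0/M1/Mx`, optional `p`/`yp`
pathological prefix which is stripped from the reported value, first match
per axis wins). It exists as a falsifiable comparison point: perfect where
stages are spelled out, blind where they are implied or corrupted.

## Anonymization and character-wise evaluation

Redaction is exact substring matching of the extracted identifier values,
case-insensitive by default (clinical letters mix "MILLER" and "Miller";
a switch restores case sensitivity). Values shorter than 2 characters and
sentinel answers ("not mentioned", empty) are excluded — a one-letter sex
code would mask arbitrary text. Each masked character is replaced by one
mask glyph, so document length, layout and every other offset survive.

Evaluation marks a gold vector from annotation spans and counts per
character: TP (masked, gold), FP (masked, not gold), FN (unmasked, gold),
TN (the rest); the four always sum to the document length. When evaluation
is restricted to one identifier label, FP counts only characters outside
*every* gold label: redacting a first name while scoring last-name
precision is not an error. The pooled ("all labels") evaluation uses the
union of all gold spans and sums counts over documents; macro averaging
takes the unweighted mean of per-document metrics. Zero-denominator
metrics are UNDEFINED (`None`), excluded from macro averages with a
reported skip count — imputing 0 or 1 would bias small-document averages.

Two structural properties follow and are tested: exact-match redaction of
the true surface forms cannot miss a planted occurrence (recall 1.0), and
a non-patient occurrence of a gold surface form (the provider-surname
collision) lowers precision by exactly its character count over (tp+fp)
while recall is unaffected.

Annotation ground truth is a ZIP of per-document JSON files (`label`,
`begin`, `end`, `covered_text`), validated against the documents on load;
this minimal span dialect is the supported contract, with conversion from
richer annotation-platform exports left to the user.

## Label-wise evaluation

Values are normalized before comparison: booleans accept
`true/false`, `yes/no`, `1/0` case-insensitively; categoricals and strings
are trimmed, case-folded and internally whitespace-collapsed; numbers are
compared as decimals after stripping leading zeros and surrounding space,
exactly (counts are integers; no tolerance by default). Evaluation refuses
to run until the declared data types are explicitly confirmed, preventing
silently mistyped columns from skewing metrics.

A MISSING prediction counts as predicted-negative for booleans (gold-true
→ FN, gold-false → TN) and as a plain mismatch for every other kind; a
`skip` mode excludes such documents from the affected label instead.
Boolean labels report the full pooled metric set; categorical labels
report trace accuracy of the gold-by-predicted confusion matrix plus
macro one-vs-rest precision/recall/F1 over classes present in gold (the
averaging scheme is a documented choice — a single printed F1 for a
multi-class stage label requires one); number/string labels report the
match fraction. Overall accuracy is the micro average over all
(document, label) comparisons, so per-document failures are included, not
skipped. The metrics bundle ZIP contains the metrics table, confusion
matrices as CSV and rendered figures, a per-document gold-vs-predicted
comparison, and the input documents, supporting report-by-report review.

## Synthetic data

The generators emulate the study conditions, not real clinical language.

**Pulmonary-embolism letters** (default n=8): template sentences embed
first/last name, sex, age (consistent with the birth year), date of birth
and patient id — each occurrence recorded as a gold span — six symptom
booleans phrased positively or as explicit denials (negation gives the
boolean metrics FN/FP structure to exercise), and an embolism side. The
generator resamples deterministically until every identifier surface form
occurs only at its planted spans, so clean letters give exactly
precision = recall = specificity = 1.0 under exact-match redaction. With
`collision_rate` the signing provider shares the patient's surname; that
occurrence is deliberately not gold, reproducing the precision-only
deficit of exact-string redaction.

**TNM reports** (default n=100): explicit staging line (`pT3 pN1 M0`
style, `Tx/Nx/Mx` stated explicitly too), node counts with
`positive ≤ examined` and `N0 ⇒ 0 positive`, margin and lymphatic-invasion
statements with a three-valued truth (`true/false/not mentioned`, the
omitted-statement case included). `conflict_rate` plants either a
simultaneous "M0 Mx" (truth keeps the first-stated M0) or a margin
described as negative with carcinoma within 1 mm of the radial margin —
both flagged `conflicting_statement`.

**OCR noise** substitutes lookalike characters inside stage tokens
(1→:/I, 0→O, 2→Z, 3→B, 4→A, x→×), one token at a time with the given
probability. Substitutions are strictly 1:1 so all offsets — and therefore
all anonymizer tests — remain valid on noisy text; truth is unchanged
because the noise models transcription, not biology.

What passing tests show: the pipeline's arithmetic, determinism, grammar
guarantees and failure isolation hold under controlled conditions. What
they do not show: anything about a real model's extraction quality on real
clinical language — template letters have none of the abbreviation
density, copy-paste noise, negation subtlety or layout damage of genuine
reports, and the mock backend's independent per-label errors are far
kinder than correlated model failures.

## Problem sizes and numerical choices

The randomized suites run at sizes chosen to make the statistics
meaningful while keeping the whole test run fast on one CPU: 1,000 random
(document, mask, spans) triples for the metric-equivalence check, 200
random schemas with ~2,600 candidates for grammar equivalence, 500 texts
per split size for the chunking round trip, 500 reports for error-rate
recovery (binomial SE ≈ 0.013 at p=0.1, checked at 3 SE). Error-rate
recovery uses fixed seeds and asserts byte-identical reruns. Metric
comparisons against oracles are exact (same arithmetic, no tolerance);
only the stochastic recovery checks use statistical bands.

Known limitations: no fuzzy or date-format-generalizing redaction; no
nested objects or arrays in schemas; the HTTP backend exposes only
temperature and `n_predict` as first-class sampling knobs; the minimal
PDF reader handles simple text layers only; categorical macro-averaging
and micro overall accuracy are documented interpretations where several
defensible conventions exist.
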