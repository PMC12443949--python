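"""Corpus ingestion, document chunking, and the preprocessed bundle.

Clinical documents arrive as tabular files (CSV/XLSX with ``id`` and
``report`` columns), as individual TXT files named by their id, or as PDFs
handed to a pluggable OCR adapter.  Documents longer than a model's context
window are split into contiguous character chunks; chunk offsets are 0-based
half-open and count Unicode code points so that annotation spans and
redaction masks computed downstream stay aligned.

The preprocessed bundle is a ZIP archive holding one file per original
document plus a ``manifest.csv`` describing every chunk; it is the interface
between preprocessing and extraction.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
import zipfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import BundleError, CorpusError, IngestionWarning, OcrRequiredError

DEFAULT_SPLIT_SIZE = 14_000  # characters; sized for common LLM context windows


@dataclass(frozen=True)
class Document:
    """A clinical text with a unique identifier.

    ``text`` has newlines unified to ``"\\n"``; no other normalization is
    applied at ingestion so character offsets remain stable.
    """

    id: str
    text: str
    source_format: str = "txt"  # one of {csv, xlsx, txt, pdf}
    source_path: str = ""


@dataclass(frozen=True)
class Chunk:
    """A contiguous slice ``[start, end)`` of a document's text."""

    doc_id: str
    index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.text):
            raise BundleError(
                f"chunk {self.doc_id}[{self.index}]: offsets [{self.start},{self.end}) "
                f"disagree with text length {len(self.text)}"
            )


@dataclass(frozen=True)
class OcrAdapter:
    """Pluggable OCR contract: a named callable turning PDF bytes into text.

    The pipeline functions without any adapter for text-only inputs; the
    adapter name is recorded in provenance so runs with different OCR
    engines stay distinguishable.
    """

    name: str
    extract: Callable[[bytes], str]


def _unify_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise CorpusError(f"duplicate document ids: {dupes}")


def load_tabular_corpus(
    path: str | Path,
    id_column: str = "id",
    report_column: str = "report",
) -> list[Document]:
    """Read documents from a CSV or XLSX table, one row per document.

    Row order is preserved. Empty report cells yield a Document with empty
    text and an :class:`IngestionWarning` rather than an error.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such file: {path}")
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "xlsx":
        # first sheet only: the interface is a single id/report table
        df = pd.read_excel(path, dtype=str, keep_default_na=False)
    else:
        raise CorpusError(f"unsupported tabular format: {path.suffix!r}")
    if df.empty:
        raise CorpusError(f"empty corpus table: {path}")
    for col in (id_column, report_column):
        if col not in df.columns:
            raise CorpusError(f"missing required column {col!r} in {path}")
    ids = [str(v) for v in df[id_column]]
    if any(not i for i in ids):
        raise CorpusError(f"empty id value in {path}")
    _check_unique_ids(ids)
    docs = []
    for doc_id, report in zip(ids, df[report_column]):
        text = _unify_newlines(str(report))
        if not text:
            warnings.warn(
                f"document {doc_id!r} has an empty report", IngestionWarning
            )
        docs.append(Document(doc_id, text, fmt, str(path)))
    return docs


def load_text_files(
    paths: Iterable[str | Path], fallback_encoding: str | None = None
) -> list[Document]:
    """Read one document per TXT file; the filename stem is the id."""
    docs = []
    for p in map(Path, paths):
        raw = p.read_bytes()
        try:
            text = raw.decode("utf-8")
        except UnicodeDecodeError:
            if fallback_encoding is None:
                raise CorpusError(f"cannot decode {p} as UTF-8") from None
            try:
                text = raw.decode(fallback_encoding)
            except UnicodeDecodeError:
                raise CorpusError(
                    f"cannot decode {p} as UTF-8 or {fallback_encoding}"
                ) from None
        if not text:
            warnings.warn(f"file {p} is empty", IngestionWarning)
        docs.append(Document(p.stem, _unify_newlines(text), "txt", str(p)))
    _check_unique_ids([d.id for d in docs])
    return docs


# --- minimal PDF text-layer extraction -------------------------------------
# Reads uncompressed or Flate-compressed content streams and collects the
# string operands of Tj/TJ text-showing operators. Enough for digitally
# produced single-layer PDFs; scanned documents need an OCR adapter.

_STREAM_RE = re.compile(rb"stream\r?\n(.*?)endstream", re.DOTALL)
_TEXT_OP_RE = re.compile(rb"\(((?:[^()\\]|\\.)*)\)\s*(?:Tj|'|\")", re.DOTALL)
_TJ_ARRAY_RE = re.compile(rb"\[((?:[^\]\\]|\\.)*)\]\s*TJ", re.DOTALL)
_PAREN_RE = re.compile(rb"\(((?:[^()\\]|\\.)*)\)")

_PDF_ESCAPES = {
    b"n": b"\n", b"r": b"\r", b"t": b"\t", b"b": b"\b", b"f": b"\f",
    b"(": b"(", b")": b")", b"\\": b"\\",
}


def _unescape_pdf_string(raw: bytes) -> bytes:
    out = bytearray()
    i = 0
    while i < len(raw):
        c = raw[i : i + 1]
        if c == b"\\" and i + 1 < len(raw):
            nxt = raw[i + 1 : i + 2]
            if nxt in _PDF_ESCAPES:
                out += _PDF_ESCAPES[nxt]
                i += 2
                continue
            if nxt.isdigit():  # octal escape, up to 3 digits
                j = i + 1
                while j < min(i + 4, len(raw)) and raw[j : j + 1].isdigit():
                    j += 1
                out.append(int(raw[i + 1 : j], 8) & 0xFF)
                i = j
                continue
        out += c
        i += 1
    return bytes(out)


def extract_pdf_text_layer(data: bytes) -> str:
    """Extract the text layer of a simple PDF; empty string when none found."""
    pieces: list[bytes] = []
    for m in _STREAM_RE.finditer(data):
        stream = m.group(1)
        if b"Tj" not in stream and b"TJ" not in stream:
            try:
                stream = zlib.decompress(stream)
            except zlib.error:
                continue
        for sm in _TEXT_OP_RE.finditer(stream):
            pieces.append(_unescape_pdf_string(sm.group(1)))
        for am in _TJ_ARRAY_RE.finditer(stream):
            for pm in _PAREN_RE.finditer(am.group(1)):
                pieces.append(_unescape_pdf_string(pm.group(1)))
        if pieces:
            pieces.append(b"\n")
    return b"".join(pieces).decode("latin-1").strip()


def ingest_pdf(path: str | Path, adapter: OcrAdapter | None = None) -> Document:
    """Ingest one PDF; via the OCR adapter when given, else its text layer.

    Raises :class:`OcrRequiredError` for image-only PDFs without an adapter
    rather than silently producing an empty document.
    """
    path = Path(path)
    data = path.read_bytes()
    if adapter is not None and adapter.name != "none":
        text = adapter.extract(data)
        provenance = f"{path}#ocr={adapter.name}"
    else:
        text = extract_pdf_text_layer(data)
        if not text:
            raise OcrRequiredError(
                f"{path}: no extractable text layer; configure an OCR adapter"
            )
        provenance = f"{path}#ocr=none"
    return Document(path.stem, _unify_newlines(text), "pdf", provenance)


def split_document(
    doc: Document,
    split_size: int = DEFAULT_SPLIT_SIZE,
    boundary_policy: str = "whitespace",
) -> list[Chunk]:
    """Split a document into contiguous chunks of at most ``split_size`` chars.

    With ``boundary_policy="whitespace"`` each cut is placed just after the
    last whitespace inside the window when one exists, avoiding mid-word
    cuts; otherwise (or when a window holds no whitespace) the cut is hard.
    Concatenating the chunk texts always reproduces the document exactly.
    """
    if split_size < 1:
        raise ValueError(f"split_size must be >= 1, got {split_size}")
    if boundary_policy not in ("hard", "whitespace"):
        raise ValueError(f"unknown boundary_policy: {boundary_policy!r}")
    text = doc.text
    if text == "":
        warnings.warn(f"document {doc.id!r} is empty", IngestionWarning)
        return [Chunk(doc.id, 0, 0, 0, "")]
    chunks = []
    start = 0
    while start < len(text):
        end = min(start + split_size, len(text))
        if end < len(text) and boundary_policy == "whitespace":
            window = text[start:end]
            ws_positions = [i for i, c in enumerate(window) if c.isspace()]
            if ws_positions:
                cut = ws_positions[-1] + 1  # keep the whitespace in this chunk
                if cut > 0:
                    end = start + cut
        chunks.append(Chunk(doc.id, len(chunks), start, end, text[start:end]))
        start = end
    return chunks


MANIFEST_COLUMNS = [
    "id", "chunk_index", "start", "end", "text",
    "source_format", "ocr_engine", "split_size",
]


def build_preprocessed_bundle(
    docs: Sequence[Document],
    chunks: Sequence[Chunk],
    out_path: str | Path,
    split_size: int = DEFAULT_SPLIT_SIZE,
    ocr_engine: str = "none",
) -> Path:
    """Write the preprocessed ZIP: one text file per document + manifest.csv."""
    out_path = Path(out_path)
    doc_ids = {d.id for d in docs}
    for c in chunks:
        if c.doc_id not in doc_ids:
            raise BundleError(f"chunk references unknown document {c.doc_id!r}")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(MANIFEST_COLUMNS)
    fmt = {d.id: d.source_format for d in docs}
    for c in chunks:
        writer.writerow(
            [c.doc_id, c.index, c.start, c.end, c.text,
             fmt[c.doc_id], ocr_engine, split_size]
        )
    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for d in docs:
            zf.writestr(f"documents/{d.id}.txt", d.text)
        zf.writestr("manifest.csv", buf.getvalue())
    return out_path


def read_preprocessed_bundle(path: str | Path) -> tuple[list[Document], list[Chunk]]:
    """Read a bundle back, validating every chunk invariant on load."""
    with zipfile.ZipFile(path) as zf:
        names = zf.namelist()
        if "manifest.csv" not in names:
            raise BundleError(f"{path}: bundle has no manifest.csv")
        texts = {}
        for n in names:
            if n.startswith("documents/") and n.endswith(".txt"):
                texts[Path(n).stem] = zf.read(n).decode("utf-8")
        manifest = pd.read_csv(
            io.StringIO(zf.read("manifest.csv").decode("utf-8")),
            dtype={"id": str, "text": str}, keep_default_na=False,
        )
    docs = []
    chunks = []
    for doc_id, grp in manifest.groupby("id", sort=False):
        if doc_id not in texts:
            raise BundleError(f"manifest references missing document {doc_id!r}")
        text = texts[doc_id]
        docs.append(
            Document(doc_id, text, str(grp.iloc[0]["source_format"]), str(path))
        )
        grp = grp.sort_values("chunk_index")
        expected_start = 0
        for _, row in grp.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if start != expected_start:
                raise BundleError(
                    f"document {doc_id!r}: chunk {int(row['chunk_index'])} starts at "
                    f"{start}, expected {expected_start} (overlap or gap)"
                )
            ctext = str(row["text"])
            if text[start:end] != ctext:
                raise BundleError(
                    f"document {doc_id!r}: chunk {int(row['chunk_index'])} text does "
                    f"not match offsets [{start},{end})"
                )
            chunks.append(Chunk(doc_id, int(row["chunk_index"]), start, end, ctext))
            expected_start = end
        if expected_start != len(text):
            raise BundleError(
                f"document {doc_id!r}: chunks cover [0,{expected_start}) but text "
                f"has length {len(text)}"
            )
    return docs, chunks
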