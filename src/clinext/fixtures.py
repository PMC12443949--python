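"""Seeded synthetic corpora with known ground truth.

Two fixture families mirror the study conditions the rest of the package is
tested under, without shipping any real clinical text:

* fictitious pulmonary-embolism discharge letters with planted personal
  identifiers (recorded as gold character spans), six symptom booleans
  phrased positively or as explicit denials, and an embolism side; an
  optional name-collision scenario makes the treating provider share the
  patient's surname, the classic exact-match-redaction precision trap;
* TCGA-style colorectal pathology reports with explicit TNM stages, lymph
  node counts, margin and lymphatic-invasion statements, plus optional
  conflicting statements ("M0 Mx") and OCR lookalike noise on stage tokens.

Everything is deterministic given the seed.  Identifier letters are
resampled until every identifier surface form occurs in the text only at
its planted spans, so exact-string redaction of the true identifiers is
character-for-character identical to the gold annotation (except for the
deliberate provider collision, which is left out of gold on purpose).
"""

from __future__ import annotations

import csv
import json
import random
import re
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .anonymize import AnnotatedSpan, redact_text
from .corpus import Document
from .schema import ExtractionSchema, LabelSpec, validate_schema


@dataclass(frozen=True)
class SyntheticCase:
    document: Document
    truth: dict[str, Any]
    gold_spans: tuple[AnnotatedSpan, ...]
    scenario_flags: frozenset[str] = frozenset()


IDENTIFIER_LABELS = (
    "first_name", "last_name", "sex", "age", "date_of_birth", "patient_id",
)

SYMPTOM_LABELS = (
    "shortness_of_breath", "chest_pain", "leg_pain_or_swelling",
    "heart_palpitations", "cough", "dizziness",
)

_SYMPTOM_PHRASES = {
    "shortness_of_breath": "shortness of breath",
    "chest_pain": "chest pain",
    "leg_pain_or_swelling": "leg pain and swelling",
    "heart_palpitations": "heart palpitations",
    "cough": "a persistent cough",
    "dizziness": "dizziness",
}

_FIRST_NAMES = (
    "Greta", "Jonas", "Felix", "Clara", "Henrik", "Paula",
    "Tobias", "Miriam", "Oskar", "Annika", "Bruno", "Celine",
)
_LAST_NAMES = (
    "Miller", "Weber", "Fischer", "Schneider", "Wagner", "Becker",
    "Hoffman", "Schulz", "Koenig", "Brandt", "Vogel", "Krause",
)


def pe_schema() -> ExtractionSchema:
    """Schema for the pulmonary-embolism letters: identifiers + symptoms + side."""
    return validate_schema(
        [
            LabelSpec("first_name", "string", max_length=20),
            LabelSpec("last_name", "string", max_length=20),
            LabelSpec("sex", "categorical", ("male", "female")),
            LabelSpec("age", "number", max_length=3),
            LabelSpec("date_of_birth", "string", max_length=10),
            LabelSpec("patient_id", "string", max_length=12),
            *[LabelSpec(s, "boolean") for s in SYMPTOM_LABELS],
            LabelSpec("embolism_side", "categorical", ("left", "right", "bilateral")),
        ]
    )


def tnm_schema() -> ExtractionSchema:
    """Schema for the colorectal pathology reports (TNM + nodes + margins)."""
    return validate_schema(
        [
            LabelSpec("t_stage", "categorical", ("T1", "T2", "T3", "T4", "Tx")),
            LabelSpec("n_stage", "categorical", ("N0", "N1", "N2", "Nx")),
            LabelSpec("m_stage", "categorical", ("M0", "M1", "Mx")),
            LabelSpec("nodes_examined", "number", max_length=3),
            LabelSpec("nodes_positive", "number", max_length=3),
            LabelSpec("margin_free", "categorical", ("true", "false", "not mentioned")),
            LabelSpec(
                "lymphatic_invasion", "categorical", ("true", "false", "not mentioned")
            ),
        ]
    )


class _TextBuilder:
    """Accumulates text while recording the offsets of annotated pieces."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0
        self.spans: list[AnnotatedSpan] = []

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.length += len(text)

    def add_span(self, label: str, text: str) -> None:
        self.spans.append(
            AnnotatedSpan(self.doc_id, label, self.length, self.length + len(text), text)
        )
        self.add(text)

    def build(self) -> tuple[str, tuple[AnnotatedSpan, ...]]:
        return "".join(self.parts), tuple(self.spans)


def _letter_once(
    doc_id: str, rng: random.Random, collide: bool
) -> tuple[SyntheticCase, tuple[int, int] | None]:
    first = rng.choice(_FIRST_NAMES)
    last = rng.choice(_LAST_NAMES)
    sex = rng.choice(("male", "female"))
    birth_year = rng.randint(1940, 1990)
    age = 2024 - birth_year
    dob = f"{birth_year}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    pid = f"PID-{rng.randint(100000, 999999)}"
    provider_first = rng.choice(_FIRST_NAMES)
    while provider_first == first:
        provider_first = rng.choice(_FIRST_NAMES)
    if collide:
        provider_last = last
    else:
        provider_last = rng.choice(_LAST_NAMES)
        while provider_last == last:
            provider_last = rng.choice(_LAST_NAMES)
    symptoms = {s: rng.random() < 0.5 for s in SYMPTOM_LABELS}
    side = rng.choice(("left", "right", "bilateral"))

    b = _TextBuilder(doc_id)
    b.add("Patient: ")
    b.add_span("first_name", first)
    b.add(" ")
    b.add_span("last_name", last)
    b.add("\nDate of birth: ")
    b.add_span("date_of_birth", dob)
    b.add("\nPatient ID: ")
    b.add_span("patient_id", pid)
    b.add("\nSex: ")
    b.add_span("sex", sex)
    b.add("\n\nDear colleague,\n\nwe report on our mutual patient ")
    b.add_span("first_name", first)
    b.add(" ")
    b.add_span("last_name", last)
    b.add(", a ")
    b.add_span("age", str(age))
    b.add("-year-old ")
    b.add_span("sex", sex)
    b.add(" patient who presented to our emergency department.\n")
    for s in SYMPTOM_LABELS:
        phrase = _SYMPTOM_PHRASES[s]
        if symptoms[s]:
            b.add(f"The patient reported {phrase}.\n")
        else:
            b.add(f"The patient explicitly denied {phrase}.\n")
    if side == "bilateral":
        b.add("Computed tomography angiography demonstrated bilateral pulmonary embolism.\n")
    else:
        b.add(
            f"Computed tomography angiography demonstrated a {side}-sided "
            "pulmonary embolism.\n"
        )
    b.add(
        "Therapeutic anticoagulation was initiated and the further course "
        "was uneventful.\n\nKind regards,\nDr. "
    )
    b.add(provider_first)
    b.add(" ")
    provider_span_start = b.length
    b.add(provider_last)
    provider_span = (provider_span_start, b.length)
    b.add("\n")
    text, spans = b.build()

    truth: dict[str, Any] = {
        "first_name": first, "last_name": last, "sex": sex, "age": age,
        "date_of_birth": dob, "patient_id": pid,
        **symptoms, "embolism_side": side,
    }
    flags = frozenset({"name_collision"}) if collide else frozenset()
    case = SyntheticCase(
        Document(doc_id, text, "txt", "synthetic"), truth, spans, flags
    )
    return case, (provider_span if collide else None)


def _identifiers_clean(case: SyntheticCase, provider_span) -> bool:
    """True iff redacting the true identifiers masks exactly the gold spans
    (plus the provider surname in the collision scenario)."""
    identifiers = {
        str(case.truth[l]) for l in IDENTIFIER_LABELS
    }
    mask, _ = redact_text(case.document, identifiers)
    expected = np.zeros(len(case.document.text), dtype=bool)
    for s in case.gold_spans:
        expected[s.start : s.end] = True
    if provider_span is not None:
        expected[provider_span[0] : provider_span[1]] = True
    return bool(np.array_equal(mask.mask, expected))


def generate_pe_letters(
    n: int = 8, seed: int = 0, collision_rate: float = 0.0
) -> list[SyntheticCase]:
    """Generate fictitious pulmonary-embolism letters with gold spans.

    ``collision_rate`` is the probability that the provider signing a letter
    shares the patient's surname; that occurrence is intentionally NOT a
    gold span, so it produces exactly one false-positive run under
    exact-match redaction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    cases = []
    for i in range(n):
        doc_id = f"pe-{i + 1:03d}"
        collide = rng.random() < collision_rate
        for _ in range(200):
            case, provider_span = _letter_once(doc_id, rng, collide)
            if _identifiers_clean(case, provider_span):
                break
        else:  # pragma: no cover - pools make clean letters easy to find
            raise RuntimeError(f"could not build a collision-free letter for {doc_id}")
        cases.append(case)
    return cases


def generate_tnm_reports(
    n: int = 100, seed: int = 0, conflict_rate: float = 0.0
) -> list[SyntheticCase]:
    """Generate pathology-style reports with explicit TNM statements.

    With probability ``conflict_rate`` a report carries a conflicting
    statement: either "M0 Mx" stated together (truth keeps the first,
    M0), or a margin described as negative with tumor within 1 mm of the
    radial margin.  Conflicted cases get the ``conflicting_statement`` flag.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    cases = []
    for i in range(n):
        doc_id = f"tnm-{i + 1:04d}"
        t = rng.choice(("T1", "T2", "T3", "T4", "Tx"))
        nst = rng.choice(("N0", "N1", "N2", "Nx"))
        m = rng.choice(("M0", "M1", "Mx"))
        examined = rng.randint(5, 40)
        positive = rng.randint(0, examined if nst not in ("N0",) else 0)
        margin = rng.choice(("true", "false", "not mentioned"))
        lymph = rng.choice(("true", "false", "not mentioned"))
        flags: set[str] = set()
        conflict_kind = None
        if rng.random() < conflict_rate:
            conflict_kind = rng.choice(("m_stage", "margin"))
            flags.add("conflicting_statement")
            if conflict_kind == "m_stage":
                m = "M0"
            else:
                margin = "true"
        lines = [
            f"Histopathology report {doc_id}.",
            "Specimen: colorectal resection.",
            "Diagnosis: adenocarcinoma of the colon.",
        ]
        if conflict_kind == "m_stage":
            lines.append(f"Staging: p{t} p{nst} M0 Mx.")
        else:
            lines.append(f"Staging: p{t} p{nst} {m}.")
        lines.append(
            f"Lymph nodes examined: {examined}. Lymph nodes positive: {positive}."
        )
        if conflict_kind == "margin":
            lines.append(
                "The resection margin is negative (carcinoma less than 1 mm "
                "from the radial margin)."
            )
        elif margin == "true":
            lines.append("The resection margin is tumor free.")
        elif margin == "false":
            lines.append("The resection margin is infiltrated by carcinoma.")
        if lymph == "true":
            lines.append("Lymphatic invasion is present.")
        elif lymph == "false":
            lines.append("No lymphatic invasion is identified.")
        text = "\n".join(lines) + "\n"
        truth = {
            "t_stage": t, "n_stage": nst, "m_stage": m,
            "nodes_examined": examined, "nodes_positive": positive,
            "margin_free": margin, "lymphatic_invasion": lymph,
        }
        cases.append(
            SyntheticCase(
                Document(doc_id, text, "txt", "synthetic"),
                truth, (), frozenset(flags),
            )
        )
    return cases


# 1:1 character lookalike confusions, as an OCR engine would make them on
# low-quality scans; 1:1 substitution keeps all character offsets valid.
OCR_CONFUSIONS: dict[str, tuple[str, ...]] = {
    "1": (":", "I"),
    "0": ("O",),
    "2": ("Z",),
    "3": ("B",),
    "4": ("A",),
    "x": ("×",),  # multiplication sign
    "X": ("×",),
}

_STAGE_TOKEN_RE = re.compile(r"\b(?:y?p)?[TNM](?:[0-4]|is|x|X)[a-c]?\b")


def inject_ocr_noise(
    case: SyntheticCase, rate: float, seed: int = 0
) -> SyntheticCase:
    """Corrupt stage tokens with lookalike character substitutions.

    Each stage token is independently corrupted with probability ``rate``;
    one confusable character inside it is replaced by a lookalike.  Truth
    and gold spans are unchanged — the noise models transcription, not
    biology — and offsets are preserved because substitutions are 1:1.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = random.Random(f"{seed}|{case.document.id}")
    text = list(case.document.text)
    changed = False
    for m in _STAGE_TOKEN_RE.finditer(case.document.text):
        if rng.random() >= rate:
            continue
        positions = [
            i for i in range(m.start(), m.end()) if text[i] in OCR_CONFUSIONS
        ]
        if not positions:
            continue
        pos = rng.choice(positions)
        text[pos] = rng.choice(OCR_CONFUSIONS[text[pos]])
        changed = True
    if not changed:
        if rate == 0:
            return case
        return replace(case, scenario_flags=case.scenario_flags | {"ocr_noise"})
    doc = Document(
        case.document.id, "".join(text), case.document.source_format,
        case.document.source_path,
    )
    return SyntheticCase(
        doc, dict(case.truth), case.gold_spans,
        case.scenario_flags | {"ocr_noise"},
    )


def truth_mapping(cases: Sequence[SyntheticCase]) -> dict[str, dict[str, Any]]:
    """The doc_id → truth mapping the mock backend consumes."""
    return {c.document.id: dict(c.truth) for c in cases}


def export_fixture_bundle(
    cases: Sequence[SyntheticCase],
    out_dir: str | Path,
    schema: ExtractionSchema,
) -> dict[str, Path]:
    """Write the interfaces the pipeline consumes: corpus CSV (id/report),
    ground-truth CSV (id + label columns) and the annotation-span ZIP."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus_path = out_dir / "corpus.csv"
    truth_path = out_dir / "ground_truth.csv"
    spans_path = out_dir / "annotations.zip"

    with open(corpus_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "report"])
        for c in cases:
            writer.writerow([c.document.id, c.document.text])

    with open(truth_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *schema.names])
        for c in cases:
            row = [c.document.id]
            for name in schema.names:
                v = c.truth[name]
                if isinstance(v, bool):
                    row.append("true" if v else "false")
                else:
                    row.append(str(v))
            writer.writerow(row)

    with zipfile.ZipFile(spans_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for c in cases:
            entries = [
                {
                    "label": s.label, "begin": s.start, "end": s.end,
                    "covered_text": s.covered_text,
                }
                for s in c.gold_spans
            ]
            zf.writestr(f"{c.document.id}.json", json.dumps(entries, indent=1))

    return {"corpus": corpus_path, "ground_truth": truth_path, "spans": spans_path}
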