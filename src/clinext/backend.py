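"""Completion backends: the llama.cpp-server HTTP client and a seeded mock.

Both implementations satisfy one contract — ``complete(request, context)``
returning a :class:`CompletionResult` — selected by configuration, so the
extraction engine is agnostic to whether a local model server or a
deterministic stand-in produces the text.

The mock backend emits records serialized in the schema grammar's own
language and injects controlled, per-label errors.  It is deterministic
given (seed, doc_id, label): the error decision and the perturbed value are
derived from a SHA-256 hash of those three, so reruns are byte-identical
across platforms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Any, Mapping

from .errors import BackendError
from .gbnf import GrammarText
from .schema import ExtractionSchema, serialize_record

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationConfig:
    """Sampling settings; temperature 0 by default for deterministic IE."""

    model_id: str = ""
    temperature: float = 0.0
    n_predict: int = 512  # token budget; under-budgeting truncates output
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.n_predict < 1:
            raise ValueError("n_predict must be >= 1")


@dataclass(frozen=True)
class CompletionRequest:
    prompt: str
    grammar: GrammarText | None = None
    config: GenerationConfig = field(default_factory=GenerationConfig)

    def __post_init__(self) -> None:
        if not self.prompt:
            raise ValueError("prompt must be non-empty")


@dataclass(frozen=True)
class CompletionResult:
    text: str
    finish_reason: str = "stop"  # stop | length | error
    tokens_predicted: int | None = None
    duration_s: float | None = None


class HttpBackend:
    """Client for the llama.cpp server completion endpoint.

    POSTs ``{prompt, grammar, temperature, n_predict, seed}`` as JSON and
    maps the response to a :class:`CompletionResult`; ``stopped_limit`` in
    the response marks truncation. Failures are retried with exponential
    backoff before a :class:`BackendError` is raised.
    """

    name = "http"

    def __init__(
        self,
        endpoint: str,
        retries: int = 2,
        timeout: float = 120.0,
        backoff: float = 0.5,
    ):
        self.endpoint = endpoint
        self.retries = retries
        self.timeout = timeout
        self.backoff = backoff

    def complete(
        self, request: CompletionRequest, context: Mapping[str, Any] | None = None
    ) -> CompletionResult:
        payload: dict[str, Any] = {
            "prompt": request.prompt,
            "temperature": request.config.temperature,
            "n_predict": request.config.n_predict,
        }
        if request.grammar is not None:
            payload["grammar"] = request.grammar.text
        if request.config.seed is not None:
            payload["seed"] = request.config.seed
        body = json.dumps(payload).encode("utf-8")
        last_error: Exception | None = None
        for attempt in range(self.retries + 1):
            t0 = time.monotonic()
            try:
                req = urllib.request.Request(
                    self.endpoint,
                    data=body,
                    headers={"Content-Type": "application/json"},
                    method="POST",
                )
                logger.debug("POST %s attempt %d", self.endpoint, attempt + 1)
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    if not 200 <= resp.status < 300:
                        raise BackendError(f"HTTP {resp.status} from {self.endpoint}")
                    data = json.loads(resp.read().decode("utf-8"))
                if "content" not in data:
                    raise BackendError("malformed server response: no 'content'")
                truncated = bool(data.get("stopped_limit"))
                return CompletionResult(
                    text=str(data["content"]),
                    finish_reason="length" if truncated else "stop",
                    tokens_predicted=data.get("tokens_predicted"),
                    duration_s=time.monotonic() - t0,
                )
            except (urllib.error.URLError, OSError, json.JSONDecodeError,
                    BackendError) as exc:
                last_error = exc
                logger.warning("completion attempt %d failed: %s", attempt + 1, exc)
                if attempt < self.retries:
                    time.sleep(self.backoff * (2**attempt))
        raise BackendError(
            f"completion failed after {self.retries + 1} attempts: {last_error}"
        )


def _stable_rng(seed: int, doc_id: str, label: str) -> random.Random:
    digest = hashlib.sha256(f"{seed}|{doc_id}|{label}".encode("utf-8")).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


class MockBackend:
    """Deterministic LLM stand-in emitting grammar-valid records.

    Given the per-document truth, serializes each record in the grammar's
    language; with probability ``error_rate`` per label it perturbs the
    value in a kind-preserving way (boolean flip, categorical resample,
    number +/-1, string character drop), so perturbed outputs still parse.
    Documents listed in ``corrupt_doc_ids`` yield non-JSON garbage and
    ``truncate_doc_ids`` yield a cut-off completion, for failure-path tests.
    """

    name = "mock"

    def __init__(
        self,
        schema: ExtractionSchema,
        truth: Mapping[str, Mapping[str, Any]],
        error_rate: float = 0.0,
        seed: int = 0,
        corrupt_doc_ids: frozenset[str] | set[str] = frozenset(),
        truncate_doc_ids: frozenset[str] | set[str] = frozenset(),
    ):
        if not 0 <= error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        self.schema = schema
        self.truth = truth
        self.error_rate = error_rate
        self.seed = seed
        self.corrupt_doc_ids = set(corrupt_doc_ids)
        self.truncate_doc_ids = set(truncate_doc_ids)

    def _perturb(self, spec, value, rng: random.Random):
        if spec.kind == "boolean":
            return not value
        if spec.kind == "categorical":
            others = [c for c in spec.categories if c != value]
            return rng.choice(others)
        if spec.kind == "number":
            v = int(str(value)) if "." not in str(value) else float(str(value))
            delta = rng.choice((-1, 1))
            out = v + delta
            if out < 0 or len(str(out)) > spec.max_length:
                out = v - delta
            return str(out)
        # string: drop one character (or substitute when empty)
        s = str(value)
        if not s:
            return "x"
        i = rng.randrange(len(s))
        return s[:i] + s[i + 1 :]

    def complete(
        self, request: CompletionRequest, context: Mapping[str, Any] | None = None
    ) -> CompletionResult:
        if not context or "doc_id" not in context:
            raise BackendError("mock backend requires chunk identity in context")
        doc_id = str(context["doc_id"])
        if doc_id in self.corrupt_doc_ids:
            return CompletionResult(text="%% not json %%", finish_reason="stop")
        if doc_id not in self.truth:
            raise BackendError(f"mock backend has no truth for document {doc_id!r}")
        values = dict(self.truth[doc_id])
        for spec in self.schema.labels:
            if spec.name not in values:
                raise BackendError(
                    f"truth for {doc_id!r} lacks label {spec.name!r}"
                )
            rng = _stable_rng(self.seed, doc_id, spec.name)
            if rng.random() < self.error_rate:
                values[spec.name] = self._perturb(spec, values[spec.name], rng)
        text = serialize_record(self.schema, values)
        if doc_id in self.truncate_doc_ids:
            return CompletionResult(text=text[: len(text) // 2], finish_reason="length")
        return CompletionResult(text=text, finish_reason="stop")


def make_backend(kind: str, **kwargs):
    """Config-driven backend selection: ``http`` or ``mock``."""
    if kind == "http":
        return HttpBackend(**kwargs)
    if kind == "mock":
        return MockBackend(**kwargs)
    raise ValueError(f"unknown backend kind: {kind!r}")
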