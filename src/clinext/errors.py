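"""Exception hierarchy.

Every error the pipeline can raise derives from :class:`ClinextError` so
callers can catch the package's failures without catching programming bugs.
"""


class ClinextError(Exception):
    """Base class for all package errors."""


class CorpusError(ClinextError):
    """Ingestion problems: missing columns, duplicate ids, undecodable files."""


class OcrRequiredError(CorpusError):
    """A PDF has no text layer and no OCR adapter is configured."""


class BundleError(ClinextError):
    """A preprocessed bundle is missing pieces or violates chunk invariants."""


class SchemaError(ClinextError):
    """An extraction schema violates a LabelSpec invariant."""


class GrammarError(ClinextError):
    """A grammar text cannot be parsed or uses an unsupported construct."""


class OutputParseError(ClinextError):
    """A model completion could not be parsed/validated against the schema.

    Carries the raw completion text so failed outputs can be audited.
    """

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw


class TemplateError(ClinextError):
    """A prompt template does not contain exactly one ``{report}`` placeholder."""


class BackendError(ClinextError):
    """The completion backend failed after exhausting retries."""


class EvaluationError(ClinextError):
    """Evaluation inputs are inconsistent (length mismatch, empty counts, ...)."""


class ConfigurationError(ClinextError):
    """A run was configured with unknown labels, unconfirmed kinds, etc."""


class IngestionWarning(UserWarning):
    """Non-fatal ingestion findings, e.g. an empty report cell."""
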