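"""Exception hierarchy.

Every error raised by the library derives from :class:`ToxflowError` so
callers (and the command-line layer, which maps error classes to exit
codes) can distinguish library failures from programming errors.
"""


class ToxflowError(Exception):
    """Base class for all toxflow errors."""


class SchemaError(ToxflowError):
    """An input file does not match the declared column schema."""


class UnknownLabelError(ToxflowError):
    """A level, stage, arm or term label is not in the declared vocabulary."""


class DuplicateRecordError(ToxflowError):
    """More than one observation for the same (patient, term, timepoint)."""


class NoMatchingRecordsError(ToxflowError):
    """A selection named a term or arm that has no records at all."""


class ValidationError(ToxflowError):
    """A table failed strict validation; carries the findings."""

    def __init__(self, findings):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings)
        super().__init__(f"{len(self.findings)} validation finding(s): {lines}")


class ConfigurationError(ToxflowError):
    """A scale, spec or query is internally inconsistent for the request."""
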